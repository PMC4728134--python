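"""Synthetic growth-cone filopodia with the statistical structure the
analysis assumes.

Each filopodium is simulated independently on the session's frame grid:

* it is born at a frame drawn uniformly over the observation window, with
  an orientation angle uniform on [0, 360);
* it belongs to a short-lived ("transient") class with probability
  ``transient_fraction``, otherwise to a long-lived ("stable") class; its
  nominal lifetime in frames is geometric (discrete-time, memoryless) with
  the class mean, truncated to at least one interval and — for the stable
  class — to at least the stable cutoff (60 min);
* at every interval the length is unchanged ("static") with probability
  ``p_static``; otherwise it takes a signed step whose magnitude is normal
  with mean ``step_mean_um`` and sd ``step_sd_um``, truncated below at the
  static threshold so that generated moving steps are detected as moving,
  and whose sign is an extension with probability ``p_extend_given_moving``;
* a retraction that would cross zero is recorded as a final sample at
  length 0 and ends the filopodium early (full retraction out of
  existence — the realistic fate of transient filopodia);
* the track is right-truncated at the window end, so window censoring
  arises naturally.

Defaults emulate a wild-type growth cone during early layer formation:
1-min frames over a 1-hr window, ~90% transient filopodia, moving-step
speeds around 1.3 μm/min and a per-interval static probability of 0.3.

A single global ``seed`` expands into independent per-track substreams by
counter, so changing ``n_filopodia`` never reshuffles earlier tracks and an
identical seed reproduces a session bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import IO

import numpy as np
import yaml
from scipy import stats

from .dynamics import STATIC_THRESHOLD_UM, STABLE_MIN_LIFETIME_MIN
from .track_io import FilopodiumTrack, ImagingSession

__all__ = [
    "SimParams",
    "truncated_step_mean",
    "simulate_filopodium",
    "simulate_session",
    "simulate_cohort",
    "load_params",
    "dump_params",
]


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for the synthetic growth-cone process.

    Units: lengths in μm, times in minutes, speeds in μm/min.
    """

    n_filopodia: int = 100
    transient_fraction: float = 0.9
    lifetime_mean_transient_min: float = 3.0
    lifetime_mean_stable_min: float = 90.0
    p_static: float = 0.3
    step_mean_um: float = 1.3
    step_sd_um: float = 0.3
    p_extend_given_moving: float = 0.5
    init_length_um: float = 1.5
    interval_min: float = 1.0
    window_min: float = 60.0
    static_threshold_um: float = STATIC_THRESHOLD_UM
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "transient_fraction": self.transient_fraction,
            "p_static": self.p_static,
            "p_extend_given_moving": self.p_extend_given_moving,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p!r}")
        if self.n_filopodia < 0:
            raise ValueError("n_filopodia must be >= 0")
        if self.interval_min <= 0 or self.window_min <= 0:
            raise ValueError("interval_min and window_min must be > 0")
        if self.static_threshold_um <= 0:
            raise ValueError("static_threshold_um must be > 0")
        if self.step_mean_um < self.static_threshold_um:
            raise ValueError(
                "step_mean_um must be >= static_threshold_um so that moving "
                "steps are detectable"
            )
        if self.step_sd_um <= 0:
            raise ValueError("step_sd_um must be > 0")
        if self.lifetime_mean_transient_min < self.interval_min:
            raise ValueError("transient lifetime mean must be >= one interval")
        if self.lifetime_mean_stable_min < STABLE_MIN_LIFETIME_MIN:
            raise ValueError(
                "stable lifetime mean must be >= the stable cutoff "
                f"({STABLE_MIN_LIFETIME_MIN:g} min)"
            )
        if self.init_length_um <= 0:
            raise ValueError("init_length_um must be > 0")
        if not 0 <= int(self.seed) < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")


def truncated_step_mean(params: SimParams) -> float:
    """Mean of the moving-step magnitude distribution.

    The magnitude is normal(step_mean, step_sd) truncated below at the
    static threshold; the truncation shifts the mean slightly above
    ``step_mean_um``.
    """
    a = (params.static_threshold_um - params.step_mean_um) / params.step_sd_um
    return float(
        stats.truncnorm.mean(
            a, np.inf, loc=params.step_mean_um, scale=params.step_sd_um
        )
    )


def _track_rng(params: SimParams, index: int, session_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(params.seed), spawn_key=(session_index, index)
    )
    return np.random.default_rng(ss)


def _draw_lifetime_intervals(params: SimParams, rng: np.random.Generator) -> int:
    """Nominal lifetime in frame intervals (before window/zero truncation)."""
    transient = rng.random() < params.transient_fraction
    mean = (
        params.lifetime_mean_transient_min
        if transient
        else params.lifetime_mean_stable_min
    )
    p = min(1.0, params.interval_min / mean)
    min_intervals = (
        1
        if transient
        else int(np.ceil(STABLE_MIN_LIFETIME_MIN / params.interval_min))
    )
    for _ in range(10_000):
        k = int(rng.geometric(p))
        if k >= min_intervals:
            return k
    raise RuntimeError(
        "could not draw a lifetime above the class minimum; check the "
        "lifetime means"
    )


def simulate_filopodium(
    params: SimParams, rng: np.random.Generator, track_id: str = "f0"
) -> FilopodiumTrack:
    """Simulate one filopodium track from an explicit random stream."""
    params.validate()
    n_frames = int(round(params.window_min / params.interval_min)) + 1
    angle = float(rng.uniform(0.0, 360.0))
    birth = int(rng.integers(0, n_frames))
    k = _draw_lifetime_intervals(params, rng)
    k = min(k, (n_frames - 1) - birth)  # right-truncate at the window end

    lengths = [params.init_length_um]
    if k > 0:
        is_static = rng.random(k) < params.p_static
        a = (params.static_threshold_um - params.step_mean_um) / params.step_sd_um
        mags = stats.truncnorm.rvs(
            a,
            np.inf,
            loc=params.step_mean_um,
            scale=params.step_sd_um,
            size=k,
            random_state=rng,
        )
        signs = np.where(rng.random(k) < params.p_extend_given_moving, 1.0, -1.0)
        for j in range(k):
            if is_static[j]:
                lengths.append(lengths[-1])
                continue
            new_len = lengths[-1] + signs[j] * mags[j]
            if new_len <= 0.0:
                # full retraction: clamp at 0 and end the filopodium
                lengths.append(0.0)
                break
            lengths.append(new_len)
    samples = tuple(
        ((birth + j) * params.interval_min, float(l))
        for j, l in enumerate(lengths)
    )
    return FilopodiumTrack(track_id=track_id, angle_deg=angle, samples=samples)


def simulate_session(
    params: SimParams,
    *,
    session_id: str = "sim",
    genotype: str = "simulated",
    stage_pct: float | None = None,
    session_index: int = 0,
) -> ImagingSession:
    """Simulate a full growth-cone session; identical seeds give identical
    sessions bit-for-bit."""
    params.validate()
    tracks = [
        simulate_filopodium(
            params, _track_rng(params, i, session_index), track_id=f"f{i:04d}"
        )
        for i in range(params.n_filopodia)
    ]
    session = ImagingSession(
        session_id=session_id,
        interval_min=params.interval_min,
        window=(0.0, params.window_min),
        tracks=tracks,
        genotype=genotype,
        stage_pct=stage_pct,
    )
    session.validate()
    return session


def simulate_cohort(
    params_a: SimParams,
    params_b: SimParams,
    n_sessions: int,
    *,
    labels: tuple[str, str] = ("arm_a", "arm_b"),
) -> tuple[list[ImagingSession], list[ImagingSession]]:
    """Simulate two arms of a cohort (e.g. wild type vs mutant).

    Each arm draws ``n_sessions`` independent sessions from its own params
    and seed; the arm label is attached as the genotype.
    """
    if n_sessions < 0:
        raise ValueError("n_sessions must be >= 0")
    arms: list[list[ImagingSession]] = []
    for arm_idx, (params, label) in enumerate(
        zip((params_a, params_b), labels)
    ):
        arm = [
            simulate_session(
                params,
                session_id=f"{label}_{s}",
                genotype=label,
                session_index=arm_idx * max(n_sessions, 1) + s,
            )
            for s in range(n_sessions)
        ]
        arms.append(arm)
    return arms[0], arms[1]


def load_params(stream: IO[str] | str) -> SimParams:
    """Read :class:`SimParams` from a YAML/key: value config stream."""
    data = yaml.safe_load(stream) or {}
    if not isinstance(data, dict):
        raise ValueError("params config must be a mapping of key: value pairs")
    known = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
    params = SimParams(**data)
    params.validate()
    return params


def dump_params(params: SimParams, stream: IO[str]) -> None:
    """Write :class:`SimParams` as a YAML config."""
    yaml.safe_dump(dataclasses.asdict(params), stream, sort_keys=False)
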