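"""Per-filopodium motion metrics and lifetime classification.

Given a filopodium's length-over-time track sampled at a fixed frame
interval, this module computes the quantities used to characterise growth
cone filopodial dynamics:

* inter-frame length changes, partitioned into *extension*, *retraction*
  and *static* steps by a minimum-displacement threshold (default 0.3 μm —
  manual filament segmentation cannot resolve smaller changes reliably);
* counts of extension/retraction *events* (maximal same-direction runs of
  moving steps; a static step terminates a run);
* mean speed over moving steps only, with extension and retraction pooled;
* *inactivity*, the fraction of inter-frame intervals that are static;
* lifetime, and a lifetime-based dynamic class: **transient** (< 8 min,
  uncensored), **stable** (≥ 60 min, censoring allowed since an observed
  lifetime is a lower bound), **indeterminate** (censored below 60 min) or
  **intermediate** (everything else);
* a seven-bin lifetime histogram classification.

The threshold partition is exhaustive: a change of exactly the threshold
counts as movement ("static" is strictly below it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .track_io import FilopodiumTrack, ImagingSession

__all__ = [
    "STATIC_THRESHOLD_UM",
    "TRANSIENT_MAX_LIFETIME_MIN",
    "STABLE_MIN_LIFETIME_MIN",
    "LIFETIME_BINS",
    "StepRecord",
    "FilopodiumMetrics",
    "GrowthConeSummary",
    "step_deltas",
    "count_events",
    "mean_speed",
    "inactivity",
    "classify_dynamics",
    "lifetime_bin",
    "filopodium_metrics",
    "session_metrics",
    "growth_cone_summary",
]

#: Minimum absolute inter-frame length change (μm) counted as real movement.
STATIC_THRESHOLD_UM = 0.3

#: Lifetimes strictly below this (minutes) are transient when uncensored.
TRANSIENT_MAX_LIFETIME_MIN = 8.0

#: Lifetimes at or above this (minutes) are stable even when censored.
STABLE_MIN_LIFETIME_MIN = 60.0

#: Lifetime histogram bins, as (label, lower edge, upper edge) with the
#: upper edge exclusive; edges in whole observed minutes.
LIFETIME_BINS = (
    ("<1 min", 0.0, 2.0),
    ("2-3 min", 2.0, 4.0),
    ("4-7 min", 4.0, 8.0),
    ("8-15 min", 8.0, 16.0),
    ("16-31 min", 16.0, 32.0),
    ("32-59 min", 32.0, 60.0),
    (">=60 min", 60.0, math.inf),
)

DYN_CLASSES = ("transient", "stable", "intermediate", "indeterminate")


@dataclass(frozen=True)
class StepRecord:
    """One inter-frame interval: signed length change and its kind.

    ``kind`` is ``"static"`` iff ``|delta_um|`` is strictly below the static
    threshold, ``"extension"`` for ``delta_um >= +threshold`` and
    ``"retraction"`` for ``delta_um <= -threshold``; the three kinds
    partition all intervals.
    """

    t_from_min: float
    t_to_min: float
    delta_um: float
    kind: str

    @property
    def moving(self) -> bool:
        return self.kind != "static"


@dataclass(frozen=True)
class FilopodiumMetrics:
    """Derived per-filopodium quantities.

    ``mean_speed_um_min`` is ``None`` when the track has no moving interval;
    ``inactivity`` is ``None`` when the track has fewer than two samples.
    ``lifetime_min`` is last minus first sample time, so a single-frame track
    has lifetime 0.
    """

    track_id: str
    lifetime_min: float
    n_frames: int
    left_censored: bool
    right_censored: bool
    n_ext_events: int
    n_ret_events: int
    mean_length_um: float
    mean_speed_um_min: float | None
    inactivity: float | None
    dyn_class: str
    lifetime_bin: str


def step_deltas(
    track: FilopodiumTrack, static_threshold_um: float = STATIC_THRESHOLD_UM
) -> list[StepRecord]:
    """Classify every consecutive sample pair of a track into a step record.

    A single-sample track yields an empty list.
    """
    if static_threshold_um <= 0:
        raise ValueError("static_threshold_um must be > 0")
    steps: list[StepRecord] = []
    for (t0, l0), (t1, l1) in zip(track.samples, track.samples[1:]):
        delta = l1 - l0
        if abs(delta) < static_threshold_um:
            kind = "static"
        elif delta > 0:
            kind = "extension"
        else:
            kind = "retraction"
        steps.append(StepRecord(t0, t1, delta, kind))
    return steps


def count_events(steps: Sequence[StepRecord]) -> tuple[int, int]:
    """Count extension and retraction events.

    An event is a maximal run of consecutive moving intervals of the same
    kind; static intervals terminate runs.
    """
    n_ext = n_ret = 0
    prev = "static"
    for s in steps:
        if s.kind != prev and s.kind == "extension":
            n_ext += 1
        elif s.kind != prev and s.kind == "retraction":
            n_ret += 1
        prev = s.kind
    return n_ext, n_ret


def mean_speed(
    steps: Sequence[StepRecord], interval_min: float
) -> float | None:
    """Mean of |Δlength|/interval over moving intervals; None if none move.

    Extension and retraction are pooled into a single average, as their
    speeds are statistically indistinguishable in this system.
    """
    moving = [abs(s.delta_um) for s in steps if s.moving]
    if not moving:
        return None
    return sum(moving) / len(moving) / interval_min


def inactivity(steps: Sequence[StepRecord]) -> float | None:
    """Fraction of inter-frame intervals that are static; None for <2 frames."""
    if not steps:
        return None
    n_static = sum(1 for s in steps if not s.moving)
    return n_static / len(steps)


def classify_dynamics(
    lifetime_min: float, left_censored: bool, right_censored: bool
) -> str:
    """Assign the lifetime-based dynamic class.

    The observed lifetime of a censored track is a lower bound on the true
    lifetime, so a censored track at or above the stable cutoff is still
    stable, while a censored track below it cannot be classified
    (indeterminate).  Transient requires both a short lifetime and no
    censoring.
    """
    if lifetime_min < 0:
        raise ValueError("lifetime_min must be >= 0")
    censored = left_censored or right_censored
    if lifetime_min >= STABLE_MIN_LIFETIME_MIN:
        return "stable"
    if censored:
        return "indeterminate"
    if lifetime_min < TRANSIENT_MAX_LIFETIME_MIN:
        return "transient"
    return "intermediate"


def lifetime_bin(lifetime_min: float) -> str:
    """Map a lifetime to its histogram bin label."""
    if lifetime_min < 0:
        raise ValueError("lifetime_min must be >= 0")
    for label, lo, hi in LIFETIME_BINS:
        if lo <= lifetime_min < hi:
            return label
    raise AssertionError("unreachable: bins cover [0, inf)")


def _censoring_flags(
    track: FilopodiumTrack, window: tuple[float, float], interval_min: float
) -> tuple[bool, bool]:
    tol = 1e-6 * max(1.0, interval_min)
    left = abs(track.times[0] - window[0]) <= tol
    right = abs(track.times[-1] - window[1]) <= tol
    return left, right


def filopodium_metrics(
    track: FilopodiumTrack,
    interval_min: float,
    static_threshold_um: float = STATIC_THRESHOLD_UM,
    window: tuple[float, float] | None = None,
) -> FilopodiumMetrics:
    """Compute all per-filopodium metrics for one track.

    ``window`` is the session observation window used to set the censoring
    flags (a track whose first/last sample coincides with the window
    boundary is censored on that side); when None, the track is treated as
    uncensored.
    """
    steps = step_deltas(track, static_threshold_um)
    if window is not None:
        left, right = _censoring_flags(track, window, interval_min)
    else:
        left = right = False
    lifetime = track.times[-1] - track.times[0]
    n_ext, n_ret = count_events(steps)
    lengths = track.lengths
    return FilopodiumMetrics(
        track_id=track.track_id,
        lifetime_min=lifetime,
        n_frames=track.n_frames,
        left_censored=left,
        right_censored=right,
        n_ext_events=n_ext,
        n_ret_events=n_ret,
        mean_length_um=sum(lengths) / len(lengths),
        mean_speed_um_min=mean_speed(steps, interval_min),
        inactivity=inactivity(steps),
        dyn_class=classify_dynamics(lifetime, left, right),
        lifetime_bin=lifetime_bin(lifetime),
    )


def session_metrics(
    session: ImagingSession,
    static_threshold_um: float = STATIC_THRESHOLD_UM,
) -> list[FilopodiumMetrics]:
    """Per-filopodium metrics for every track of a session."""
    return [
        filopodium_metrics(
            t, session.interval_min, static_threshold_um, session.window
        )
        for t in session.tracks
    ]


@dataclass(frozen=True)
class GrowthConeSummary:
    """Per-growth-cone (session-level) filopodia summary.

    ``mean_length_um`` is the grand mean of the per-filopodium mean lengths
    (each filopodium weighted equally, not each frame); None when the session
    is empty.
    """

    session_id: str
    n_filopodia: int
    class_counts: dict[str, int]
    bin_counts: dict[str, int]
    mean_length_um: float | None


def growth_cone_summary(
    session: ImagingSession,
    metrics: Iterable[FilopodiumMetrics] | None = None,
    static_threshold_um: float = STATIC_THRESHOLD_UM,
) -> GrowthConeSummary:
    """Summarise one growth cone: counts per class/bin and mean length."""
    ms = (
        list(metrics)
        if metrics is not None
        else session_metrics(session, static_threshold_um)
    )
    class_counts = {c: 0 for c in DYN_CLASSES}
    bin_counts = {label: 0 for label, _, _ in LIFETIME_BINS}
    for m in ms:
        class_counts[m.dyn_class] += 1
        bin_counts[m.lifetime_bin] += 1
    mean_len = (
        sum(m.mean_length_um for m in ms) / len(ms) if ms else None
    )
    return GrowthConeSummary(
        session_id=session.session_id,
        n_filopodia=len(ms),
        class_counts=class_counts,
        bin_counts=bin_counts,
        mean_length_um=mean_len,
    )
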