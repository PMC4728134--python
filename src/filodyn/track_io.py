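"""Reading and writing filopodium track tables.

Filament-tracking software exports, per growth cone, the length of every
filopodium over time together with the orientation angle it had when it first
formed.  This module defines the in-memory containers for those exports
(:class:`FilopodiumTrack`, :class:`ImagingSession`) and reads/writes them in
two delimited-text dialects:

* **long** (canonical): one row per (track, frame) with columns
  ``track_id,time_min,length_um,angle_deg``;
* **wide**: one row per frame, one column per filopodium, empty cells where
  the filopodium does not exist, with an optional second header row carrying
  the per-column angles.

Times are minutes from the session start (first frame = 0).  Lengths are the
3D filament lengths as exported, in micrometres; no geometry is done here.
Angles are reduced modulo 360 on read so that stored values lie in [0, 360).
Missing values in outputs are written as the literal token ``NA``, never 0:
a zero is a meaningful measurement in this analysis.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FilopodiumTrack",
    "ImagingSession",
    "TrackFormatError",
    "TrackValidationError",
    "NA_TOKEN",
    "METRICS_COLUMNS",
    "read_tracks_long",
    "read_tracks_wide",
    "write_tracks_long",
    "write_tracks_wide",
    "write_metrics",
    "read_metrics",
]

#: Sentinel token used for undefined values in all delimited outputs.
NA_TOKEN = "NA"

#: Fixed column order of the per-filopodium metrics table.
METRICS_COLUMNS = (
    "track_id",
    "lifetime_min",
    "n_frames",
    "left_censored",
    "right_censored",
    "n_ext_events",
    "n_ret_events",
    "mean_length_um",
    "mean_speed_um_min",
    "inactivity",
    "dyn_class",
    "lifetime_bin",
)

_LONG_COLUMNS = ("track_id", "time_min", "length_um", "angle_deg")

#: Relative tolerance used when checking frame-interval uniformity.
_TIME_RTOL = 1e-6


class TrackFormatError(ValueError):
    """The input stream is not a recognisable track table (e.g. missing column)."""


class TrackValidationError(ValueError):
    """The table parsed but violates a track/session invariant."""


@dataclass(frozen=True)
class FilopodiumTrack:
    """One filopodium: a length time series plus its initial orientation.

    Parameters
    ----------
    track_id:
        Opaque identifier, unique within a session.
    angle_deg:
        Orientation of the base->tip vector in the imaging plane at the time
        of initial formation, degrees in [0, 360).
    samples:
        Ordered ``(time_min, length_um)`` pairs at the session frame interval,
        with no internal gaps.
    """

    track_id: str
    angle_deg: float
    samples: tuple[tuple[float, float], ...]

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.samples)

    @property
    def lengths(self) -> tuple[float, ...]:
        return tuple(length for _, length in self.samples)

    @property
    def n_frames(self) -> int:
        return len(self.samples)

    def validate(self, interval_min: float) -> None:
        if not self.samples:
            raise TrackValidationError(
                f"track {self.track_id!r} has no samples"
            )
        if not math.isfinite(self.angle_deg) or not 0.0 <= self.angle_deg < 360.0:
            raise TrackValidationError(
                f"track {self.track_id!r}: angle {self.angle_deg!r} outside [0, 360)"
            )
        times = self.times
        for (t0, l0), (t1, _l1) in zip(self.samples, self.samples[1:]):
            dt = t1 - t0
            if dt <= 0 or abs(dt - interval_min) > _TIME_RTOL * max(1.0, interval_min):
                raise TrackValidationError(
                    f"track {self.track_id!r}: non-uniform time spacing "
                    f"{dt:g} min between t={t0:g} and t={t1:g} "
                    f"(expected interval {interval_min:g} min)"
                )
        for t, length in self.samples:
            if not math.isfinite(length) or length < 0:
                raise TrackValidationError(
                    f"track {self.track_id!r}: invalid length {length!r} at t={t:g}"
                )
        del times


@dataclass
class ImagingSession:
    """A growth cone's tracked filopodia over one observation window.

    ``window`` is ``(t_start_min, t_end_min)``; every track's samples must lie
    within it.  ``stage_pct`` is the developmental stage as percent of pupal
    development (e.g. 28 for P + 28%); it may be ``None`` when unknown.
    """

    session_id: str
    interval_min: float
    window: tuple[float, float]
    tracks: list[FilopodiumTrack] = field(default_factory=list)
    genotype: str = ""
    stage_pct: float | None = None

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def validate(self) -> None:
        if self.interval_min <= 0:
            raise TrackValidationError(
                f"session {self.session_id!r}: interval must be > 0"
            )
        t_start, t_end = self.window
        if t_end < t_start:
            raise TrackValidationError(
                f"session {self.session_id!r}: window end precedes start"
            )
        seen: set[str] = set()
        for track in self.tracks:
            if track.track_id in seen:
                raise TrackValidationError(
                    f"session {self.session_id!r}: duplicate track_id "
                    f"{track.track_id!r}"
                )
            seen.add(track.track_id)
            track.validate(self.interval_min)
            tol = _TIME_RTOL * max(1.0, self.interval_min)
            if track.times[0] < t_start - tol or track.times[-1] > t_end + tol:
                raise TrackValidationError(
                    f"track {track.track_id!r} extends outside the session "
                    f"window [{t_start:g}, {t_end:g}]"
                )


def _normalize_angle(angle: float) -> float:
    a = float(angle) % 360.0
    return 0.0 if a == 360.0 else a


def _infer_window(
    tracks: Sequence[FilopodiumTrack], window: tuple[float, float] | None
) -> tuple[float, float]:
    if window is not None:
        return (float(window[0]), float(window[1]))
    if not tracks:
        return (0.0, 0.0)
    t_max = max(t.times[-1] for t in tracks)
    t_min = min(0.0, min(t.times[0] for t in tracks))
    return (t_min, t_max)


def _read_table(stream: IO[str] | str, delimiter: str | None) -> pd.DataFrame:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if delimiter is None:
        head = stream.readline()
        stream = io.StringIO(head + stream.read())
        delimiter = "\t" if "\t" in head else ","
    return pd.read_csv(
        stream, sep=delimiter, dtype={0: str}, na_values=[NA_TOKEN, ""],
        keep_default_na=False, skipinitialspace=True,
        float_precision="round_trip",
    )


def read_tracks_long(
    stream: IO[str] | str,
    interval_min: float,
    *,
    delimiter: str | None = None,
    session_id: str = "session",
    genotype: str = "",
    stage_pct: float | None = None,
    window: tuple[float, float] | None = None,
) -> ImagingSession:
    """Parse a long-dialect track table into a validated session.

    The stream must have header columns ``track_id,time_min,length_um,
    angle_deg`` (comma- or tab-delimited; autodetected when ``delimiter`` is
    None).  Rows are grouped by ``track_id`` and sorted by time; the angle is
    taken from each track's first row.  When ``window`` is None it is inferred
    as ``(0, max observed time)`` — censoring flags derived from an inferred
    window are conservative.
    """
    df = _read_table(stream, delimiter)
    for col in _LONG_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"missing required column {col!r}")
    tracks: list[FilopodiumTrack] = []
    for track_id, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("time_min")
        angle = _normalize_angle(float(grp["angle_deg"].iloc[0]))
        samples = tuple(
            (float(t), float(l))
            for t, l in zip(grp["time_min"], grp["length_um"])
        )
        tracks.append(FilopodiumTrack(str(track_id), angle, samples))
    session = ImagingSession(
        session_id=session_id,
        interval_min=float(interval_min),
        window=_infer_window(tracks, window),
        tracks=tracks,
        genotype=genotype,
        stage_pct=stage_pct,
    )
    session.validate()
    return session


def read_tracks_wide(
    stream: IO[str] | str,
    interval_min: float,
    *,
    delimiter: str | None = None,
    angles: Mapping[str, float] | None = None,
    session_id: str = "session",
    genotype: str = "",
    stage_pct: float | None = None,
    window: tuple[float, float] | None = None,
) -> ImagingSession:
    """Parse a wide-dialect table (one column per filopodium).

    The first column is ``time_min``; every other column is one track, named
    by its ``track_id``, with empty cells where the filopodium does not exist.
    Each track's samples are the single contiguous non-empty run of its
    column; a hole inside the run is a validation error.  Per-column angles
    come from an optional second header row whose ``time_min`` cell holds the
    token ``angle_deg``, or from the ``angles`` mapping; with neither, angles
    default to 0 with a warning.
    """
    df = _read_table(stream, delimiter)
    if df.columns[0] != "time_min":
        raise TrackFormatError("first column of a wide table must be 'time_min'")
    angle_row: Mapping[str, float] | None = None
    first_cell = df.iloc[0, 0] if len(df) else None
    if isinstance(first_cell, str) and first_cell.strip() == "angle_deg":
        angle_row = {
            col: float(df[col].iloc[0])
            for col in df.columns[1:]
            if not pd.isna(df[col].iloc[0])
        }
        df = df.iloc[1:].reset_index(drop=True)
    if angles is None:
        angles = angle_row
    if angles is None:
        warnings.warn(
            "wide table has no angle_deg row and no angles mapping; "
            "angles default to 0",
            stacklevel=2,
        )
        angles = {}

    times = [float(t) for t in df["time_min"]]
    tracks: list[FilopodiumTrack] = []
    for col in df.columns[1:]:
        values = pd.to_numeric(df[col], errors="coerce")
        present = values.notna().to_numpy()
        idx = present.nonzero()[0]
        if idx.size == 0:
            raise TrackValidationError(f"track {col!r}: column is entirely empty")
        run = range(idx[0], idx[-1] + 1)
        if not present[run].all():
            raise TrackValidationError(
                f"track {col!r}: non-contiguous lifetime (hole inside the "
                "non-empty run)"
            )
        samples = tuple((times[i], float(values.iloc[i])) for i in run)
        angle = _normalize_angle(float(angles.get(col, 0.0)))
        tracks.append(FilopodiumTrack(str(col), angle, samples))
    session = ImagingSession(
        session_id=session_id,
        interval_min=float(interval_min),
        window=_infer_window(tracks, window),
        tracks=tracks,
        genotype=genotype,
        stage_pct=stage_pct,
    )
    session.validate()
    return session


def _fmt(x: float) -> str:
    """Format a float so that reading it back reproduces the value exactly."""
    return repr(float(x))


def write_tracks_long(session: ImagingSession, stream: IO[str]) -> int:
    """Write a session in the long dialect; returns the data-row count."""
    stream.write(",".join(_LONG_COLUMNS) + "\n")
    n = 0
    for track in session.tracks:
        for t, length in track.samples:
            stream.write(
                f"{track.track_id},{_fmt(t)},{_fmt(length)},{_fmt(track.angle_deg)}\n"
            )
            n += 1
    return n


def write_tracks_wide(session: ImagingSession, stream: IO[str]) -> int:
    """Write a session in the wide dialect (with an angle_deg header row)."""
    t_start, t_end = session.window
    n_frames = int(round((t_end - t_start) / session.interval_min)) + 1
    times = [t_start + i * session.interval_min for i in range(n_frames)]
    cols = [track.track_id for track in session.tracks]
    stream.write(",".join(["time_min", *cols]) + "\n")
    stream.write(
        ",".join(["angle_deg", *(_fmt(t.angle_deg) for t in session.tracks)]) + "\n"
    )
    index = {
        track.track_id: dict(track.samples) for track in session.tracks
    }
    tol = _TIME_RTOL * max(1.0, session.interval_min)

    def lookup(track_id: str, t: float) -> str:
        table = index[track_id]
        for tt, length in table.items():
            if abs(tt - t) <= tol:
                return _fmt(length)
        return ""

    for t in times:
        row = [lookup(c, t) for c in cols]
        stream.write(",".join([_fmt(t), *row]) + "\n")
    return n_frames


def write_metrics(metrics: Iterable, stream: IO[str]) -> int:
    """Write per-filopodium metrics as delimited text; returns data-row count.

    One row per filopodium in the fixed :data:`METRICS_COLUMNS` order.
    Undefined values (``None``) are written as the ``NA`` token.
    """
    stream.write(",".join(METRICS_COLUMNS) + "\n")
    n = 0
    for m in metrics:
        cells = []
        for col in METRICS_COLUMNS:
            value = getattr(m, col)
            if value is None:
                cells.append(NA_TOKEN)
            elif isinstance(value, bool):
                cells.append(str(value).lower())
            elif isinstance(value, float):
                cells.append(_fmt(value))
            else:
                cells.append(str(value))
        stream.write(",".join(cells) + "\n")
        n += 1
    return n


def read_metrics(stream: IO[str] | str, *, delimiter: str | None = None) -> pd.DataFrame:
    """Read a metrics table written by :func:`write_metrics` into a DataFrame."""
    df = _read_table(stream, delimiter)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing metrics column(s): {missing}")
    for col in ("left_censored", "right_censored"):
        df[col] = df[col].map({"true": True, "false": False, True: True, False: False})
    return df
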