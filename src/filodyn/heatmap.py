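"""Angle-sorted filopodium length heat maps.

A growth cone's session is rendered as a time x filopodium matrix: one
column per filopodium, ordered by the orientation angle at initial
formation (ties broken by first-appearance time, then track id); one row
per frame of the observation window.  Cells hold the filopodium's length
where it exists and NaN elsewhere, so each column's non-missing run spans
exactly the filopodium's lifetime — the kymograph-style display in which
transient filopodia appear as short vertical strokes and stable ones as
full-height columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np

from .track_io import NA_TOKEN, ImagingSession

__all__ = ["HeatmapMatrix", "build_heatmap", "export_heatmap", "import_heatmap", "render_heatmap"]


@dataclass
class HeatmapMatrix:
    """Time x filopodium grid of lengths.

    ``values`` has shape ``(len(times), len(track_ids))`` with NaN marking
    frames where a filopodium does not exist.  Columns are in non-decreasing
    ``angles`` order.
    """

    times: np.ndarray
    track_ids: list[str]
    angles: np.ndarray
    values: np.ndarray

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)


def _time_grid(window: tuple[float, float], interval_min: float) -> np.ndarray:
    t_start, t_end = window
    n = int(round((t_end - t_start) / interval_min)) + 1 if t_end > t_start else 1
    return t_start + interval_min * np.arange(n)


def build_heatmap(session: ImagingSession) -> HeatmapMatrix:
    """Build the angle-sorted heat-map matrix for one session.

    An empty session yields a 0-column matrix over the full time grid.
    """
    times = _time_grid(session.window, session.interval_min)
    order = sorted(
        session.tracks, key=lambda t: (t.angle_deg, t.times[0], t.track_id)
    )
    values = np.full((len(times), len(order)), np.nan)
    t_start = session.window[0]
    for j, track in enumerate(order):
        for t, length in track.samples:
            i = int(round((t - t_start) / session.interval_min))
            values[i, j] = length
    return HeatmapMatrix(
        times=times,
        track_ids=[t.track_id for t in order],
        angles=np.array([t.angle_deg for t in order]),
        values=values,
    )


def export_heatmap(matrix: HeatmapMatrix, stream: IO[str]) -> int:
    """Write a heat-map matrix as delimited text; returns the data-row count.

    First column ``time_min``; one column per filopodium headed
    ``track_id@angle``; missing cells as ``NA``.  Floats are serialised to
    full precision so that :func:`import_heatmap` reproduces the matrix
    exactly.
    """
    headers = ["time_min"] + [
        f"{tid}@{float(a)!r}" for tid, a in zip(matrix.track_ids, matrix.angles)
    ]
    stream.write(",".join(headers) + "\n")
    for i, t in enumerate(matrix.times):
        cells = [repr(float(t))]
        for v in matrix.values[i]:
            cells.append(NA_TOKEN if np.isnan(v) else repr(float(v)))
        stream.write(",".join(cells) + "\n")
    return len(matrix.times)


def import_heatmap(stream: IO[str]) -> HeatmapMatrix:
    """Read a matrix written by :func:`export_heatmap`."""
    header = stream.readline().rstrip("\n").split(",")
    if not header or header[0] != "time_min":
        raise ValueError("heat-map export must start with a time_min column")
    track_ids: list[str] = []
    angles: list[float] = []
    for h in header[1:]:
        tid, _, angle = h.rpartition("@")
        track_ids.append(tid)
        angles.append(float(angle))
    times: list[float] = []
    rows: list[list[float]] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split(",")
        times.append(float(cells[0]))
        rows.append(
            [np.nan if c == NA_TOKEN else float(c) for c in cells[1:]]
        )
    values = (
        np.array(rows) if rows else np.empty((0, len(track_ids)))
    )
    if values.size == 0:
        values = values.reshape(len(times), len(track_ids))
    return HeatmapMatrix(
        times=np.array(times),
        track_ids=track_ids,
        angles=np.array(angles),
        values=values,
    )


def render_heatmap(
    matrix: HeatmapMatrix,
    path: str,
    *,
    cmap: str = "viridis",
    background: str = "#10306a",
    dpi: int = 100,
) -> str:
    """Render the matrix to a raster image with time on the y-axis.

    Filopodia run along x in angle order; cell colour encodes length (μm);
    missing cells take the background colour.  Returns the path written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(background)
    h = max(2.0, matrix.n_times / 15.0)
    w = max(2.0, matrix.n_tracks / 15.0)
    fig, ax = plt.subplots(figsize=(w, h))
    ax.set_facecolor(background)
    if matrix.n_tracks:
        im = ax.imshow(
            matrix.values,
            aspect="auto",
            interpolation="nearest",
            cmap=cm,
            extent=(
                -0.5,
                matrix.n_tracks - 0.5,
                float(matrix.times[-1]),
                float(matrix.times[0]),
            ),
        )
        fig.colorbar(im, ax=ax, label="length (μm)")
    ax.set_xlabel("filopodia (sorted by initial orientation angle)")
    ax.set_ylabel("time (min)")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
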