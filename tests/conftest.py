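"""Shared fixtures and an independent brute-force metrics oracle.

The oracle recomputes every per-filopodium metric with plain Python loops
straight from the length sequence, without touching the package's step/event
machinery, so agreement between the two is a meaningful check.
"""

from __future__ import annotations

import pytest

from filodyn import FilopodiumTrack, ImagingSession


def make_track(
    lengths,
    track_id: str = "f1",
    angle: float = 0.0,
    t0: float = 0.0,
    interval: float = 1.0,
) -> FilopodiumTrack:
    samples = tuple(
        (t0 + i * interval, float(l)) for i, l in enumerate(lengths)
    )
    return FilopodiumTrack(track_id=track_id, angle_deg=angle, samples=samples)


def make_session(
    tracks,
    interval: float = 1.0,
    window=(0.0, 60.0),
    session_id: str = "s1",
    **kwargs,
) -> ImagingSession:
    session = ImagingSession(
        session_id=session_id,
        interval_min=interval,
        window=tuple(window),
        tracks=list(tracks),
        **kwargs,
    )
    session.validate()
    return session


#: The worked trajectory: deltas (+0.5, +0.2, +0.8, 0.0) at 1-min spacing.
WORKED_LENGTHS = (0.5, 1.0, 1.2, 2.0, 2.0)


@pytest.fixture
def worked_track() -> FilopodiumTrack:
    # placed at t=1..5 so that it is uncensored inside a (0, 60) window
    return make_track(WORKED_LENGTHS, track_id="w1", angle=90.0, t0=1.0)


def naive_metrics(
    lengths,
    interval: float,
    threshold: float,
    t0: float = 0.0,
    window=None,
):
    """Brute-force per-filopodium metrics from a plain length sequence.

    Returns a dict with the same field names as FilopodiumMetrics.
    """
    n = len(lengths)
    times = [t0 + i * interval for i in range(n)]
    kinds = []
    for i in range(n - 1):
        d = lengths[i + 1] - lengths[i]
        if d >= threshold:
            kinds.append("E")
        elif d <= -threshold:
            kinds.append("R")
        else:
            kinds.append("S")
    n_ext = n_ret = 0
    for i, k in enumerate(kinds):
        if k == "E" and (i == 0 or kinds[i - 1] != "E"):
            n_ext += 1
        if k == "R" and (i == 0 or kinds[i - 1] != "R"):
            n_ret += 1
    moving = [
        abs(lengths[i + 1] - lengths[i])
        for i in range(n - 1)
        if kinds[i] != "S"
    ]
    speed = (sum(moving) / len(moving)) / interval if moving else None
    inact = (kinds.count("S") / len(kinds)) if kinds else None
    lifetime = times[-1] - times[0]
    left = window is not None and abs(times[0] - window[0]) <= 1e-9
    right = window is not None and abs(times[-1] - window[1]) <= 1e-9
    if lifetime >= 60.0:
        dyn = "stable"
    elif left or right:
        dyn = "indeterminate"
    elif lifetime < 8.0:
        dyn = "transient"
    else:
        dyn = "intermediate"
    if lifetime < 2:
        b = "<1 min"
    elif lifetime < 4:
        b = "2-3 min"
    elif lifetime < 8:
        b = "4-7 min"
    elif lifetime < 16:
        b = "8-15 min"
    elif lifetime < 32:
        b = "16-31 min"
    elif lifetime < 60:
        b = "32-59 min"
    else:
        b = ">=60 min"
    return {
        "lifetime_min": lifetime,
        "n_frames": n,
        "left_censored": left,
        "right_censored": right,
        "n_ext_events": n_ext,
        "n_ret_events": n_ret,
        "mean_length_um": sum(lengths) / n,
        "mean_speed_um_min": speed,
        "inactivity": inact,
        "dyn_class": dyn,
        "lifetime_bin": b,
    }
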