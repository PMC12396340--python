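"""Process motility: per-interval new-pixel index and branch-tip speeds."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Tuple

import numpy as np

from ..core import ImageSeries

__all__ = ["MotilityResult", "motility_index", "ProcessTrack", "process_speeds"]

Normalization = Literal["next", "current", "mean"]


@dataclass
class MotilityResult:
    """Per-interval motility indices and their movie-level mean."""

    per_frame: np.ndarray     # index per consecutive frame pair
    additions: np.ndarray     # new pixels per interval
    cell_sizes: np.ndarray    # normalizing cell size per interval
    mean: float


def motility_index(masks: ImageSeries, normalization: Normalization = "next") -> MotilityResult:
    """New pixels per interval normalised to cell size.

    For each consecutive pair of binary masks, additions are the pixels
    present at t+1 but absent at t.  The index divides additions by the
    cell size — by default the size at t+1, configurable to the size at
    t or the pair mean.
    """
    data = np.asarray(masks.data).astype(bool)
    if data.shape[0] < 2:
        raise ValueError("motility index needs at least 2 frames")
    sizes = data.reshape(data.shape[0], -1).sum(axis=1)
    if np.any(sizes == 0):
        raise ValueError("empty mask frame; cell size undefined")

    prev, nxt = data[:-1], data[1:]
    additions = (nxt & ~prev).reshape(len(nxt), -1).sum(axis=1)
    if normalization == "next":
        norm = sizes[1:]
    elif normalization == "current":
        norm = sizes[:-1]
    elif normalization == "mean":
        norm = (sizes[1:] + sizes[:-1]) / 2.0
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    idx = additions / norm
    return MotilityResult(per_frame=idx, additions=additions,
                          cell_sizes=np.asarray(norm, dtype=float),
                          mean=float(idx.mean()))


@dataclass
class ProcessTrack:
    """Positions of one branch tip over time, with its soma reference."""

    positions: np.ndarray       # (t, 2 or 3) µm
    soma: np.ndarray            # (2 or 3,) µm
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.soma = np.asarray(self.soma, dtype=float)
        if len(self.positions) < 2:
            raise ValueError("a track needs at least 2 time points")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    def radial_distance(self) -> np.ndarray:
        return np.linalg.norm(self.positions - self.soma, axis=1)


@dataclass
class MotilityEvent:
    kind: str                   # "extension" | "retraction"
    start: int                  # frame index
    stop: int
    net_um: float
    speed_um_per_min: float


def process_speeds(
    track: ProcessTrack,
    min_steps: int = 2,
    min_net_um: float = 0.5,
) -> List[MotilityEvent]:
    """Classify maximal monotone runs of tip–soma distance.

    A run qualifies as an event when it spans >= ``min_steps`` intervals
    or changes the radial distance by >= ``min_net_um``.  Speed is the
    absolute net distance change over the run duration, in µm/min.
    """
    r = track.radial_distance()
    dr = np.diff(r)
    events: List[MotilityEvent] = []
    i = 0
    n = len(dr)
    while i < n:
        if dr[i] == 0:
            i += 1
            continue
        sign = np.sign(dr[i])
        j = i
        while j + 1 < n and np.sign(dr[j + 1]) == sign:
            j += 1
        steps = j - i + 1
        net = r[j + 1] - r[i]
        if steps >= min_steps or abs(net) >= min_net_um:
            minutes = steps * track.frame_interval_s / 60.0
            events.append(MotilityEvent(
                kind="extension" if sign > 0 else "retraction",
                start=i, stop=j + 1, net_um=float(net),
                speed_um_per_min=float(abs(net) / minutes),
            ))
        i = j + 1
    return events
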