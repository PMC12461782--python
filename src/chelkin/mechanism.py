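"""Ligand-binding event detection and exchange-mechanism classification.

Works on distance trajectories: metal-nitrogen distances for every amine
donor and metal-oxygen distances for every water. A donor is bound when
its distance is below the first-shell cutoff (3.4 A for Cd-N) and an
entry only counts as a binding event if the donor then resides in the
shell for at least a minimum residence time (20 ps), which filters
spurious re-crossings.

Each event is classified from the ordering of water departure relative
to nitrogen entry within a +/-20 ps window:

* dissociative — a first-shell water leaves before the nitrogen enters
  and the total first-shell coordination never exceeds its pre-event
  baseline;
* associative — the water is still inside when the nitrogen binds and
  leaves afterwards, producing a transient overcoordination above the
  baseline;
* ambiguous — neither signature fires (e.g. exchange within one frame).

For events with Cartesian coordinates the leaving water is tracked in a
frame with the metal at the origin and the entering nitrogen along +X;
its in-plane position and the N-metal-O angle quantify the exit
geometry (orthogonal exit shows up as angles near 90 degrees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DistanceTrajectory",
    "BindingEvent",
    "ExitGeometry",
    "coordination_series",
    "detect_binding_events",
    "classify_mechanism",
    "leaving_water_geometry",
    "mechanism_summary",
    "CUTOFF_NITROGEN",
    "CUTOFF_WATER",
    "MIN_RESIDENCE_PS",
]

#: first-shell metal-nitrogen cutoff, Angstrom (Cd(II)-amine)
CUTOFF_NITROGEN = 3.4
#: first-shell metal-water-oxygen cutoff, Angstrom (Cd(II); 2.9 for Ni(II))
CUTOFF_WATER = 3.2
#: minimum in-shell residence for a genuine binding event, ps
MIN_RESIDENCE_PS = 20.0


@dataclass
class DistanceTrajectory:
    """Per-frame metal-donor distances, optionally with coordinates.

    ``nitrogen_distances`` has shape (n_frames, n_nitrogens) and
    ``water_distances`` (n_frames, n_waters), both in Angstrom. The
    optional ``coords`` dict carries Cartesian positions: ``metal``
    (n_frames, 3), ``nitrogens`` (n_frames, n_nitrogens, 3), ``waters``
    (n_frames, n_waters, 3).
    """

    dt: float
    nitrogen_distances: np.ndarray
    water_distances: np.ndarray
    coords: dict | None = None

    def __post_init__(self) -> None:
        self.nitrogen_distances = np.atleast_2d(np.asarray(self.nitrogen_distances, float))
        self.water_distances = np.atleast_2d(np.asarray(self.water_distances, float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if (self.nitrogen_distances < 0).any() or (self.water_distances < 0).any():
            raise ValueError("distances must be non-negative")
        if self.nitrogen_distances.shape[0] != self.water_distances.shape[0]:
            raise ValueError("nitrogen and water tables disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.nitrogen_distances.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class BindingEvent:
    """A detected nitrogen-binding episode, annotated for classification."""

    frame: int
    time: float
    nitrogen_index: int
    transition: tuple[int, int]
    lig_window: np.ndarray
    wat_window: np.ndarray
    window_dt: float
    window_frames: int
    baseline: int | None = None
    label: str | None = None
    leaving_water: int | None = None
    water_exit_time: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ExitGeometry:
    """Leaving-water track in the metal-centred, nitrogen-aligned frame."""

    times: np.ndarray
    xy: np.ndarray
    angles: np.ndarray
    shell_radius: float

    def __post_init__(self) -> None:
        if ((self.angles < -1e-9) | (self.angles > 180.0 + 1e-9)).any():
            raise ValueError("angles must lie in [0, 180] degrees")


def coordination_series(distances: np.ndarray, cutoff: float) -> np.ndarray:
    """Sharp per-frame count of partners within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.atleast_2d(np.asarray(distances, float))
    return (d < cutoff).sum(axis=1).astype(np.int64)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_binding_events(
    traj: DistanceTrajectory,
    cutoff: float = CUTOFF_NITROGEN,
    min_residence: float = MIN_RESIDENCE_PS,
    cutoff_water: float = CUTOFF_WATER,
    window: float = MIN_RESIDENCE_PS,
) -> list[BindingEvent]:
    """Find genuine nitrogen-binding events in a distance trajectory.

    A bound interval shorter than ``min_residence`` is discarded as a
    spurious crossing; unbound gaps shorter than ``min_residence`` inside
    a bound stretch are bridged first, so brief re-crossings neither
    split nor create events. Each event records the coordination windows
    (+/- ``window`` ps) and its transition class (ligand coordination
    before -> after entry).
    """
    res_frames = max(1, int(round(min_residence / traj.dt)))
    if traj.n_frames < 2 * res_frames:
        raise ValueError("trajectory shorter than twice the residence time")
    win_frames = max(1, int(round(window / traj.dt)))
    lig_series = coordination_series(traj.nitrogen_distances, cutoff)
    wat_series = coordination_series(traj.water_distances, cutoff_water)
    events: list[BindingEvent] = []
    for j in range(traj.nitrogen_distances.shape[1]):
        bound = traj.nitrogen_distances[:, j] < cutoff
        # bridge sub-residence unbound gaps between bound stretches
        smoothed = bound.copy()
        for a, b in _runs(~bound):
            if b - a < res_frames and a > 0 and b < bound.size:
                smoothed[a:b] = True
        for a, b in _runs(smoothed):
            if b - a < res_frames:
                continue  # spurious dip
            lo = max(0, a - win_frames)
            hi = min(traj.n_frames, a + win_frames + 1)
            pre = lig_series[max(0, a - res_frames) : a]
            post = lig_series[a : min(traj.n_frames, a + res_frames)]
            n_before = int(np.bincount(pre).argmax()) if pre.size else 0
            n_after = int(np.bincount(post).argmax()) if post.size else n_before
            events.append(
                BindingEvent(
                    frame=int(a),
                    time=float(a * traj.dt),
                    nitrogen_index=j,
                    transition=(n_before, n_after),
                    lig_window=lig_series[lo:hi].copy(),
                    wat_window=wat_series[lo:hi].copy(),
                    window_dt=traj.dt,
                    window_frames=win_frames,
                )
            )
    events.sort(key=lambda e: e.frame)
    return events


def _leaving_water(
    traj: DistanceTrajectory, event: BindingEvent, cutoff_water: float, win: int
) -> tuple[int | None, float | None]:
    """Identify the leaving water: the first-shell water with the latest
    exit inside the window that is outside the shell at the window end."""
    a = event.frame
    lo, hi = a - win, a + win + 1
    d = traj.water_distances[lo:hi]
    inside = d < cutoff_water
    candidate, exit_rel = None, None
    for w in range(d.shape[1]):
        col = inside[:, w]
        if not col[0] or col[-1]:
            continue  # must start inside the shell and end outside
        last_in = int(np.flatnonzero(col).max())
        t_rel = (lo + last_in + 1 - a) * traj.dt  # first frame outside
        if exit_rel is None or t_rel > exit_rel:
            candidate, exit_rel = w, t_rel
    return candidate, exit_rel


def classify_mechanism(
    event: BindingEvent,
    traj: DistanceTrajectory,
    cutoff_water: float = CUTOFF_WATER,
    window: float = MIN_RESIDENCE_PS,
) -> BindingEvent | None:
    """Label one binding event associative/dissociative/ambiguous.

    The baseline is the mode of the summed (water + ligand) first-shell
    coordination over the pre-event window. Events whose window is
    truncated by the trajectory edge are skipped with a warning (returns
    None). The event is annotated in place and returned.
    """
    win = max(1, int(round(window / traj.dt)))
    a = event.frame
    if a - win < 0 or a + win + 1 > traj.n_frames:
        warnings.warn(
            f"binding event at frame {a} has a truncated +/-{window} ps window; skipped"
        )
        return None
    lig = coordination_series(traj.nitrogen_distances[a - win : a + win + 1], CUTOFF_NITROGEN)
    wat = coordination_series(traj.water_distances[a - win : a + win + 1], cutoff_water)
    total = lig + wat
    pre_total = total[:win]
    baseline = int(np.bincount(pre_total).argmax())
    event.baseline = baseline
    water_idx, exit_rel = _leaving_water(traj, event, cutoff_water, win)
    event.leaving_water = water_idx
    event.water_exit_time = exit_rel
    over = bool((total > baseline).any())
    if exit_rel is not None and exit_rel < 0 and not over:
        event.label = "dissociative"
    elif exit_rel is not None and exit_rel > 0 and over:
        event.label = "associative"
    else:
        event.label = "ambiguous"
    return event


def leaving_water_geometry(
    event: BindingEvent,
    traj: DistanceTrajectory,
    window: float = 5.0,
    shell_radius: float = CUTOFF_WATER,
) -> ExitGeometry:
    """Exit geometry of the leaving water around one event.

    For each frame in the +/-``window`` ps interval the rigid frame puts
    the metal at the origin and the entering nitrogen along +X; the
    leaving water is reduced to its (parallel, perpendicular) in-plane
    coordinates, so the point's norm equals the metal-oxygen distance
    and atan2 of the pair is the N-metal-O angle in [0, 180] degrees.
    """
    if traj.coords is None:
        raise ValueError("trajectory carries no Cartesian coordinates")
    if event.leaving_water is None:
        raise ValueError("event has no identified leaving water; classify it first")
    win = max(1, int(round(window / traj.dt)))
    a = event.frame
    lo, hi = max(0, a - win), min(traj.n_frames, a + win + 1)
    metal = traj.coords["metal"][lo:hi]
    nitro = traj.coords["nitrogens"][lo:hi, event.nitrogen_index]
    water = traj.coords["waters"][lo:hi, event.leaving_water]
    vn = nitro - metal
    norm_n = np.linalg.norm(vn, axis=1)
    if (norm_n < 1e-9).any():
        raise ValueError("degenerate geometry: entering nitrogen on top of the metal")
    xhat = vn / norm_n[:, None]
    w = water - metal
    x = np.einsum("ij,ij->i", w, xhat)
    perp = w - x[:, None] * xhat
    y = np.linalg.norm(perp, axis=1)
    angles = np.degrees(np.arctan2(y, x))
    times = (np.arange(lo, hi) - a) * traj.dt
    return ExitGeometry(
        times=times, xy=np.column_stack([x, y]), angles=angles, shell_radius=shell_radius
    )


def mechanism_summary(events: Sequence[BindingEvent]) -> pd.DataFrame:
    """Contingency of transition class x mechanism with binomial CIs.

    One row per observed transition class (e.g. "0->1"), with event
    counts per label, the dissociative fraction and its 95% Wilson
    interval. Classes without events are simply absent (never reported
    as 0/0).
    """
    labeled = [e for e in events if e.label is not None]
    if not labeled:
        raise ValueError("no classified events to summarize")
    rows = []
    classes = sorted({e.transition for e in labeled})
    for tr in classes:
        evs = [e for e in labeled if e.transition == tr]
        n = len(evs)
        counts = {
            lbl: sum(e.label == lbl for e in evs)
            for lbl in ("dissociative", "associative", "ambiguous")
        }
        frac = counts["dissociative"] / n
        lo, hi = _wilson_interval(counts["dissociative"], n)
        rows.append(
            {
                "transition": f"{tr[0]}->{tr[1]}",
                "n_events": n,
                **counts,
                "dissociative_fraction": frac,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def _wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    if n == 0:
        raise ValueError("no trials")
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)
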