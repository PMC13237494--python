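"""Gait measurements: stride curvature, duty factors, footfalls, stability.

Turning sharpness is quantified stride-by-stride with the signed Menger
curvature of the COM positions at three consecutive left-forelimb
touchdowns: kappa = 1/R with R the circumradius of the triple, positive
for counter-clockwise (left-turning) triples.  The stabilized curvature
kappa* of a run is the median over post-transient strides (the first
``n_discard`` post-ramp strides are dropped).

Duty factors (stance time / stride period) are computed per limb over
complete touchdown-to-touchdown cycles; turning asymmetry is summarised by
the inner/outer duty-factor ratios of the fore and hind pairs, with
"inner" resolved from the commanded turn direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .body_mechanics import LimbId

__all__ = [
    "StrideRecord",
    "GaitSummary",
    "debounce_events",
    "menger_curvature",
    "stride_curvatures",
    "duty_factors",
    "classify_stability",
    "footfall_diagram",
    "summarize",
]

#: curvature scale (1/cm) below which a run counts as straight; the
#: relative-spread convergence test is meaningless around zero curvature
CURVATURE_FLOOR = 5e-3

#: coefficient-of-variation threshold of the non-convergence check
CONVERGENCE_CV = 0.2

#: footfall diagram row order (hind before fore, right before left)
FOOTFALL_ROWS = ("RH", "LH", "RF", "LF")


@dataclass
class StrideRecord:
    index: int
    t_start: float
    t_end: float
    points: np.ndarray  # (3, 2) COM positions at the defining touchdowns
    curvature: float
    duration: float


@dataclass
class GaitSummary:
    kappa_star: float
    mean_speed: float
    duty: dict = field(default_factory=dict)
    fore_ratio: float = math.nan
    hind_ratio: float = math.nan
    stability: str = "unstable"
    failure_mode: Optional[str] = None
    n_strides: int = 0
    stride_period: float = math.nan

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def debounce_events(events: pd.DataFrame, window: float = 0.02) -> pd.DataFrame:
    """Collapse touchdown/liftoff bounces shorter than ``window`` seconds.

    The hybrid loop serializes one transition per step, so a limb grounded
    onto a spot that cannot bear load lifts again within a few integration
    steps while the correct limb re-grounds.  For gait statistics such a
    pair is a single functional transition: adjacent opposite-kind events
    of one limb closer than ``window`` are removed pairwise (iterating
    until stable), leaving the net stance/swing alternation.
    """
    keep = []
    for limb in sorted(events["limb"].unique()):
        ev = events[events["limb"] == limb].sort_values("t").reset_index()
        while len(ev) >= 2:
            # remove the tightest opposite-kind pair below the window first,
            # so a bounce nested next to a real transition resolves correctly
            best, best_gap = -1, window
            for i in range(len(ev) - 1):
                gap = ev.iloc[i + 1]["t"] - ev.iloc[i]["t"]
                opposite = ev.iloc[i]["kind"].startswith("liftoff") != ev.iloc[
                    i + 1
                ]["kind"].startswith("liftoff")
                if opposite and gap < best_gap:
                    best, best_gap = i, gap
            if best < 0:
                break
            ev = ev.drop(ev.index[[best, best + 1]]).reset_index(drop=True)
        keep.append(ev)
    out = pd.concat(keep, ignore_index=True) if keep else events.iloc[0:0]
    return out.sort_values("t").reset_index(drop=True)


def menger_curvature(p1, p2, p3) -> float:
    """Signed Menger curvature (1/cm) of three planar points.

    |kappa| = 4 * area(p1, p2, p3) / (|p1p2| |p2p3| |p1p3|); the sign is
    the orientation of the triple (counter-clockwise = left = positive).
    Collinear points give 0; coincident points are rejected.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.hypot(*(p2 - p1))
    b = np.hypot(*(p3 - p2))
    c = np.hypot(*(p3 - p1))
    if a == 0.0 or b == 0.0 or c == 0.0:
        raise ValueError("Menger curvature undefined for coincident points")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    return 2.0 * cross / (a * b * c)


def stride_curvatures(
    points: np.ndarray, n_discard: int = 10
) -> tuple[list[StrideRecord], float]:
    """Stride records from LF-touchdown stride points and the stabilized
    curvature kappa* (median after discarding the first ``n_discard``).

    ``points`` has rows (t, com_x, com_y), one per LF touchdown in the
    measurement window.

    Raises
    ------
    ValueError ("insufficient_strides") if fewer than ``n_discard + 3``
    touchdowns are available.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < n_discard + 3:
        raise ValueError("insufficient_strides")
    records = []
    for j in range(pts.shape[0] - 2):
        trip = pts[j:j + 3, 1:3]
        records.append(
            StrideRecord(
                index=j,
                t_start=pts[j, 0],
                t_end=pts[j + 2, 0],
                points=trip,
                curvature=menger_curvature(trip[0], trip[1], trip[2]),
                duration=pts[j + 2, 0] - pts[j, 0],
            )
        )
    kept = [r.curvature for r in records[n_discard:]]
    return records, float(np.median(kept))


def _phase_intervals(
    events: pd.DataFrame, limb: int, window: tuple[float, float]
) -> list[tuple[str, float, float]]:
    """(phase, start, end) intervals of one limb covering the window.

    The phase at the window start is reconstructed from the last event
    before it (default stance when no prior event exists).
    """
    t0, t1 = window
    ev = events[(events["limb"] == limb) & (events["t"] <= t1)].sort_values("t")
    before = ev[ev["t"] < t0]
    phase = "stance"
    if len(before) and before.iloc[-1]["kind"].startswith("liftoff"):
        phase = "swing"
    cur = t0
    intervals = []
    for _, e in ev[ev["t"] >= t0].iterrows():
        te = float(e["t"])
        if te > cur:
            intervals.append((phase, cur, te))
        phase = "swing" if e["kind"].startswith("liftoff") else "stance"
        cur = te
    if t1 > cur:
        intervals.append((phase, cur, t1))
    return intervals


def duty_factors(
    events: pd.DataFrame,
    window: tuple[float, float],
    turn: str = "left",
    min_cycles: int = 3,
) -> tuple[dict, float, float]:
    """Per-limb duty factors and the fore/hind inner-outer ratios.

    The duty factor is the fraction of the window a limb spends in
    stance, reconstructed from the event log.  Over whole stride cycles
    this equals the cycle-averaged stance/stride ratio, and it remains
    well defined when turning produces very short stances or the hybrid
    loop emits bounce events.  ``inner`` is the left side for a left
    turn.  Raises if any limb shows fewer than ``min_cycles`` touchdowns
    inside the window.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty duty-factor window")
    duty = {}
    for limb in LimbId:
        ev = events[(events["limb"] == int(limb))
                    & (events["t"] >= t0) & (events["t"] <= t1)]
        n_td = int((ev["kind"] == "touchdown").sum())
        if n_td < min_cycles:
            raise ValueError(
                f"limb {limb.name}: only {n_td} touchdowns in window"
            )
        intervals = _phase_intervals(events, int(limb), window)
        stance = sum(b - a for ph, a, b in intervals if ph == "stance")
        duty[limb.name] = stance / (t1 - t0)
    if turn == "left":
        fore_ratio = duty["LF"] / duty["RF"]
        hind_ratio = duty["LH"] / duty["RH"]
    else:
        fore_ratio = duty["RF"] / duty["LF"]
        hind_ratio = duty["RH"] / duty["LH"]
    return duty, fore_ratio, hind_ratio


def footfall_diagram(
    events: pd.DataFrame, window: tuple[float, float]
) -> tuple[pd.DataFrame, float]:
    """Stance/swing interval table (rows ordered RH, LH, RF, LF) and the
    swing-overlap fraction of the left hind/fore pair.

    Each table row holds limb, phase, t_start, t_end.  The overlap
    fraction is the time both LH and LF are simultaneously in swing,
    relative to the window duration.
    """
    t0, t1 = window
    rows = []
    swing_masks = {}
    for name in FOOTFALL_ROWS:
        intervals = _phase_intervals(events, int(LimbId[name]), window)
        swing_masks[name] = [(a, b) for ph, a, b in intervals if ph == "swing"]
        for ph, a, b in intervals:
            rows.append({"limb": name, "phase": ph, "t_start": a, "t_end": b})
    table = pd.DataFrame(rows, columns=["limb", "phase", "t_start", "t_end"])
    overlap = 0.0
    for a0, a1 in swing_masks.get("LH", []):
        for b0, b1 in swing_masks.get("LF", []):
            overlap += max(0.0, min(a1, b1) - max(a0, b0))
    frac = overlap / (t1 - t0) if t1 > t0 else 0.0
    return table, frac


def classify_stability(
    status: str, curvatures: Optional[Sequence[float]] = None
) -> tuple[str, Optional[str]]:
    """Binary stable/unstable call plus the failure mode.

    A run is unstable if the simulation terminated abnormally
    (support_lost, com_escape, height_collapse, no_gait,
    insufficient_strides, event_overflow) or if the post-transient stride
    curvatures did not converge: standard deviation above
    max(CONVERGENCE_CV * |median|, CURVATURE_FLOOR).
    """
    if status != "completed":
        return "unstable", status
    if curvatures is not None and len(curvatures) >= 2:
        arr = np.asarray(list(curvatures), dtype=float)
        med = abs(float(np.median(arr)))
        if float(np.std(arr)) > max(CONVERGENCE_CV * med, CURVATURE_FLOOR):
            return "unstable", "non_convergent"
    return "stable", None


def summarize(result, min_cycles: int = 3) -> GaitSummary:
    """Full gait summary of a :class:`~quadturn.dynamics.SimResult`."""
    cfg = result.config
    if result.status != "completed":
        stab, mode = classify_stability(result.status)
        return GaitSummary(math.nan, math.nan, stability=stab, failure_mode=mode)
    pts = result.measured_points
    records, kappa_star = stride_curvatures(pts, n_discard=cfg.n_discard)
    kept = [r.curvature for r in records[cfg.n_discard:]]
    stab, mode = classify_stability(result.status, kept)
    window = (pts[0, 0], pts[-1, 0])
    chords = np.hypot(np.diff(pts[:, 1]), np.diff(pts[:, 2]))
    speed = float(chords.sum() / (window[1] - window[0]))
    periods = np.diff(pts[:, 0])
    try:
        duty, fore_ratio, hind_ratio = duty_factors(
            result.events, window, cfg.strategy.turn, min_cycles
        )
    except ValueError:
        duty, fore_ratio, hind_ratio = {}, math.nan, math.nan
    return GaitSummary(
        kappa_star=kappa_star,
        mean_speed=speed,
        duty=duty,
        fore_ratio=fore_ratio,
        hind_ratio=hind_ratio,
        stability=stab,
        failure_mode=mode,
        n_strides=len(kept),
        stride_period=float(np.mean(periods)),
    )
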