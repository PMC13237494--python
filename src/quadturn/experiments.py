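"""Sweep drivers: stability/curvature heatmaps and envelope analyses.

The study-level experiments sweep the propulsion force (which regulates
walking speed) against the intensity of a turning strategy, optionally
across several axial-shift values, and summarise each cell by the
measured mean speed, the stabilized stride curvature kappa*, and a
stable/unstable call.  Envelope analyses bin stable runs by measured
speed (1 cm/s bins by default) and keep the per-bin maximum curvature
toward the commanded turn; saturation/peak locations over the axial-shift
grid and per-strategy speed-optimized envelopes are derived from those
curves.  All sweeps are brute force and fully deterministic: rerunning a
grid reproduces every cell bit-for-bit, and cells are independent.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import SimConfig, simulate
from .gait_analysis import summarize
from .turning_strategies import (
    STRATEGY_KINDS,
    CombinedStrategySpec,
    make_strategy,
)

__all__ = [
    "SweepGrid",
    "HeatmapResult",
    "EnvelopeCurve",
    "DEFAULT_F0_GRID",
    "DEFAULT_INTENSITY_GRIDS",
    "run_cell",
    "run_heatmap",
    "envelope_vs_velocity",
    "saturation_shift",
    "peak_shift",
    "combined_envelope",
    "strategy_comparison",
    "crossover_velocities",
]

#: propulsion forces (dyn) spanning walking speeds of roughly 6-45 cm/s
DEFAULT_F0_GRID = (200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0,
                   1000.0, 1200.0, 1500.0)

#: desk-scale intensity grids per strategy (units: rad, dyn, cm)
DEFAULT_INTENSITY_GRIDS = {
    "bending": tuple(np.round(np.linspace(0.125, 1.0, 8), 4)),
    "lateral_force": tuple(np.round(np.linspace(62.5, 500.0, 8), 2)),
    "lateral_shift": tuple(np.round(np.linspace(0.1, 0.8, 8), 3)),
}

#: axial-shift grids used by the envelope analyses (cm)
DEFAULT_AXIAL_GRIDS = {
    "bending": (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
    "lateral_force": (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
    "lateral_shift": (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
}

CELL_COLUMNS = [
    "strategy", "F0", "intensity", "axial_shift", "s_weight", "t",
    "speed", "kappa", "stable", "failure_mode",
]


@dataclass(frozen=True)
class SweepGrid:
    """Axes of a heatmap sweep; grids must be non-empty and increasing."""

    F0: Sequence[float] = DEFAULT_F0_GRID
    intensity: Sequence[float] = ()
    axial_shift: Sequence[float] = (0.0,)

    def __post_init__(self) -> None:
        for name in ("F0", "intensity", "axial_shift"):
            vals = list(getattr(self, name))
            if name != "intensity" and not vals:
                raise ValueError(f"grid {name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"grid {name} must be strictly increasing")


@dataclass
class HeatmapResult:
    strategy: str
    cells: pd.DataFrame
    grid: SweepGrid


@dataclass
class EnvelopeCurve:
    """Per-velocity-bin maximum stable curvature toward the turn."""

    bins: np.ndarray        # bin centers (cm/s)
    kappa: np.ndarray       # max stable curvature per bin (1/cm)
    meta: pd.DataFrame      # arg-max rows (full cell records)

    def value_at(self, b: float) -> float:
        hit = np.flatnonzero(np.isclose(self.bins, b))
        return float(self.kappa[hit[0]]) if hit.size else math.nan


def _cell_key(cfg: SimConfig) -> str:
    s = cfg.strategy
    blob = json.dumps([
        cfg.params.L, cfg.params.H, cfg.params.h, cfg.params.D, cfg.params.m,
        cfg.params.lam, cfg.params.grav, cfg.F0, s.delta, s.f_lat, s.s_shift,
        s.a_shift, s.turn, cfg.dt, cfg.t_max, cfg.n_ramp, cfg.n_discard,
        cfg.n_keep,
    ])
    return hashlib.sha1(blob.encode()).hexdigest()


def run_cell(config: SimConfig, cache_dir: Optional[Path] = None) -> dict:
    """One sweep cell: simulate, summarise, return a flat record.

    With ``cache_dir`` set, results are cached on disk keyed by a hash of
    the configuration; cached and fresh results agree exactly.
    """
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        path = cache_dir / f"{_cell_key(config)}.json"
        if path.exists():
            return json.loads(path.read_text())
    res = simulate(replace(config, record_every=0))
    summ = summarize(res)
    rec = {
        "speed": None if math.isnan(summ.mean_speed) else summ.mean_speed,
        "kappa": None if math.isnan(summ.kappa_star) else summ.kappa_star,
        "stable": summ.stable,
        "failure_mode": summ.failure_mode,
    }
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(rec))
    return rec


def run_heatmap(
    kind: str,
    grid: SweepGrid,
    axial_shift: float = 0.0,
    turn: str = "left",
    base_config: Optional[SimConfig] = None,
    cache_dir: Optional[Path] = None,
    progress: bool = False,
) -> HeatmapResult:
    """Speed-intensity map of one strategy at a fixed axial shift.

    Unstable cells carry no curvature value; individual cell failures are
    recorded, never raised.
    """
    if kind not in STRATEGY_KINDS:
        raise ValueError(f"unknown strategy kind {kind!r}")
    base = base_config or SimConfig()
    rows = []
    cells = [(F0, m) for F0 in grid.F0 for m in grid.intensity]
    it = cells
    if progress:
        from tqdm import tqdm

        it = tqdm(cells, desc=f"{kind} a={axial_shift}")
    for F0, mag in it:
        strategy = make_strategy(kind, mag, a_shift=axial_shift, turn=turn)
        cfg = replace(base, F0=F0, strategy=strategy)
        rec = run_cell(cfg, cache_dir)
        rows.append({
            "strategy": kind, "F0": F0, "intensity": mag,
            "axial_shift": axial_shift, "s_weight": None, "t": None,
            **rec,
        })
    return HeatmapResult(kind, pd.DataFrame(rows, columns=CELL_COLUMNS), grid)


def _envelope_from_cells(
    cells: pd.DataFrame, turn_sign: int = 1, bin_width: float = 1.0
) -> EnvelopeCurve:
    """Bin stable cells by measured speed; keep the max curvature toward
    the commanded turn per bin.  Bins with no stable run are omitted."""
    # reset the index: concatenated heatmap frames carry duplicate labels,
    # which would corrupt the groupby/idxmax row lookup below
    ok = cells[cells["stable"].fillna(False)].reset_index(drop=True).copy()
    ok = ok.dropna(subset=["speed", "kappa"])
    if not len(ok):
        return EnvelopeCurve(np.empty(0), np.empty(0), ok)
    ok["signed"] = turn_sign * ok["kappa"]
    ok["bin"] = (ok["speed"] / bin_width).apply(math.floor) * bin_width + bin_width / 2
    idx = ok.groupby("bin")["signed"].idxmax()
    best = ok.loc[idx].sort_values("bin")
    return EnvelopeCurve(
        bins=best["bin"].to_numpy(float),
        kappa=best["signed"].to_numpy(float),
        meta=best.reset_index(drop=True),
    )


def envelope_vs_velocity(
    kind: str,
    axial_shifts: Sequence[float],
    grid: SweepGrid,
    turn: str = "left",
    bin_width: float = 1.0,
    base_config: Optional[SimConfig] = None,
    cache_dir: Optional[Path] = None,
    progress: bool = False,
) -> dict[float, EnvelopeCurve]:
    """Max-curvature-vs-velocity envelope per axial-shift value."""
    sign = 1 if turn == "left" else -1
    out = {}
    for a in axial_shifts:
        hm = run_heatmap(kind, grid, a, turn, base_config, cache_dir, progress)
        out[a] = _envelope_from_cells(hm.cells, sign, bin_width)
    return out


#: absolute envelope-comparison floor (1/cm): differences below the
#: package's curvature resolution do not count as improvement
KAPPA_ABS_TOL = 5e-3


def saturation_shift(
    envelopes: dict[float, EnvelopeCurve],
    rel_tol: float = 0.05,
    abs_tol: float = KAPPA_ABS_TOL,
) -> float:
    """Axial shift beyond which no further improvement in the maximal
    achievable curvature is observed.

    Returns the smallest shift whose envelope maximum is not exceeded by
    any larger shift's envelope maximum by more than ``rel_tol``
    (relative) and ``abs_tol`` (absolute).  The envelope maximum is the
    robust summary of the per-shift curves: individual velocity bins of a
    desk-scale sweep are populated by few cells and fluctuate too much
    for bin-wise comparison.
    """
    shifts = sorted(envelopes)
    maxima = {
        a: (float(env.kappa.max()) if len(env.kappa) else -math.inf)
        for a, env in envelopes.items()
    }
    for i, a in enumerate(shifts):
        later = [maxima[b] for b in shifts[i + 1:]]
        if not later:
            return a
        ceiling = maxima[a] + max(rel_tol * abs(maxima[a]), abs_tol)
        if max(later) <= ceiling:
            return a
    return shifts[-1]


def peak_shift(envelopes: dict[float, EnvelopeCurve]) -> float:
    """Axial shift whose envelope attains the highest global maximum."""
    best_a, best_v = None, -math.inf
    for a, env in envelopes.items():
        if len(env.kappa) and env.kappa.max() > best_v:
            best_v = float(env.kappa.max())
            best_a = a
    if best_a is None:
        raise ValueError("no stable runs in any envelope")
    return best_a


def combined_envelope(
    pair: tuple[str, str],
    maxima: tuple[float, float],
    F0_values: Sequence[float],
    s_weights: Sequence[float] = tuple(np.round(np.linspace(0, 1, 11), 2)),
    t_values: Sequence[float] = tuple(np.round(np.linspace(0.125, 1.0, 8), 4)),
    axial_shifts: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
    turn: str = "left",
    bin_width: float = 1.0,
    base_config: Optional[SimConfig] = None,
    cache_dir: Optional[Path] = None,
    progress: bool = False,
) -> tuple[dict[float, EnvelopeCurve], EnvelopeCurve, pd.DataFrame]:
    """Pairwise strategy combination sweep.

    For each relative weight ``s`` the two magnitudes are
    ``t*s*max1`` and ``t*(1-s)*max2``; ``t``, the propulsion force and the
    axial shift are swept and each velocity bin keeps the best stable
    curvature.  Returns (per-s curves, upper envelope, all cell records).
    """
    base = base_config or SimConfig()
    sign = 1 if turn == "left" else -1
    all_rows = []
    curves = {}
    combos = [(s, t, F0, a) for s in s_weights for t in t_values
              for F0 in F0_values for a in axial_shifts]
    it = combos
    if progress:
        from tqdm import tqdm

        it = tqdm(combos, desc=f"combined {pair[0]}+{pair[1]}")
    for s, t, F0, a in it:
        spec = CombinedStrategySpec(pair, s, t, *maxima)
        strategy = make_strategy(spec, a_shift=a, turn=turn)
        try:
            strategy.validate(base.params)
        except ValueError:
            continue  # magnitude out of admissible range (e.g. s_shift >= h)
        cfg = replace(base, F0=F0, strategy=strategy)
        rec = run_cell(cfg, cache_dir)
        all_rows.append({
            "strategy": f"{pair[0]}+{pair[1]}", "F0": F0,
            "intensity": None, "axial_shift": a, "s_weight": s, "t": t,
            **rec,
        })
    cells = pd.DataFrame(all_rows, columns=CELL_COLUMNS)
    for s in s_weights:
        curves[s] = _envelope_from_cells(
            cells[cells["s_weight"] == s], sign, bin_width
        )
    upper = _envelope_from_cells(cells, sign, bin_width)
    return curves, upper, cells


def strategy_comparison(
    grids: Optional[dict[str, SweepGrid]] = None,
    axial_grids: Optional[dict[str, Sequence[float]]] = None,
    turn: str = "left",
    bin_width: float = 1.0,
    base_config: Optional[SimConfig] = None,
    cache_dir: Optional[Path] = None,
    progress: bool = False,
) -> dict[str, EnvelopeCurve]:
    """Per-strategy speed-optimized envelopes (axial shift optimized per
    velocity bin), on a shared velocity axis."""
    sign = 1 if turn == "left" else -1
    out = {}
    for kind in STRATEGY_KINDS:
        grid = (grids or {}).get(kind) or SweepGrid(
            intensity=DEFAULT_INTENSITY_GRIDS[kind]
        )
        shifts = (axial_grids or DEFAULT_AXIAL_GRIDS)[kind]
        cells = []
        for a in shifts:
            hm = run_heatmap(kind, grid, a, turn, base_config, cache_dir, progress)
            cells.append(hm.cells)
        out[kind] = _envelope_from_cells(pd.concat(cells), sign, bin_width)
    return out


# ---------------------------------------------------------------------------
# Desk-scale reproduction studies.  These grids are the package's declared
# study conditions: propulsion forces spanning walking speeds ~4-45 cm/s,
# 10 intensity levels per strategy over the ranges the single-strategy maps
# use, and the axial-shift grids of the envelope analyses.
# ---------------------------------------------------------------------------

STUDY_F0_GRID = (150.0, 175.0, 200.0, 225.0, 250.0, 275.0, 300.0, 350.0,
                 400.0, 500.0, 600.0, 700.0, 800.0, 1000.0, 1200.0, 1500.0)

STUDY_INTENSITY_GRIDS = {
    "bending": tuple(np.round(np.linspace(0.1, 1.0, 10), 3)),
    "lateral_force": tuple(np.round(np.linspace(50.0, 500.0, 10), 1)),
    "lateral_shift": tuple(np.round(np.linspace(0.09, 0.9, 10), 3)),
}

#: combined-sweep maxima: 2 rad bending, 500 dyn lateral force, 1 cm shift
COMBINED_MAXIMA = {"bending": 2.0, "lateral_force": 500.0, "lateral_shift": 1.0}

STUDY_COMBINED_F0_GRID = (150.0, 200.0, 250.0, 300.0, 400.0, 500.0, 600.0,
                          800.0, 1000.0, 1200.0)


def single_strategy_cells(
    kind: str,
    cache_dir: Optional[Path] = None,
    progress: bool = False,
) -> dict[float, pd.DataFrame]:
    """All heatmap cells of one strategy across its axial-shift grid, at
    the desk-scale study resolution."""
    grid = SweepGrid(F0=STUDY_F0_GRID, intensity=STUDY_INTENSITY_GRIDS[kind])
    return {
        a: run_heatmap(kind, grid, a, cache_dir=cache_dir, progress=progress).cells
        for a in DEFAULT_AXIAL_GRIDS[kind]
    }


def axial_shift_study(
    cells_by_kind: dict[str, dict[float, pd.DataFrame]],
    saturation_bin_width: float = 2.0,
) -> dict:
    """Axial-shift saturation/peak locations and the speed crossovers.

    Returns a dict with the saturation shifts of bending and lateral
    force, the peak shift of lateral shift, and the two crossover
    velocities of the speed-optimized strategy comparison.
    """
    env2 = {
        kind: {a: _envelope_from_cells(c, 1, saturation_bin_width)
               for a, c in by_shift.items()}
        for kind, by_shift in cells_by_kind.items()
    }
    comp = {
        kind: _envelope_from_cells(pd.concat(list(by_shift.values())), 1, 1.0)
        for kind, by_shift in cells_by_kind.items()
    }
    v_bend, v_shift = crossover_velocities(comp)
    return {
        "bending_saturation_cm": saturation_shift(env2["bending"]),
        "lateral_force_saturation_cm": saturation_shift(env2["lateral_force"]),
        "lateral_shift_peak_cm": peak_shift(env2["lateral_shift"]),
        "bending_best_below_cm_s": v_bend,
        "lateral_shift_best_above_cm_s": v_shift,
        "envelopes": env2,
        "comparison": comp,
    }


def combined_bending_force_study(
    cache_dir: Optional[Path] = None,
    progress: bool = False,
) -> dict:
    """Brute-force bending + lateral-force combination sweep.

    Eleven relative weights, eight overall magnitudes, the combined
    propulsion grid and four axial shifts; reports the maximum stable
    stabilized curvature found and the per-weight envelope curves.
    """
    pair = ("bending", "lateral_force")
    maxima = (COMBINED_MAXIMA[pair[0]], COMBINED_MAXIMA[pair[1]])
    curves, upper, cells = combined_envelope(
        pair, maxima, STUDY_COMBINED_F0_GRID,
        cache_dir=cache_dir, progress=progress,
    )
    max_kappa = float(upper.kappa.max()) if len(upper.kappa) else math.nan
    return {
        "max_kappa": max_kappa,
        "n_cells": len(cells),
        "curves": curves,
        "upper": upper,
        "cells": cells,
    }


def crossover_velocities(
    envelopes: dict[str, EnvelopeCurve],
    eps: float = KAPPA_ABS_TOL,
) -> tuple[float, float]:
    """Speed-dependency summary of the three strategies.

    Returns ``(v_bend, v_shift)``: the highest velocity bin in which body
    bending's envelope is greatest, and the lowest bin from which lateral
    shift's envelope is greatest for all higher bins with any stable run.
    "Greatest" tolerates deficits up to ``eps`` (the curvature measurement
    resolution): envelope values in a desk-scale sweep are per-bin maxima
    over few cells, so sub-resolution differences are ties, not rankings.
    ``v_bend`` is ``-inf`` when bending is nowhere the greatest;
    ``v_shift`` is ``inf`` when no dominant tail exists.
    """

    def greatest(kind, vals):
        if kind not in vals:
            return False
        rivals = [v for k, v in vals.items() if k != kind]
        return not rivals or vals[kind] >= max(rivals) - eps

    bins = sorted({float(b) for env in envelopes.values() for b in env.bins})
    v_bend = -math.inf
    shift_best_from = math.inf
    for b in reversed(bins):
        vals = {k: env.value_at(b) for k, env in envelopes.items()}
        vals = {k: v for k, v in vals.items() if not math.isnan(v)}
        if not vals:
            continue
        if greatest("lateral_shift", vals):
            shift_best_from = b
        else:
            break
    for b in bins:
        vals = {k: env.value_at(b) for k, env in envelopes.items()}
        vals = {k: v for k, v in vals.items() if not math.isnan(v)}
        if greatest("bending", vals):
            v_bend = max(v_bend, b)
    return v_bend, shift_best_from
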