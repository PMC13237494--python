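"""Rhythm-generator state machines and sensory phase-transition rules.

Each limb is driven by a two-state rhythm generator (stance/swing) whose
transitions are triggered by proprioceptive feedback rather than by an
internal oscillator:

* **stance -> swing (liftoff)** when the limb's vertical load drops to
  zero or below (unloading), or when the paw's displacement from its
  touchdown reference in body coordinates exceeds the limit ``D_eff``
  (extension).  Unloading takes precedence when both hold in one step.
* **swing -> stance (touchdown)** when the total vertical load G_tot
  starts to decrease (backward difference below ``-eps_G``), signalling
  that the current support is becoming unsustainable.  The limb that has
  been swinging the longest is grounded (ties broken by limb order
  LF, RF, LH, RH).

Touchdown placement: the paw lands at its current strategy-modified target
(bending and lateral shift applied) moved posteriorly by the axial shift
along the body's longitudinal axis.  The axial shift also reduces the
forelimb displacement limit to ``D - a`` to preserve fore-hind timing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .body_mechanics import (
    BodyParams,
    BodyState,
    LimbId,
    PawState,
    attachment_points,
    body_to_world,
)
from .turning_strategies import StrategyParams

__all__ = [
    "RhythmGeneratorState",
    "TransitionEvent",
    "EPS_G_REL",
    "check_stance_to_swing",
    "check_swing_to_stance",
    "select_touchdown_limb",
    "place_paw_at_touchdown",
    "effective_displacement_limit",
]

#: tolerance on the per-step G_tot decrease, relative to body weight
EPS_G_REL = 1e-6

LIFTOFF_NONE = -1
LIFTOFF_UNLOAD = 0
LIFTOFF_EXTENSION = 1
TOUCHDOWN = 2

KIND_NAMES = {
    LIFTOFF_UNLOAD: "liftoff_unload",
    LIFTOFF_EXTENSION: "liftoff_extension",
    TOUCHDOWN: "touchdown",
}


@dataclass
class TransitionEvent:
    time: float
    limb: LimbId
    kind: str
    position: np.ndarray


@dataclass
class RhythmGeneratorState:
    """Phases and phase-start times of the four generators."""

    phases: list = None
    phase_start: np.ndarray = None

    def __post_init__(self):
        if self.phases is None:
            self.phases = ["stance"] * 4
        if self.phase_start is None:
            self.phase_start = np.zeros(4)


@njit(cache=True)
def liftoff_kind(load, dr_norm, d_eff):
    """Liftoff decision for one stance limb: -1 none, 0 unload, 1 extension."""
    if load <= 0.0:
        return 0
    if dr_norm > d_eff:
        return 1
    return -1


@njit(cache=True)
def touchdown_trigger(gtot_prev, gtot_now, eps_g):
    """True when the one-step backward difference of G_tot is below -eps_g."""
    return gtot_now - gtot_prev < -eps_g


@njit(cache=True)
def longest_swing_limb(in_swing, phase_start):
    """Index of the longest-swinging limb; ties go to the lower limb index."""
    best = -1
    best_t = 0.0
    for i in range(4):
        if in_swing[i]:
            if best == -1 or phase_start[i] < best_t:
                best = i
                best_t = phase_start[i]
    return best


def effective_displacement_limit(limb: LimbId, params: BodyParams, a_shift: float) -> float:
    """D for hindlimbs, D - a_shift for forelimbs."""
    return params.D - a_shift if limb.is_fore else params.D


def check_stance_to_swing(
    paw: PawState,
    load: float,
    d_eff: float,
    body_pos: np.ndarray,
) -> Optional[str]:
    """Liftoff event kind for a stance paw, or None.

    ``body_pos`` is the paw's current body-frame position; displacement is
    measured from ``touchdown_ref``.  Unloading takes precedence over the
    extension limit.
    """
    dr = float(np.hypot(*(np.asarray(body_pos) - paw.touchdown_ref)))
    kind = liftoff_kind(load, dr, d_eff)
    return KIND_NAMES.get(kind)


def check_swing_to_stance(
    total_load_history: Sequence[float],
    params: BodyParams,
    any_swing: bool = True,
    eps_rel: float = EPS_G_REL,
) -> bool:
    """Touchdown trigger from the recent G_tot samples (needs >= 2)."""
    if not any_swing or len(total_load_history) < 2:
        return False
    eps = eps_rel * params.weight
    return bool(
        touchdown_trigger(total_load_history[-2], total_load_history[-1], eps)
    )


def select_touchdown_limb(rg: RhythmGeneratorState) -> LimbId:
    """The limb that has been swinging for the longest time."""
    in_swing = np.array([p == "swing" for p in rg.phases])
    idx = longest_swing_limb(in_swing, rg.phase_start)
    if idx < 0:
        raise ValueError("no limb in swing")
    return LimbId(idx + 1)


@njit(cache=True)
def touchdown_target(attach, limb_idx, a_shift):
    """Body-frame touchdown target: the strategy-modified attachment moved
    posteriorly by the axial shift along the body's longitudinal axis."""
    tx = attach[limb_idx, 0] - a_shift
    ty = attach[limb_idx, 1]
    return tx, ty


def place_paw_at_touchdown(
    limb: LimbId,
    state: BodyState,
    strategy: StrategyParams,
    params: BodyParams,
) -> tuple[np.ndarray, np.ndarray]:
    """World contact point and body-frame touchdown reference for a landing.

    The target is the strategy-modified attachment (bending + lateral
    shift) shifted posteriorly by ``a_shift`` along the body's longitudinal
    axis; the contact is its world image under the current body pose.
    """
    attach = attachment_points(
        params.L, params.h, strategy.delta, strategy.s_shift, strategy.turn_sign
    )
    tx, ty = touchdown_target(attach, limb.index, strategy.a_shift)
    target = np.array([tx, ty])
    return body_to_world(state, target), target
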