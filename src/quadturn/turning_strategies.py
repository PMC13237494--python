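"""The three turning asymmetries, axial-shift stride control, and combinations.

Turning is produced by breaking left-right symmetry in one of three ways:

* **body bending** -- an angular deviation ``delta`` between the shoulder
  and hip girdles, implemented as a ``delta/2`` counter-rotation of the
  fore and hind attachment pairs about the COM (fore pair toward the turn);
* **lateral force** -- an extra force of magnitude ``f_lat`` perpendicular
  to the body axis, toward the turn centre, applied to each grounded
  forelimb only;
* **lateral shift** -- touchdown targets of the inner limbs moved to
  lateral offset ``h - s`` and of the outer limbs to ``h + s``.

Independently of the strategy, the **axial shift** ``a`` moves every
touchdown target posteriorly by ``a`` along the (local) body axis and
reduces the forelimb displacement limit to ``D - a``.

Pairs of strategies are combined through a relative weight ``s_weight``
and an overall magnitude ``t``: the first member has magnitude
``t * s_weight * max1`` and the second ``t * (1 - s_weight) * max2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .body_mechanics import BodyParams, BodyState, PawState, StrategyGeometry

__all__ = [
    "StrategyParams",
    "CombinedStrategySpec",
    "STRATEGY_KINDS",
    "resolve_geometry",
    "lateral_force_vectors",
    "combined_magnitudes",
    "make_strategy",
]

STRATEGY_KINDS = ("bending", "lateral_force", "lateral_shift")


@dataclass(frozen=True)
class StrategyParams:
    """Magnitudes of the turning asymmetries plus stride control.

    All magnitudes are >= 0; handedness comes from ``turn`` alone.
    """

    delta: float = 0.0        # bending angle (rad)
    f_lat: float = 0.0        # lateral force magnitude (dyn)
    s_shift: float = 0.0      # lateral shift (cm)
    a_shift: float = 0.0      # axial (posterior) shift (cm)
    turn: str = "left"        # "left" | "right"

    @property
    def turn_sign(self) -> int:
        return 1 if self.turn == "left" else -1

    def validate(self, params: BodyParams) -> "StrategyParams":
        if self.turn not in ("left", "right"):
            raise ValueError("turn must be 'left' or 'right'")
        for name in ("delta", "f_lat", "s_shift", "a_shift"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"strategy magnitude {name} must be >= 0")
        if self.s_shift >= params.h:
            raise ValueError(
                f"lateral shift {self.s_shift} cm must stay below half-width h={params.h}"
            )
        if self.a_shift >= params.D:
            raise ValueError(
                f"axial shift {self.a_shift} cm must stay below displacement limit D={params.D}"
            )
        return self

    def mirrored(self) -> "StrategyParams":
        """Same magnitudes, opposite turn direction."""
        return replace(self, turn="right" if self.turn == "left" else "left")


@dataclass(frozen=True)
class CombinedStrategySpec:
    """Pairwise combination of two strategies.

    ``pair`` holds two distinct members of :data:`STRATEGY_KINDS`;
    ``max1``/``max2`` are the per-strategy maxima the weights scale.
    """

    pair: tuple[str, str]
    s_weight: float
    t: float
    max1: float
    max2: float

    def __post_init__(self) -> None:
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ValueError("pair must name two distinct strategies")
        for kind in self.pair:
            if kind not in STRATEGY_KINDS:
                raise ValueError(f"unknown strategy kind {kind!r}")
        if not (0.0 <= self.s_weight <= 1.0 and 0.0 <= self.t <= 1.0):
            raise ValueError("s_weight and t must lie in [0, 1]")


def combined_magnitudes(spec: CombinedStrategySpec) -> tuple[float, float]:
    """Magnitudes (t*s_weight*max1, t*(1-s_weight)*max2) of the pair."""
    return spec.t * spec.s_weight * spec.max1, spec.t * (1.0 - spec.s_weight) * spec.max2


def make_strategy(
    kind_or_spec,
    magnitude: float | None = None,
    a_shift: float = 0.0,
    turn: str = "left",
) -> StrategyParams:
    """Build :class:`StrategyParams` from a single kind + magnitude or a
    :class:`CombinedStrategySpec`."""
    kw = {"a_shift": a_shift, "turn": turn}
    field_of = {"bending": "delta", "lateral_force": "f_lat", "lateral_shift": "s_shift"}
    if isinstance(kind_or_spec, CombinedStrategySpec):
        m1, m2 = combined_magnitudes(kind_or_spec)
        kw[field_of[kind_or_spec.pair[0]]] = m1
        kw[field_of[kind_or_spec.pair[1]]] = m2
        return StrategyParams(**kw)
    if magnitude is None:
        raise ValueError("magnitude required for a single-strategy spec")
    kw[field_of[kind_or_spec]] = magnitude
    return StrategyParams(**kw)


def resolve_geometry(strategy: StrategyParams, params: BodyParams) -> StrategyGeometry:
    """Attachment-geometry record consumed by ``nominal_attachments``.

    Validates the strategy bounds first; violations raise before any
    simulation starts.
    """
    strategy.validate(params)
    return StrategyGeometry(
        delta=strategy.delta, s_shift=strategy.s_shift, turn_sign=strategy.turn_sign
    )


def lateral_force_vectors(
    strategy: StrategyParams, state: BodyState, paws: list[PawState]
) -> np.ndarray:
    """Per-limb steering-force additions (4x2, dyn, world frame).

    Each grounded forelimb receives a vector of magnitude ``f_lat``
    perpendicular to the body axis pointing toward the turn centre
    (leftward for a left turn); hindlimbs and swing limbs receive zero.
    """
    out = np.zeros((4, 2))
    if strategy.f_lat == 0.0:
        return out
    # body +y axis in world coordinates, times the turn sign
    ny = strategy.turn_sign
    direction = np.array(
        [-math.sin(state.theta) * ny, math.cos(state.theta) * ny]
    )
    for paw in paws:
        if paw.limb.is_fore and paw.in_stance:
            out[paw.limb.index] = strategy.f_lat * direction
    return out
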