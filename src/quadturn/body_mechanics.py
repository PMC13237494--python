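"""Rigid-rod body geometry, frames, and support-polygon queries.

The body is a uniform rigid rod of length ``L`` carried parallel to the
ground at nominal height ``H``.  Limbs attach to a rectangular frame of
half-width ``h``: the forelimbs at the front corners ``(L/2, +-h)`` and the
hindlimbs level with the centre of mass at ``(0, +-h)``.  The body frame is
COM-centred with x pointing forward along the rod and y pointing to the
animal's left; the world frame is ground-fixed.  All lengths are cm, masses
g, times s, forces dyn (CGS).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from shapely.geometry import MultiPoint, Point

__all__ = [
    "BodyParams",
    "LimbId",
    "BodyState",
    "PawState",
    "StrategyGeometry",
    "SupportPolygonResult",
    "nominal_attachments",
    "body_to_world",
    "world_to_body",
    "support_polygon",
]

#: absolute tolerance (cm) for boundary containment tests
CONTAINMENT_TOL = 1e-9


class LimbId(enum.IntEnum):
    """Limb numbering: left fore, right fore, left hind, right hind."""

    LF = 1
    RF = 2
    LH = 3
    RH = 4

    @property
    def is_fore(self) -> bool:
        return self in (LimbId.LF, LimbId.RF)

    @property
    def is_left(self) -> bool:
        return self in (LimbId.LF, LimbId.LH)

    @property
    def index(self) -> int:
        """Zero-based array index (LF=0, RF=1, LH=2, RH=3)."""
        return int(self) - 1


@dataclass(frozen=True)
class BodyParams:
    """Fixed geometric and inertial constants of the rod body.

    Defaults are the mouse-scale values used throughout: L=10 cm, H=3 cm,
    h=1 cm, D=L/2=5 cm, m=25 g, lam=100 g/s, grav=1000 cm/s^2.  The yaw
    moment of inertia of a uniform rod, I = m L^2 / 12, is derived.
    """

    L: float = 10.0
    H: float = 3.0
    h: float = 1.0
    D: float = 5.0
    m: float = 25.0
    lam: float = 100.0
    grav: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("L", "H", "h", "D", "m", "lam", "grav"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"BodyParams.{name} must be strictly positive")
        if self.h >= self.L:
            raise ValueError("half-width h must be smaller than body length L")
        if self.D > self.L / 2.0 + 1e-12:
            raise ValueError("displacement limit D may not exceed L/2")

    @property
    def I(self) -> float:  # noqa: E743 - field name follows the physics
        """Yaw moment of inertia of the uniform rod, m*L^2/12 (g cm^2)."""
        return self.m * self.L**2 / 12.0

    @property
    def weight(self) -> float:
        """Body weight m*g (dyn)."""
        return self.m * self.grav


@dataclass
class BodyState:
    """Planar state of the body: COM pose, velocities, and COM height."""

    rc: np.ndarray = field(default_factory=lambda: np.zeros(2))
    vc: np.ndarray = field(default_factory=lambda: np.zeros(2))
    theta: float = 0.0
    omega: float = 0.0
    hc: float = 3.0
    t: float = 0.0


@dataclass
class PawState:
    """Per-limb contact bookkeeping.

    During stance ``contact`` is fixed in the world frame; ``touchdown_ref``
    is the body-frame position at the touchdown instant, against which the
    extension limit is measured; ``nominal_target`` is the unperturbed
    body-frame target used for propulsion directions.  ``load`` is the
    vertical ground-reaction force (dyn) and is zero in swing.
    """

    limb: LimbId
    phase: str = "stance"  # "stance" | "swing"
    contact: np.ndarray = field(default_factory=lambda: np.zeros(2))
    touchdown_ref: np.ndarray = field(default_factory=lambda: np.zeros(2))
    nominal_target: np.ndarray = field(default_factory=lambda: np.zeros(2))
    phase_start: float = 0.0
    load: float = 0.0

    @property
    def in_stance(self) -> bool:
        return self.phase == "stance"


@dataclass(frozen=True)
class StrategyGeometry:
    """Attachment-geometry modifications: bending angle, lateral shift, turn.

    ``turn_sign`` is +1 for a left turn, -1 for a right turn.  ``delta`` is
    the total bending angle (rad) split delta/2 between the fore and hind
    girdles; ``s_shift`` moves the inner-side lateral offsets to ``h - s``
    and the outer ones to ``h + s``.
    """

    delta: float = 0.0
    s_shift: float = 0.0
    turn_sign: int = 1


@njit(cache=True)
def attachment_points(L, h, delta, s_shift, turn_sign):
    """Body-frame attachment/target points, rows LF, RF, LH, RH.

    Bending treats the rod as two uniform segments hinged at the centre:
    the shoulder girdle (at the far end of the front segment) rotates by
    delta/2 and the hip girdle (at the hinge) by delta/2 the opposite way,
    and coordinates are re-centred on the mass centroid of the bent
    two-segment body (offset (L/4) sin(delta/2) from the hinge).  The
    handedness plants the forepaws outside the nominal straight-walking
    track for the commanded turn: with propulsion directed along paw
    displacement toward the nominal target, placing the paws opposite the
    intended turn is what generates the inward steering components — the
    same principle the lateral shift uses.  Lateral shift moves the
    inner-side lateral offsets to h - s and the outer ones to h + s
    (inner = turn side) along the local girdle normals.
    """
    a = -turn_sign * delta / 2.0
    ca, sa = math.cos(a), math.sin(a)
    y_left = h - turn_sign * s_shift
    y_right = -(h + turn_sign * s_shift)
    # left-pointing normals of the front and rear girdle axes
    nfx, nfy = -sa, ca
    nhx, nhy = sa, ca
    fx, fy = L / 2.0 * ca, L / 2.0 * sa   # front of the frame (hinge frame)
    cy = L / 4.0 * sa                      # bent-body centroid offset
    pts = np.empty((4, 2))
    pts[0, 0] = fx + y_left * nfx
    pts[0, 1] = fy + y_left * nfy - cy
    pts[1, 0] = fx + y_right * nfx
    pts[1, 1] = fy + y_right * nfy - cy
    pts[2, 0] = y_left * nhx
    pts[2, 1] = y_left * nhy - cy
    pts[3, 0] = y_right * nhx
    pts[3, 1] = y_right * nhy - cy
    return pts


def nominal_attachments(
    params: BodyParams, geometry_mods: StrategyGeometry | None = None
) -> np.ndarray:
    """Four body-frame attachment/target points, rows ordered LF, RF, LH, RH.

    With all modifications zero this is the baseline frame geometry:
    fore points at (L/2, +-h), hind points at (0, +-h).

    Raises
    ------
    ValueError
        if ``s_shift >= h`` (the inner attachment would cross the midline)
        or ``delta < 0`` / ``s_shift < 0``.
    """
    g = geometry_mods or StrategyGeometry()
    if g.delta < 0.0:
        raise ValueError("bending angle delta must be >= 0")
    if g.s_shift < 0.0:
        raise ValueError("lateral shift s must be >= 0")
    if g.s_shift >= params.h:
        raise ValueError(
            f"lateral shift s={g.s_shift} must be smaller than half-width h={params.h}"
        )
    if g.turn_sign not in (-1, 1):
        raise ValueError("turn_sign must be +1 (left) or -1 (right)")
    return attachment_points(params.L, params.h, g.delta, g.s_shift, g.turn_sign)


@njit(cache=True)
def _rot(theta, x, y):
    c, s = math.cos(theta), math.sin(theta)
    return c * x - s * y, s * x + c * y


def body_to_world(state: BodyState, p_body: np.ndarray) -> np.ndarray:
    """Map a body-frame point to the world frame (rotate by theta, add rc)."""
    x, y = _rot(state.theta, float(p_body[0]), float(p_body[1]))
    return np.array([x + state.rc[0], y + state.rc[1]])


def world_to_body(state: BodyState, p_world: np.ndarray) -> np.ndarray:
    """Inverse of :func:`body_to_world`."""
    dx = float(p_world[0]) - state.rc[0]
    dy = float(p_world[1]) - state.rc[1]
    x, y = _rot(-state.theta, dx, dy)
    return np.array([x, y])


@dataclass
class SupportPolygonResult:
    polygon: object  # shapely geometry (Polygon, LineString, or Point)
    contains: bool
    margin: float
    degenerate: bool = False


def support_polygon(
    stance_points: np.ndarray, com_xy: np.ndarray, tol: float = CONTAINMENT_TOL
) -> SupportPolygonResult:
    """Convex support region of the stance contacts and the COM margin.

    ``margin`` is the signed distance (cm) from the COM to the boundary of
    the convex hull of the contacts: positive inside, zero on the boundary
    (within ``tol``), negative outside.  Two contacts give a degenerate
    segment whose margin is minus the distance to the segment.  Fewer than
    two contacts set the ``degenerate`` flag.
    """
    pts = np.asarray(stance_points, dtype=float)
    com = Point(float(com_xy[0]), float(com_xy[1]))
    if pts.shape[0] < 2:
        geom = Point(pts[0]) if pts.shape[0] == 1 else Point()
        return SupportPolygonResult(geom, False, -math.inf, degenerate=True)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type == "Polygon":
        d = com.distance(hull.exterior)
        inside = hull.contains(com) or d <= tol
        margin = d if hull.contains(com) else (0.0 if d <= tol else -d)
        return SupportPolygonResult(hull, inside, margin)
    # collinear or two-point support: a segment (or a point)
    d = com.distance(hull)
    return SupportPolygonResult(hull, d <= tol, -d if d > tol else 0.0)
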