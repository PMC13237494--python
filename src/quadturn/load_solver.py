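"""Vertical ground-reaction (weight-bearing) forces and COM-height kinematics.

With the body frame held horizontal, the vertical limb loads G_i of three
or four stance limbs must balance gravity (sum G_i = m g) and produce zero
pitch/roll torque about the COM (sum G_i (r_i - r_c) = 0).  Three non-
collinear contacts determine the loads uniquely (they are the barycentric
coordinates of the COM scaled by m g); four contacts are underdetermined
and the minimum-norm solution (minimising sum G_i^2, the most even
distribution) is selected via the KKT conditions of the 3-constraint
quadratic program.

With only two stance limbs the full balance cannot hold.  The body tilts
about the support line like an inverted pendulum: with z the signed
perpendicular COM offset from the line, hc the instantaneous COM height,
cos(phi) = hc / sqrt(z^2 + hc^2) and vp the COM velocity component
perpendicular to the line, the total load is

    G_a + G_b = m g cos(phi) - m vp^2 / H,

split by the zero-pitch lever rule G_a s_a = G_b s_b, where s_a, s_b are
the along-line distances from the COM projection to the two paws.  The
destabilising effect of gravity appears in the horizontal dynamics as the
effective inverted-pendulum force Fp = m g z / H directed from the line
toward the COM.  While the pendulum arm R = sqrt(z^2 + hc^2) is preserved,
the COM height obeys d(hc)/dt = -(z/hc) vp.

A computed negative load is reported as-is with ``admissible=False``: it is
not a physical pulling force but the signal that the limb cannot remain in
stance (the phase controller converts it into a liftoff event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .body_mechanics import BodyParams, BodyState, PawState

__all__ = [
    "LoadDistribution",
    "TwoLimbGeometry",
    "solve_loads",
    "solve_three_limb",
    "solve_four_limb",
    "solve_two_limb",
    "pendulum_force",
    "com_height_rate",
    "two_limb_geometry",
]

#: relative tolerance of the small linear solves
SOLVER_RTOL = 1e-10


@dataclass
class LoadDistribution:
    """Per-limb vertical loads (dyn); swing limbs carry exactly zero."""

    loads: np.ndarray = field(default_factory=lambda: np.zeros(4))
    total: float = 0.0
    admissible: bool = False
    mode: str = "degenerate"  # four | three | two | degenerate


@dataclass
class TwoLimbGeometry:
    """Geometry of a two-limb support phase.

    ``z`` is the signed perpendicular COM displacement from the support
    line (positive on the side of the unit normal ``normal``); ``vp`` the
    signed perpendicular COM velocity; ``s2``/``s3`` the along-line
    distances from the COM projection to the first and second paw.
    """

    p_a: np.ndarray
    p_b: np.ndarray
    z: float
    phi: float
    vp: float
    s2: float
    s3: float
    normal: np.ndarray
    hc: float


@njit(cache=True)
def three_limb_loads(px, py, cx, cy, mg):
    """Unique loads of three stance contacts (Cramer solve of the 3x3 system).

    Rows of the system: x-lever balance, y-lever balance, total = mg.
    Returns (loads[3], ok); ok is False for (near-)collinear contacts.
    """
    a11, a12, a13 = px[0] - cx, px[1] - cx, px[2] - cx
    a21, a22, a23 = py[0] - cy, py[1] - cy, py[2] - cy
    det = (
        a11 * (a22 - a23)
        - a12 * (a21 - a23)
        + a13 * (a21 - a22)
    )
    out = np.zeros(3)
    scale = abs(a11) + abs(a12) + abs(a13) + abs(a21) + abs(a22) + abs(a23) + 1.0
    if abs(det) <= 1e-12 * scale * scale:
        return out, False
    # Cramer: replace successive columns of [[a1],[a2],[1,1,1]] with (0,0,mg)
    out[0] = mg * (a12 * a23 - a13 * a22) / det
    out[1] = -mg * (a11 * a23 - a13 * a21) / det
    out[2] = mg * (a11 * a22 - a12 * a21) / det
    return out, True


@njit(cache=True)
def four_limb_loads(px, py, cx, cy, mg):
    """Minimum-norm loads of four stance contacts.

    Minimises sum G_i^2 subject to A G = b with A = [dx; dy; 1] (3x4),
    b = (0, 0, mg); the KKT solution is G = A^T (A A^T)^{-1} b.  Returns
    (loads[4], ok); ok is False when the constraint matrix loses rank.
    """
    dx = np.empty(4)
    dy = np.empty(4)
    for i in range(4):
        dx[i] = px[i] - cx
        dy[i] = py[i] - cy
    # M = A A^T, symmetric 3x3
    m11 = dx @ dx
    m12 = dx @ dy
    m13 = dx.sum()
    m22 = dy @ dy
    m23 = dy.sum()
    m33 = 4.0
    det = (
        m11 * (m22 * m33 - m23 * m23)
        - m12 * (m12 * m33 - m23 * m13)
        + m13 * (m12 * m23 - m22 * m13)
    )
    out = np.zeros(4)
    scale = m11 + m22 + m33
    if abs(det) <= 1e-12 * scale * scale * scale:
        return out, False
    # y = M^{-1} b with b = (0, 0, mg): last column of M^{-1} times mg
    y1 = mg * (m12 * m23 - m13 * m22) / det
    y2 = mg * (m12 * m13 - m11 * m23) / det
    y3 = mg * (m11 * m22 - m12 * m12) / det
    for i in range(4):
        out[i] = dx[i] * y1 + dy[i] * y2 + y3
    return out, True


@njit(cache=True)
def two_limb_solve(ax, ay, bx, by, cx, cy, vx, vy, m, g, H, hc):
    """Loads, tilt geometry and pendulum normal for two stance contacts.

    Returns (G_a, G_b, z, vp, s_a, s_b, nx, ny, ok).  The normal (nx, ny)
    is the left-perpendicular of the a->b direction; z and vp are signed
    along it.  ok is False when the contacts coincide.
    """
    ux, uy = bx - ax, by - ay
    d = math.hypot(ux, uy)
    if d <= 1e-12:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, False
    ux /= d
    uy /= d
    nx, ny = -uy, ux
    rx, ry = cx - ax, cy - ay
    z = nx * rx + ny * ry
    vp = nx * vx + ny * vy
    c = ux * rx + uy * ry  # along-line coordinate of the COM projection
    s_a = c
    s_b = d - c
    cos_phi = hc / math.sqrt(z * z + hc * hc)
    total = m * g * cos_phi - m * vp * vp / H
    denom = s_a + s_b  # = d > 0
    g_a = total * s_b / denom
    g_b = total * s_a / denom
    return g_a, g_b, z, vp, s_a, s_b, nx, ny, True


def two_limb_geometry(
    state: BodyState, paw_a: PawState, paw_b: PawState
) -> TwoLimbGeometry:
    """Build the two-limb support geometry record from the current state."""
    ga, gb, z, vp, sa, sb, nx, ny, ok = two_limb_solve(
        float(paw_a.contact[0]),
        float(paw_a.contact[1]),
        float(paw_b.contact[0]),
        float(paw_b.contact[1]),
        float(state.rc[0]),
        float(state.rc[1]),
        float(state.vc[0]),
        float(state.vc[1]),
        1.0,
        1.0,
        1.0,
        state.hc,
    )
    if not ok:
        raise ValueError("coincident stance contacts")
    phi = math.atan2(abs(z), state.hc)
    return TwoLimbGeometry(
        p_a=np.array(paw_a.contact, dtype=float),
        p_b=np.array(paw_b.contact, dtype=float),
        z=z,
        phi=phi,
        vp=vp,
        s2=sa,
        s3=sb,
        normal=np.array([nx, ny]),
        hc=state.hc,
    )


def solve_three_limb(
    contacts: np.ndarray, com_xy: np.ndarray, params: BodyParams
) -> LoadDistribution:
    """Unique load distribution of three stance contacts."""
    contacts = np.asarray(contacts, dtype=float)
    loads3, ok = three_limb_loads(
        np.ascontiguousarray(contacts[:, 0]),
        np.ascontiguousarray(contacts[:, 1]),
        float(com_xy[0]),
        float(com_xy[1]),
        params.weight,
    )
    dist = LoadDistribution(loads=np.asarray(loads3), mode="three")
    if not ok:
        dist.mode = "degenerate"
        return dist
    dist.total = float(loads3.sum())
    dist.admissible = bool((loads3 > 0.0).all())
    return dist


def solve_four_limb(
    contacts: np.ndarray, com_xy: np.ndarray, params: BodyParams
) -> LoadDistribution:
    """Minimum-norm load distribution of four stance contacts."""
    contacts = np.asarray(contacts, dtype=float)
    loads4, ok = four_limb_loads(
        np.ascontiguousarray(contacts[:, 0]),
        np.ascontiguousarray(contacts[:, 1]),
        float(com_xy[0]),
        float(com_xy[1]),
        params.weight,
    )
    dist = LoadDistribution(loads=np.asarray(loads4), mode="four")
    if not ok:
        dist.mode = "degenerate"
        return dist
    dist.total = float(loads4.sum())
    dist.admissible = bool((loads4 > 0.0).all())
    return dist


def solve_two_limb(geom: TwoLimbGeometry, params: BodyParams) -> LoadDistribution:
    """Loads of a two-limb support phase from its geometry record."""
    total = params.m * params.grav * math.cos(geom.phi) - params.m * geom.vp**2 / params.H
    denom = geom.s2 + geom.s3
    dist = LoadDistribution(loads=np.zeros(2), mode="two")
    if abs(denom) <= 1e-12:
        dist.mode = "degenerate"
        return dist
    g_a = total * geom.s3 / denom
    g_b = total * geom.s2 / denom
    dist.loads = np.array([g_a, g_b])
    dist.total = g_a + g_b
    dist.admissible = g_a > 0.0 and g_b > 0.0
    return dist


def pendulum_force(geom: TwoLimbGeometry, params: BodyParams) -> np.ndarray:
    """Effective inverted-pendulum force Fp = m g z / H (dyn, world frame).

    Perpendicular to the support line, pointing from the line toward the
    COM; defined for two-limb support only (callers must supply zero when
    more than two limbs are grounded).
    """
    mag = params.m * params.grav * geom.z / params.H
    return mag * geom.normal


def com_height_rate(z: float, hc: float, vp: float) -> float:
    """d(hc)/dt = -(z/hc) vp during two-limb support.

    Preserves the pendulum arm R^2 = z^2 + hc^2 along the flow.  Raises
    for hc <= 0 (the body has collapsed; the run is invalid).
    """
    if hc <= 0.0:
        raise ValueError("COM height must be positive")
    return -(z / hc) * vp


def solve_loads(
    state: BodyState, paws: list[PawState], params: BodyParams
) -> LoadDistribution:
    """Dispatch on the stance count and fill per-limb loads (swing limbs 0).

    0 or 1 stance limbs give ``mode='degenerate'`` with ``admissible=False``
    (entering such support is treated as an instability event by the
    simulation loop, which records the ``support_lost`` failure mode).
    """
    stance = [p for p in paws if p.in_stance]
    n = len(stance)
    full = np.zeros(4)
    if n <= 1:
        return LoadDistribution(loads=full, mode="degenerate")
    com = state.rc
    if n == 2:
        geom = two_limb_geometry(state, stance[0], stance[1])
        dist = solve_two_limb(geom, params)
        if dist.mode == "degenerate":
            return LoadDistribution(loads=full, mode="degenerate")
        for paw, g in zip(stance, dist.loads):
            full[paw.limb.index] = g
        return LoadDistribution(full, dist.total, dist.admissible, "two")
    contacts = np.array([p.contact for p in stance], dtype=float)
    if n == 3:
        dist = solve_three_limb(contacts, com, params)
    else:
        dist = solve_four_limb(contacts, com, params)
    if dist.mode == "degenerate":
        return LoadDistribution(loads=full, mode="degenerate")
    for paw, g in zip(stance, dist.loads):
        full[paw.limb.index] = g
    return LoadDistribution(full, dist.total, dist.admissible, dist.mode)
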