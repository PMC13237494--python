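"""Horizontal-plane equations of motion and the hybrid simulation loop.

The COM velocity and yaw rate obey

    m dvc/dt = sum_i F_i - lam vc + Fp
    I domega/dt = sum_i F_i x (r_i - rc) - lam I omega / m

with per-limb propulsion forces of fixed magnitude ``F0`` directed along
the paw's displacement toward its unperturbed nominal target in body
coordinates, viscous friction ``lam vc`` (and the matching friction torque
``lam I omega / m``), and the inverted-pendulum force ``Fp = m g z / H``
during two-limb support.  The loop is a fixed-step hybrid integrator:
continuous dynamics advance one step, then the load solver and the
rhythm-generator transition rules fire liftoff/touchdown events at the
step boundary (liftoffs first, then at most one touchdown per step).

The viscous terms are integrated exactly (exponential factor per step)
and the remaining forces are held constant over the step, so with F0 = 0
the COM speed decays as exp(-lam t / m) to machine precision; positions
update semi-implicitly from the new velocities.

A full run follows the measurement protocol: warm up with zero asymmetry
until the stride cycle is periodic, ramp the strategy magnitudes linearly
over ``n_ramp`` strides, then record left-forelimb stride points until
enough post-transient strides are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .body_mechanics import BodyParams, attachment_points
from .cpg_controller import liftoff_kind, longest_swing_limb, touchdown_target
from .load_solver import four_limb_loads, three_limb_loads, two_limb_solve
from .turning_strategies import StrategyParams

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "propulsion_forces",
    "net_wrench",
    "STATUS_NAMES",
]

STATUS_NAMES = {
    0: "completed",
    1: "no_gait",
    2: "support_lost",
    3: "com_escape",
    4: "height_collapse",
    5: "insufficient_strides",
    6: "event_overflow",
}

TRAJ_COLUMNS = [
    "t", "x", "y", "theta", "vx", "vy", "omega", "hc",
    "G_LF", "G_RF", "G_LH", "G_RH",
    "ph_LF", "ph_RF", "ph_LH", "ph_RH",
]

EVENT_COLUMNS = ["t", "limb", "kind", "x", "y", "com_x", "com_y"]


@dataclass(frozen=True)
class SimConfig:
    """Everything a run needs; the model is fully deterministic."""

    params: BodyParams = field(default_factory=BodyParams)
    F0: float = 400.0
    strategy: StrategyParams = field(default_factory=StrategyParams)
    dt: float = 5e-4
    t_max: float = 40.0
    warmup_timeout: float = 10.0
    n_ramp: int = 5
    periodicity_tol: float = 0.01
    n_discard: int = 10
    n_keep: int = 10
    record_every: int = 20
    raw: bool = False
    v0: Optional[float] = None
    v0_vec: Optional[tuple] = None
    omega0: float = 0.0
    init_stagger: float = 2.0
    eps_g_rel: float = 1e-6
    escape_window: float = 0.6

    def validate(self) -> "SimConfig":
        if self.dt <= 0.0 or self.t_max <= self.dt:
            raise ValueError("need dt > 0 and t_max > dt")
        if self.F0 < 0.0:
            raise ValueError("propulsion force F0 must be >= 0")
        self.strategy.validate(self.params)
        return self


@dataclass
class SimResult:
    """Trajectory, event log and protocol metadata of one run."""

    config: SimConfig
    status: str
    t_warmup_end: float
    t_ramp_end: float
    t_final: float
    stride_period_ref: float
    events: pd.DataFrame
    traj: pd.DataFrame
    lf_touchdowns: np.ndarray  # (n, 3): t, com_x, com_y
    meas_start: int            # index of first post-ramp LF touchdown, or -1

    @property
    def ok(self) -> bool:
        return self.status == "completed"

    @property
    def measured_points(self) -> np.ndarray:
        """Post-ramp LF-touchdown stride points (t, com_x, com_y)."""
        if self.meas_start < 0:
            return np.empty((0, 3))
        return self.lf_touchdowns[self.meas_start:]


@njit(cache=True)
def _stance_loads(phase, contact, rcx, rcy, vx, vy, m, g, H, hc):
    """Loads of the current stance set.

    Returns (G[4], ns, z, vp, nx, ny, gtot, ok): z/vp/(nx,ny) describe the
    two-limb support geometry (zero otherwise); gtot is the total vertical
    load of the stance limbs.
    """
    G = np.zeros(4)
    idx = np.empty(4, np.int64)
    ns = 0
    for i in range(4):
        if phase[i] == 0:
            idx[ns] = i
            ns += 1
    z = 0.0
    vp = 0.0
    nx = 0.0
    ny = 0.0
    ok = True
    gtot = 0.0
    if ns == 4:
        px = np.empty(4)
        py = np.empty(4)
        for k in range(4):
            px[k] = contact[idx[k], 0]
            py[k] = contact[idx[k], 1]
        g4, ok = four_limb_loads(px, py, rcx, rcy, m * g)
        if ok:
            for k in range(4):
                G[idx[k]] = g4[k]
                gtot += g4[k]
    elif ns == 3:
        px = np.empty(3)
        py = np.empty(3)
        for k in range(3):
            px[k] = contact[idx[k], 0]
            py[k] = contact[idx[k], 1]
        g3, ok = three_limb_loads(px, py, rcx, rcy, m * g)
        if ok:
            for k in range(3):
                G[idx[k]] = g3[k]
                gtot += g3[k]
    elif ns == 2:
        a = idx[0]
        b = idx[1]
        ga, gb, z, vp, sa, sb, nx, ny, ok = two_limb_solve(
            contact[a, 0], contact[a, 1], contact[b, 0], contact[b, 1],
            rcx, rcy, vx, vy, m, g, H, hc,
        )
        if ok:
            G[a] = ga
            G[b] = gb
            gtot = ga + gb
    return G, ns, z, vp, nx, ny, gtot, ok


@njit(cache=True)
def _two_limb_geom(phase, contact, rcx, rcy, vx, vy):
    """Signed offset z, perpendicular velocity vp and normal of the support
    line when exactly two limbs are grounded (zeros otherwise)."""
    a = -1
    b = -1
    ns = 0
    for i in range(4):
        if phase[i] == 0:
            if a == -1:
                a = i
            elif b == -1:
                b = i
            ns += 1
    if ns != 2:
        return 0.0, 0.0, 0.0, 0.0, ns
    ux = contact[b, 0] - contact[a, 0]
    uy = contact[b, 1] - contact[a, 1]
    d = math.hypot(ux, uy)
    if d <= 1e-12:
        return 0.0, 0.0, 0.0, 0.0, ns
    ux /= d
    uy /= d
    nx, ny = -uy, ux
    z = nx * (rcx - contact[a, 0]) + ny * (rcy - contact[a, 1])
    vp = nx * vx + ny * vy
    return z, vp, nx, ny, ns


@njit(cache=True)
def simulate_kernel(
    L, H, h, D, m, lam, g,
    F0, delta, f_lat, s_shift, a_shift, turn_sign,
    dt, t_max, raw,
    warmup_timeout, n_ramp, period_tol,
    n_discard, n_keep,
    eps_g_rel, escape_default,
    record_every,
    x0, y0, th0, vx0, vy0, om0, hc0,
    phase0, contact0, tdref0,
):
    n_steps = int(t_max / dt) + 1
    ev_cap = 2 * n_steps + 64
    events = np.zeros((ev_cap, 7))
    n_ev = 0
    lf_cap = 8192
    lf = np.zeros((lf_cap, 3))
    n_lf = 0
    if record_every > 0:
        traj = np.zeros((n_steps // record_every + 2, 16))
    else:
        traj = np.zeros((0, 16))
    n_rec = 0

    I = m * L * L / 12.0
    mg = m * g
    eps_g = eps_g_rel * mg
    decay = math.exp(-lam * dt / m)
    gain = (1.0 - decay) / lam  # v += F * gain (exact for constant F)

    # state
    x, y, th = x0, y0, th0
    vx, vy, om = vx0, vy0, om0
    hc = hc0
    t = 0.0
    phase = phase0.copy()
    contact = contact0.copy()
    tdref = tdref0.copy()
    phase_start = np.zeros(4)

    # protocol
    mode = 2 if raw else 0  # 0 warmup, 1 ramp, 2 post-ramp
    r = 1.0 if raw else 0.0
    r_prev = -1.0
    ramp_t0 = 0.0
    ramp_dur = 0.0
    T_ref = 0.0
    t_warmup_end = -1.0
    t_ramp_end = 0.0 if raw else -1.0
    meas_start = -1
    n_meas_needed = n_discard + n_keep + 2

    attach = attachment_points(L, h, 0.0, 0.0, turn_sign)
    # propulsion reference: the unperturbed baseline targets inherited from
    # straight walking (no bending, no lateral/axial shift) — fixed all run
    attach_prop = attachment_points(L, h, 0.0, 0.0, turn_sign)
    a_c = 0.0
    flat_c = 0.0

    gtot_prev = mg
    t_last_adm = 0.0
    status = 5  # insufficient_strides unless decided otherwise

    for istep in range(n_steps):
        # --- ramp factor and current strategy magnitudes ---
        if mode == 1:
            r = (t - ramp_t0) / ramp_dur
            if r >= 1.0:
                r = 1.0
                mode = 2
                t_ramp_end = t
        if r != r_prev:
            d_c = r * delta
            s_c = r * s_shift
            a_c = r * a_shift
            flat_c = r * f_lat
            attach = attachment_points(L, h, d_c, s_c, turn_sign)
            r_prev = r

        # --- continuous dynamics over [t, t+dt] ---
        z, vp, nx, ny, ns = _two_limb_geom(phase, contact, x, y, vx, vy)
        if ns <= 1:
            status = 2
            break
        cth = math.cos(th)
        sth = math.sin(th)
        Fx = 0.0
        Fy = 0.0
        tau = 0.0
        for i in range(4):
            if phase[i] != 0:
                continue
            # paw position in body frame
            dxw = contact[i, 0] - x
            dyw = contact[i, 1] - y
            pbx = cth * dxw + sth * dyw
            pby = -sth * dxw + cth * dyw
            ddx = attach_prop[i, 0] - pbx
            ddy = attach_prop[i, 1] - pby
            dn = math.hypot(ddx, ddy)
            fx = 0.0
            fy = 0.0
            if dn > 1e-9:
                fbx = F0 * ddx / dn
                fby = F0 * ddy / dn
                fx = cth * fbx - sth * fby
                fy = sth * fbx + cth * fby
            if i < 2 and flat_c > 0.0:
                # steering addition, perpendicular to the body axis toward the turn
                fx += -sth * turn_sign * flat_c
                fy += cth * turn_sign * flat_c
            Fx += fx
            Fy += fy
            tau += dxw * fy - dyw * fx
        if ns == 2:
            # inverted-pendulum force, applied at the COM (no torque)
            fp = mg * z / H
            Fx += fp * nx
            Fy += fp * ny

        vx = vx * decay + Fx * gain
        vy = vy * decay + Fy * gain
        om = om * decay + tau * gain * m / I
        x += vx * dt
        y += vy * dt
        th += om * dt
        if ns == 2:
            hc += -(z / hc) * vp * dt
            if hc < 0.5 * H:
                status = 4
                t = t + dt
                break
        else:
            hc = H
        t += dt

        # --- transitions at the step boundary ---
        G, ns2, z2, vp2, nx2, ny2, gtot, okl = _stance_loads(
            phase, contact, x, y, vx, vy, m, g, H, hc
        )
        cth = math.cos(th)
        sth = math.sin(th)
        lifted = False
        for i in range(4):
            if phase[i] != 0:
                continue
            dxw = contact[i, 0] - x
            dyw = contact[i, 1] - y
            pbx = cth * dxw + sth * dyw
            pby = -sth * dxw + cth * dyw
            drn = math.hypot(pbx - tdref[i, 0], pby - tdref[i, 1])
            d_eff = D - a_c if i < 2 else D
            if okl:
                kind = liftoff_kind(G[i], drn, d_eff)
            else:
                kind = 1 if drn > d_eff else -1
            if kind >= 0:
                phase[i] = 1
                phase_start[i] = t
                G[i] = 0.0
                if n_ev < ev_cap:
                    events[n_ev, 0] = t
                    events[n_ev, 1] = i + 1
                    events[n_ev, 2] = kind
                    events[n_ev, 3] = contact[i, 0]
                    events[n_ev, 4] = contact[i, 1]
                    events[n_ev, 5] = x
                    events[n_ev, 6] = y
                    n_ev += 1
                lifted = True
        if n_ev >= ev_cap:
            status = 6
            break
        if lifted:
            G, ns2, z2, vp2, nx2, ny2, gtot, okl = _stance_loads(
                phase, contact, x, y, vx, vy, m, g, H, hc
            )
        if ns2 <= 1:
            status = 2
            break

        # the trigger compares the one-step backward difference of G_tot,
        # including the discontinuous drop when a limb lifts: losing a
        # support limb is itself the strongest loss-of-balance signal, so a
        # replacement limb grounds within the same step
        if ns2 < 4 and gtot - gtot_prev < -eps_g:
            li = longest_swing_limb(phase == 1, phase_start)
            if li >= 0:
                tx, ty = touchdown_target(attach, li, a_c)
                wx = cth * tx - sth * ty + x
                wy = sth * tx + cth * ty + y
                contact[li, 0] = wx
                contact[li, 1] = wy
                tdref[li, 0] = tx
                tdref[li, 1] = ty
                phase[li] = 0
                phase_start[li] = t
                if n_ev < ev_cap:
                    events[n_ev, 0] = t
                    events[n_ev, 1] = li + 1
                    events[n_ev, 2] = 2
                    events[n_ev, 3] = wx
                    events[n_ev, 4] = wy
                    events[n_ev, 5] = x
                    events[n_ev, 6] = y
                    n_ev += 1
                G, ns2, z2, vp2, nx2, ny2, gtot, okl = _stance_loads(
                    phase, contact, x, y, vx, vy, m, g, H, hc
                )
                # --- stride bookkeeping on LF touchdowns ---
                # a re-touchdown much sooner than the running stride
                # interval replaces the previous stride point (the paw
                # stutter-stepped rather than started a new stride)
                if li == 0:
                    bounce_win = 0.02
                    if n_lf >= 2:
                        prev_T = lf[n_lf - 1, 0] - lf[n_lf - 2, 0]
                        if 0.2 * prev_T > bounce_win:
                            bounce_win = 0.2 * prev_T
                    if n_lf > 0 and t - lf[n_lf - 1, 0] < bounce_win:
                        lf[n_lf - 1, 0] = t
                        lf[n_lf - 1, 1] = x
                        lf[n_lf - 1, 2] = y
                    elif n_lf < lf_cap:
                        lf[n_lf, 0] = t
                        lf[n_lf, 1] = x
                        lf[n_lf, 2] = y
                        n_lf += 1
                    else:
                        status = 6
                        break
                    if mode == 0 and n_lf >= 4:
                        ok_p = True
                        for k in range(2):
                            T0 = lf[n_lf - 3 + k, 0] - lf[n_lf - 4 + k, 0]
                            T1 = lf[n_lf - 2 + k, 0] - lf[n_lf - 3 + k, 0]
                            S0 = math.hypot(
                                lf[n_lf - 3 + k, 1] - lf[n_lf - 4 + k, 1],
                                lf[n_lf - 3 + k, 2] - lf[n_lf - 4 + k, 2],
                            )
                            S1 = math.hypot(
                                lf[n_lf - 2 + k, 1] - lf[n_lf - 3 + k, 1],
                                lf[n_lf - 2 + k, 2] - lf[n_lf - 3 + k, 2],
                            )
                            if T0 <= 0.0 or S0 <= 0.0:
                                ok_p = False
                                break
                            if abs(T1 - T0) / T0 > period_tol:
                                ok_p = False
                                break
                            if abs(S1 - S0) / S0 > period_tol:
                                ok_p = False
                                break
                        if ok_p:
                            T_ref = lf[n_lf - 1, 0] - lf[n_lf - 2, 0]
                            t_warmup_end = t
                            ramp_t0 = t
                            ramp_dur = n_ramp * T_ref
                            if ramp_dur <= 0.0:
                                ramp_dur = dt
                            mode = 1
                    elif mode == 2 and not raw:
                        if meas_start < 0 and t >= t_ramp_end:
                            meas_start = n_lf - 1
                        if meas_start >= 0 and n_lf - meas_start >= n_meas_needed:
                            status = 0
                            gtot_prev = gtot
                            break
        gtot_prev = gtot

        # admissibility tracking for the rollover (com_escape) failure mode
        adm = okl and ns2 >= 2
        if adm:
            for i in range(4):
                if phase[i] == 0 and G[i] <= 0.0:
                    adm = False
                    break
        if adm:
            t_last_adm = t
        else:
            window = T_ref if T_ref > 0.0 else escape_default
            if t - t_last_adm > window:
                status = 3
                break

        # warmup timeout
        if mode == 0 and t >= warmup_timeout:
            status = 1
            break

        # decimated recording
        if record_every > 0 and istep % record_every == 0:
            traj[n_rec, 0] = t
            traj[n_rec, 1] = x
            traj[n_rec, 2] = y
            traj[n_rec, 3] = th
            traj[n_rec, 4] = vx
            traj[n_rec, 5] = vy
            traj[n_rec, 6] = om
            traj[n_rec, 7] = hc
            for i in range(4):
                traj[n_rec, 8 + i] = G[i]
                traj[n_rec, 12 + i] = float(phase[i])
            n_rec += 1

    else:
        # ran out of steps
        if raw:
            status = 0
        elif mode == 0:
            status = 1

    if raw and status == 5:
        status = 0
    return (
        status, t_warmup_end, t_ramp_end, t, T_ref,
        events[:n_ev], traj[:n_rec], lf[:n_lf], meas_start,
    )


# mid-stride initial paw offsets (fractions of the stagger length) in
# lateral-sequence walk order: LH leads, then LF, RH, RF
_INIT_PHASE_FRAC = np.array([0.75, 0.25, 1.0, 0.5])


def _initial_arrays(config: SimConfig):
    """Initial paw layout: all four grounded mid-stride.

    Contacts start displaced backward from the nominal targets by staggered
    amounts (touchdown references stay at the nominal targets, as if each
    paw had landed there earlier in its cycle).  A perfectly symmetric
    start is a left-right invariant subspace of the deterministic dynamics
    in which the limb pairs transition simultaneously and no alternating
    gait can form, so the stagger seeds the stance phases the feedback
    then locks into a walk.
    """
    p = config.params
    attach = attachment_points(p.L, p.h, 0.0, 0.0, 1)
    phase0 = np.zeros(4, dtype=np.int64)
    tdref0 = attach.copy()
    contact0 = attach.copy()
    contact0[:, 0] -= _INIT_PHASE_FRAC * config.init_stagger
    return phase0, contact0, tdref0


def simulate(config: SimConfig) -> SimResult:
    """Run one full simulation (warmup, ramp, measurement window).

    With ``config.raw`` the protocol is skipped: the strategy acts at full
    magnitude from t = 0 and the run simply integrates to ``t_max``.
    Identical configs produce bit-identical results; there is no randomness.
    """
    config.validate()
    p = config.params
    s = config.strategy
    phase0, contact0, tdref0 = _initial_arrays(config)
    if config.v0_vec is not None:
        vx0, vy0 = float(config.v0_vec[0]), float(config.v0_vec[1])
    else:
        vx0 = config.v0 if config.v0 is not None else config.F0 / p.lam
        vy0 = 0.0
    out = simulate_kernel(
        p.L, p.H, p.h, p.D, p.m, p.lam, p.grav,
        config.F0, s.delta, s.f_lat, s.s_shift, s.a_shift, s.turn_sign,
        config.dt, config.t_max, config.raw,
        config.warmup_timeout, config.n_ramp, config.periodicity_tol,
        config.n_discard, config.n_keep,
        config.eps_g_rel, config.escape_window,
        config.record_every,
        0.0, 0.0, 0.0, vx0, vy0, config.omega0, p.H,
        phase0, contact0, tdref0,
    )
    (status, t_wu, t_re, t_fin, T_ref, events, traj, lf, meas_start) = out
    ev = pd.DataFrame(events, columns=EVENT_COLUMNS)
    ev["limb"] = ev["limb"].astype(int)
    ev["kind"] = ev["kind"].map(
        {0: "liftoff_unload", 1: "liftoff_extension", 2: "touchdown"}
    )
    tr = pd.DataFrame(traj, columns=TRAJ_COLUMNS)
    return SimResult(
        config=config,
        status=STATUS_NAMES[int(status)],
        t_warmup_end=float(t_wu),
        t_ramp_end=float(t_re),
        t_final=float(t_fin),
        stride_period_ref=float(T_ref),
        events=ev,
        traj=tr,
        lf_touchdowns=np.asarray(lf),
        meas_start=int(meas_start),
    )


# ---------------------------------------------------------------------------
# Introspectable single-configuration force/torque helpers (the same math the
# kernel runs, exposed on the dataclass API for analysis and testing).
# ---------------------------------------------------------------------------

def propulsion_forces(state, paws, F0: float, strategy: StrategyParams,
                      params: BodyParams) -> np.ndarray:
    """Per-limb horizontal forces (4x2, world frame, dyn).

    Stance limbs push with magnitude ``F0`` along the displacement of the
    paw toward its unperturbed nominal target — the baseline straight-walking
    attachment, without bending or lateral/axial shift — in body
    coordinates; grounded forelimbs additionally receive the lateral
    steering force.  Swing limbs contribute zero, as does a stance limb
    sitting exactly on its target.
    """
    from .body_mechanics import world_to_body
    from .turning_strategies import lateral_force_vectors

    out = np.zeros((4, 2))
    attach_prop = attachment_points(
        params.L, params.h, 0.0, 0.0, strategy.turn_sign
    )
    c, s_ = math.cos(state.theta), math.sin(state.theta)
    R = np.array([[c, -s_], [s_, c]])
    for paw in paws:
        if not paw.in_stance:
            continue
        pb = world_to_body(state, paw.contact)
        d = attach_prop[paw.limb.index] - pb
        dn = float(np.hypot(*d))
        if dn > 1e-9:
            out[paw.limb.index] = R @ (F0 * d / dn)
    out += lateral_force_vectors(strategy, state, paws)
    return out


def net_wrench(forces: np.ndarray, paws, state, params: BodyParams,
               pendulum: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Total horizontal force (2,) and yaw torque (z-component, dyn cm).

    force = sum F_i - lam vc + Fp; torque = sum (r_i - rc) x F_i - lam I w/m.
    The pendulum force acts at the COM and therefore adds no torque.
    """
    total = forces.sum(axis=0) - params.lam * np.asarray(state.vc, dtype=float)
    if pendulum is not None:
        total = total + pendulum
    tau = 0.0
    for paw in paws:
        f = forces[paw.limb.index]
        lever = np.asarray(paw.contact, dtype=float) - state.rc
        tau += lever[0] * f[1] - lever[1] * f[0]
    tau -= params.lam * params.I * state.omega / params.m
    return total, tau
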