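"""Extended body-cover vocal-fold model.

Three lumped masses per fold (lower cover, upper cover, body) coupled by
springs and dampers, driven by quasi-steady Bernoulli aerodynamics with flow
separation at the minimum glottal area and a constant posterior glottal gap.
Intrinsic-muscle activations (cricothyroid a_CT, thyroarytenoid a_TA, and a
combined adductory level a_LC) set the geometry and effective stiffnesses
through physiological rules: elongation strain, cover/body depths, nodal
point, and fiber-stress-derived spring constants.

All quantities are SI (m, kg, s, Pa).  The configuration constants live in
:mod:`laryngosim.bcm_params` and are calibrated once to a male modal voice
(baseline f_o near 134 Hz, ~75 dB SPL at P_s = 800 Pa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

import numpy as np
from numba import njit

from . import bcm_params as P

__all__ = [
    "MuscleActivation",
    "BCMParameters",
    "SimulationConfig",
    "GlottalWaveforms",
    "SimulationError",
    "InsufficientDataError",
    "activation_to_params",
    "simulate_vocal_folds",
    "steady_state_segment",
    "vocal_fold_strain",
]


class SimulationError(RuntimeError):
    """Raised when the time integration produces non-finite state."""


class InsufficientDataError(ValueError):
    """Raised when a waveform segment is too short for the requested analysis."""


@dataclass(frozen=True)
class MuscleActivation:
    """Normalized intrinsic laryngeal muscle activation levels.

    a_CT stretches and tenses the folds, a_TA tenses/shortens the body,
    a_LC is the combined LCA/PCA adductory setting (0 = abducted,
    1 = pressed).  All in [0, 1].
    """

    a_CT: float
    a_TA: float
    a_LC: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name}={v!r} outside [0, 1]")


@dataclass(frozen=True)
class BCMParameters:
    """Lumped-element parameters produced by the muscle-activation rules."""

    # geometry
    length: float           # vibrating membranous length [m]
    thickness: float        # fold thickness [m]
    depth_cover: float      # effective cover depth [m]
    depth_body: float       # effective body depth [m]
    strain: float           # elongation strain epsilon (dimensionless)
    # masses [kg]
    m1: float
    m2: float
    mb: float
    # springs [N/m]
    k1: float
    k2: float
    kc: float
    kb: float
    # damping ratios (dimensionless)
    zeta1: float
    zeta2: float
    zetab: float
    zeta_collision: float   # added to cover damping during contact
    # collision springs [N/m]
    h1: float
    h2: float
    # rest half-widths at lower/upper margins [m]
    xi01: float
    xi02: float
    # posterior glottal gap area [m^2]
    a_pgo: float
    # spring cubic coefficients [1/m^2]
    eta_k: float
    eta_h: float

    def __post_init__(self) -> None:
        for name in ("length", "thickness", "depth_cover", "depth_body",
                     "m1", "m2", "mb", "k1", "k2", "kb", "h1", "h2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BCMParameters.{name} must be positive")

    def as_array(self) -> np.ndarray:
        """Flat float64 vector in the order the simulation kernel expects."""
        return np.array([
            self.length, self.thickness, self.m1, self.m2, self.mb,
            self.k1, self.k2, self.kc, self.kb,
            self.zeta1, self.zeta2, self.zetab, self.zeta_collision,
            self.h1, self.h2, self.xi01, self.xi02, self.a_pgo,
            self.eta_k, self.eta_h, self.depth_cover, self.depth_body,
        ])


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings for a vocal-fold simulation.

    P_s is the subglottal pressure in Pa (forward-map operating range
    0..2010 Pa); fs_sim must resolve collision events (>= 40 kHz).
    """

    P_s: float = 800.0
    duration: float = 1.0
    fs_sim: float = 44100.0
    onset_discard: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.P_s <= 2010.0):
            raise ValueError(f"P_s={self.P_s} outside [0, 2010] Pa")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.fs_sim < 40000.0:
            raise ValueError("fs_sim must be >= 40 kHz")
        if self.onset_discard < 0:
            raise ValueError("onset_discard must be non-negative")


@dataclass
class GlottalWaveforms:
    """Glottal area and volume-velocity time series from one simulation."""

    t: np.ndarray           # [s]
    a_g: np.ndarray         # glottal area incl. posterior gap [m^2]
    U_g: np.ndarray         # glottal volume velocity [m^3/s]
    fs_sim: float
    oscillating: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.a_g) == len(self.U_g)):
            raise ValueError("t, a_g, U_g must share length")

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs_sim

    def to_dataframe(self):
        """(t, a_g, U_g) as a pandas DataFrame for CSV export."""
        import pandas as pd

        return pd.DataFrame({"t": self.t, "a_g": self.a_g, "U_g": self.U_g})


def vocal_fold_strain(act: MuscleActivation) -> float:
    """Elongation strain of the folds: eps = G(R*a_CT - a_TA) - H*a_LC."""
    return P.G_STRAIN * (P.R_TORQUE * act.a_CT - act.a_TA) - P.H_ADDUCT * act.a_LC


def _passive_stress(eps: float, sigma0: float, eps2: float,
                    sigma2: float, c: float) -> float:
    """One-branch linear + exponential passive fiber stress model [Pa]."""
    s = -(sigma0 / P.EPS1) * (eps - P.EPS1)
    if eps > eps2:
        x = c * (eps - eps2)
        s += sigma2 * (math.exp(x) - 1.0 - x)
    return max(s, 0.0)


def _active_muscle_stress(a_TA: float, eps: float) -> float:
    """Active TA fiber stress with a parabolic length-tension curve [Pa]."""
    lt = 1.0 - P.B_ACT * (eps - P.EPS_ACT_MAX) ** 2
    return P.SIGMA_ACT_MAX * a_TA * max(lt, 0.0)


def activation_to_params(act: MuscleActivation) -> BCMParameters:
    """Evaluate the muscle-activation rules.

    Deterministic: the same activation triple always yields the identical
    parameter set.  Monotone effects: raising a_CT elongates the folds and
    stiffens the cover through passive ligament/mucosa stress; raising a_TA
    shortens the folds and both stiffens (active stress) and thickens/
    loads (depth, mass) the body; a_LC sets the rest half-widths.
    """
    if not isinstance(act, MuscleActivation):
        act = MuscleActivation(*act)

    eps = vocal_fold_strain(act)
    L = P.L0 * (1.0 + eps)
    T = P.T0 / (1.0 + 0.8 * eps)
    zn = min((1.0 + act.a_TA) / 3.0, 0.75) * T      # nodal point from below
    dc = (P.D_MUC + 0.5 * P.D_LIG) / (1.0 + 0.2 * eps)
    db = (act.a_TA * P.D_MUS + 0.5 * P.D_LIG) / (1.0 + 0.2 * eps)

    t1, t2 = zn, T - zn

    # fiber stresses per tissue, then depth-weighted for cover and body
    s_muc = _passive_stress(eps, P.SIG0_MUC, P.EPS2_MUC, P.SIG2_MUC, P.C_MUC)
    s_lig = _passive_stress(eps, P.SIG0_LIG, P.EPS2_LIG, P.SIG2_LIG, P.C_LIG)
    s_mus = (_passive_stress(eps, P.SIG0_MUS, P.EPS2_MUS, P.SIG2_MUS, P.C_MUS)
             + _active_muscle_stress(act.a_TA, eps))
    w_muc, w_lig = P.D_MUC, 0.5 * P.D_LIG
    sigma_c = (w_muc * s_muc + w_lig * s_lig) / (w_muc + w_lig)
    w_mus = act.a_TA * P.D_MUS
    sigma_b = (w_lig * s_lig + w_mus * s_mus) / (w_lig + w_mus)

    rho_t = P.RHO_TISSUE * P.MODAL_MASS_FACTOR
    m1 = rho_t * L * t1 * dc
    m2 = rho_t * L * t2 * dc
    mb = rho_t * L * T * db

    cal = P.STIFFNESS_SCALE

    def spring(mu: float, sigma: float, ti: float, d: float) -> float:
        shear = 2.0 * mu * (L * ti / d)
        fiber = (math.pi ** 2) * sigma * (ti * d / L)
        return cal * (shear + fiber)

    k1 = spring(P.MU_COVER, sigma_c, t1, dc)
    k2 = spring(P.MU_COVER, sigma_c, t2, dc)
    kb = spring(P.MU_BODY, sigma_b, T, db)
    kc = cal * P.KC_SHEAR_FACTOR * P.MU_COVER * L * dc / T

    xi02 = 0.25 * P.L0 * (1.0 - 2.0 * act.a_LC)
    xi01 = xi02 + P.CONVERGENCE_FACTOR * T

    return BCMParameters(
        length=L, thickness=T, depth_cover=dc, depth_body=db, strain=eps,
        m1=m1, m2=m2, mb=mb, k1=k1, k2=k2, kc=kc, kb=kb,
        zeta1=P.ZETA_COVER, zeta2=P.ZETA_COVER, zetab=P.ZETA_BODY,
        zeta_collision=P.ZETA_COLLISION,
        h1=P.COLLISION_FACTOR * k1, h2=P.COLLISION_FACTOR * k2,
        xi01=xi01, xi02=xi02, a_pgo=P.A_PGO,
        eta_k=P.ETA_K, eta_h=P.ETA_H,
    )


@njit(cache=True)
def _bcm_kernel(par, ps_series, fs, rho_air):  # pragma: no cover - jit
    """RK4 integration of the three-mass system.

    ``par`` is either a (22,) vector (constant parameters) or an (n, 22)
    array (per-sample parameters, already expanded by the caller).
    Returns (a_g, U_g, ok_flag).
    """
    n = ps_series.shape[0]
    a_g = np.empty(n)
    u_g = np.empty(n)
    dt = 1.0 / fs

    x1 = 0.0
    x2 = 0.0
    xb = 0.0
    v1 = 0.0
    v2 = 0.0
    vb = 0.0

    varying = par.ndim == 2
    row = par[0] if varying else par

    for i in range(n):
        if varying:
            row = par[i]
        L = row[0]
        T = row[1]
        m1 = row[2]
        m2 = row[3]
        mb = row[4]
        k1 = row[5]
        k2 = row[6]
        kc = row[7]
        kb = row[8]
        z1 = row[9]
        z2 = row[10]
        zb = row[11]
        zcol = row[12]
        h1 = row[13]
        h2 = row[14]
        xi01 = row[15]
        xi02 = row[16]
        apgo = row[17]
        eta_k = row[18]
        eta_h = row[19]
        ps = ps_series[i]
        zn = m1 / (m1 + m2) * T  # lower-mass plate height fraction of T

        # -- record output from current state -------------------------------
        xi1 = xi01 + x1
        xi2 = xi02 + x2
        a1 = 2.0 * L * xi1
        a2 = 2.0 * L * xi2
        if a1 < 0.0:
            a1 = 0.0
        if a2 < 0.0:
            a2 = 0.0
        am = a1 if a1 < a2 else a2
        ag_tot = am + apgo
        a_g[i] = ag_tot
        u_g[i] = ag_tot * math.sqrt(2.0 * ps / rho_air)

        # -- one RK4 step ---------------------------------------------------
        y0 = x1
        y1 = x2
        y2 = xb
        y3 = v1
        y4 = v2
        y5 = vb

        # derivative evaluation inlined 4x (k1..k4 stages)
        d0 = d1 = d2 = d3 = d4 = d5 = 0.0
        e0 = e1 = e2 = e3 = e4 = e5 = 0.0
        f0 = f1 = f2 = f3 = f4 = f5 = 0.0
        g0 = g1 = g2 = g3 = g4 = g5 = 0.0
        for stage in range(4):
            if stage == 0:
                sx1 = y0
                sx2 = y1
                sxb = y2
                sv1 = y3
                sv2 = y4
                svb = y5
            elif stage == 1:
                sx1 = y0 + 0.5 * dt * d0
                sx2 = y1 + 0.5 * dt * d1
                sxb = y2 + 0.5 * dt * d2
                sv1 = y3 + 0.5 * dt * d3
                sv2 = y4 + 0.5 * dt * d4
                svb = y5 + 0.5 * dt * d5
            elif stage == 2:
                sx1 = y0 + 0.5 * dt * e0
                sx2 = y1 + 0.5 * dt * e1
                sxb = y2 + 0.5 * dt * e2
                sv1 = y3 + 0.5 * dt * e3
                sv2 = y4 + 0.5 * dt * e4
                svb = y5 + 0.5 * dt * e5
            else:
                sx1 = y0 + dt * f0
                sx2 = y1 + dt * f1
                sxb = y2 + dt * f2
                sv1 = y3 + dt * f3
                sv2 = y4 + dt * f4
                svb = y5 + dt * f5

            # areas at stage state
            sxi1 = xi01 + sx1
            sxi2 = xi02 + sx2
            sa1 = 2.0 * L * sxi1
            sa2 = 2.0 * L * sxi2
            open1 = sa1 > 0.0
            open2 = sa2 > 0.0

            # driving pressures: separation at the minimum area; stagnation
            # pressure when the channel is blocked anywhere
            if open1 and open2:
                samin = sa1 if sa1 < sa2 else sa2
                p1 = ps * (1.0 - (samin / sa1) ** 2)
            else:
                p1 = ps
            p2 = 0.0

            f_aero1 = p1 * L * zn
            f_aero2 = p2 * L * (T - zn)

            # cover springs (anchored to body) with cubic hardening
            d1c = sx1 - sxb
            d2c = sx2 - sxb
            fs1 = k1 * d1c * (1.0 + eta_k * d1c * d1c)
            fs2 = k2 * d2c * (1.0 + eta_k * d2c * d2c)
            fsb = kb * sxb * (1.0 + eta_k * sxb * sxb)
            fkc = kc * (sx1 - sx2)

            # damping (cover damping rises during collision)
            zz1 = z1 + (0.0 if open1 else zcol)
            zz2 = z2 + (0.0 if open2 else zcol)
            b1 = 2.0 * zz1 * math.sqrt(m1 * k1)
            b2 = 2.0 * zz2 * math.sqrt(m2 * k2)
            bb = 2.0 * zb * math.sqrt(mb * kb)
            fd1 = b1 * (sv1 - svb)
            fd2 = b2 * (sv2 - svb)
            fdb = bb * svb

            # collision springs past the midline
            fc1 = 0.0
            fc2 = 0.0
            if not open1:
                fc1 = -h1 * sxi1 * (1.0 + eta_h * sxi1 * sxi1)
            if not open2:
                fc2 = -h2 * sxi2 * (1.0 + eta_h * sxi2 * sxi2)

            ax1 = (f_aero1 - fs1 - fd1 - fkc + fc1) / m1
            ax2 = (f_aero2 - fs2 - fd2 + fkc + fc2) / m2
            axb = (fs1 + fs2 + fd1 + fd2 - fsb - fdb) / mb

            if stage == 0:
                d0 = sv1
                d1 = sv2
                d2 = svb
                d3 = ax1
                d4 = ax2
                d5 = axb
            elif stage == 1:
                e0 = sv1
                e1 = sv2
                e2 = svb
                e3 = ax1
                e4 = ax2
                e5 = axb
            elif stage == 2:
                f0 = sv1
                f1 = sv2
                f2 = svb
                f3 = ax1
                f4 = ax2
                f5 = axb
            else:
                g0 = sv1
                g1 = sv2
                g2 = svb
                g3 = ax1
                g4 = ax2
                g5 = axb

        x1 = y0 + dt / 6.0 * (d0 + 2.0 * e0 + 2.0 * f0 + g0)
        x2 = y1 + dt / 6.0 * (d1 + 2.0 * e1 + 2.0 * f1 + g1)
        xb = y2 + dt / 6.0 * (d2 + 2.0 * e2 + 2.0 * f2 + g2)
        v1 = y3 + dt / 6.0 * (d3 + 2.0 * e3 + 2.0 * f3 + g3)
        v2 = y4 + dt / 6.0 * (d4 + 2.0 * e4 + 2.0 * f4 + g4)
        vb = y5 + dt / 6.0 * (d5 + 2.0 * e5 + 2.0 * f5 + g5)

        if not (math.isfinite(x1) and math.isfinite(x2) and math.isfinite(xb)):
            return a_g, u_g, i

    return a_g, u_g, -1


def simulate_vocal_folds(params: BCMParameters, cfg: SimulationConfig) -> GlottalWaveforms:
    """Integrate the three-mass equations of motion.

    Returns the glottal area and flow waveforms sampled at ``cfg.fs_sim``.
    The ``oscillating`` flag is set when the steady-state portion of the
    membranous area shows a peak-to-peak excursion above the documented
    threshold (see :data:`laryngosim.bcm_params.OSC_AREA_THRESHOLD`).
    """
    n = int(round(cfg.duration * cfg.fs_sim))
    ps = np.full(n, float(cfg.P_s))
    a_g, u_g, bad = _bcm_kernel(params.as_array(), ps, float(cfg.fs_sim),
                                P.RHO_AIR)
    if bad >= 0:
        raise SimulationError(
            f"non-finite state at step {bad} (t={bad / cfg.fs_sim:.4f} s); "
            "integration unstable for these parameters")
    t = np.arange(n) / cfg.fs_sim
    w = GlottalWaveforms(t=t, a_g=a_g, U_g=u_g, fs_sim=cfg.fs_sim)
    w.oscillating = _is_oscillating(w, cfg.onset_discard)
    return w


def simulate_vocal_folds_trajectory(
        params_seq: list[BCMParameters], ps_seq: np.ndarray,
        step_duration: float, fs_sim: float = 44100.0) -> GlottalWaveforms:
    """Simulate a whole utterance from a time series of rule evaluations.

    ``params_seq[k]`` and ``ps_seq[k]`` hold for the k-th control step of
    ``step_duration`` seconds; parameters are held constant within a step
    (the fold kinematics carry over, so the waveform stays continuous).
    """
    if len(params_seq) != len(ps_seq):
        raise ValueError("params_seq and ps_seq must have equal length")
    if not params_seq:
        raise ValueError("empty trajectory")
    spb = int(round(step_duration * fs_sim))
    n = spb * len(params_seq)
    par = np.empty((n, 22))
    ps = np.empty(n)
    for k, (p, pres) in enumerate(zip(params_seq, ps_seq)):
        par[k * spb:(k + 1) * spb] = p.as_array()
        ps[k * spb:(k + 1) * spb] = pres
    a_g, u_g, bad = _bcm_kernel(par, ps, float(fs_sim), P.RHO_AIR)
    if bad >= 0:
        raise SimulationError(f"non-finite state at step {bad}")
    t = np.arange(n) / fs_sim
    w = GlottalWaveforms(t=t, a_g=a_g, U_g=u_g, fs_sim=fs_sim)
    w.oscillating = _is_oscillating(w, min(0.2, 0.25 * w.duration))
    return w


def _is_oscillating(w: GlottalWaveforms, onset_discard: float) -> bool:
    i0 = min(int(onset_discard * w.fs_sim), max(len(w.a_g) - 1, 0))
    tail = w.a_g[i0:]
    if len(tail) < 2:
        return False
    return float(tail.max() - tail.min()) > P.OSC_AREA_THRESHOLD


def steady_state_segment(w: GlottalWaveforms, onset_discard: float | None = None) -> GlottalWaveforms:
    """Trailing portion of a waveform with the onset transient removed."""
    if onset_discard is None:
        onset_discard = P.ONSET_DISCARD_DEFAULT
    if onset_discard >= w.duration:
        raise InsufficientDataError(
            f"onset_discard {onset_discard} s >= waveform duration {w.duration} s")
    i0 = int(round(onset_discard * w.fs_sim))
    seg = GlottalWaveforms(t=w.t[i0:], a_g=w.a_g[i0:], U_g=w.U_g[i0:],
                           fs_sim=w.fs_sim, oscillating=w.oscillating)
    if seg.duration < 2.0 / 50.0:  # two periods at the 50 Hz search floor
        raise InsufficientDataError(
            f"steady segment of {seg.duration:.3f} s is shorter than two "
            "periods at 50 Hz")
    return seg
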