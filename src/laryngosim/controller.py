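"""Feedforward/feedback control loop over the laryngeal forward map.

The loop runs on a 5-ms control grid.  At every step the motor command
(mobility state a_CT, a_TA at fixed P_s) is pushed through the forward map
to produce the auditory state; a perturbation in cents may be injected
into the fed-back f_o; the delayed, JND-gated auditory error is inverse
mapped through the Jacobian pseudo-inverse and realized as a feedback
velocity inside the motor integrator; feedforward weights over the motor
reference trajectory are adapted trial-by-trial at rate lambda_ff.

Timing: the perturbation-to-production latency is the configured auditory
loop latency (120 ms by default), split into a sensing leg (acoustic ->
auditory cortex -> motor cortex, padded to 70 ms) and an actuation leg
(motor command -> acoustic effect, 50 ms).

The feedback velocity drives the accumulated corrective command toward
the delayed proportional target g_fb_aud * J^-1 e at a first-order rate
per step; the accumulated correction therefore settles at the fixed point
g/(1+g) of the perturbation, giving the exact half-compensation bound at
g = 1 that the competition between feedforward and feedback commands
implies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acoustics import cents_to_hz, hz_to_cents
from .forward_map import JacobianConfig, LaryngealForwardMap, UnvoicedRegionError

__all__ = [
    "TargetRegion",
    "ControllerGains",
    "DelayConfig",
    "FeedforwardWeights",
    "UtteranceResult",
    "TunedTarget",
    "TuningError",
    "auditory_error",
    "feedback_command",
    "step_motor_command",
    "update_feedforward_weights",
    "run_utterance",
    "tune_target",
    "CONTROL_STEP",
    "FB_INTEGRATION_RATE",
]

CONTROL_STEP = 0.005            # [s] control loop step
FB_INTEGRATION_RATE = 0.15      # first-order realization rate of the
                                # corrective command per control step
FB_CORRECTION_CAP = 0.5         # bound on each corrective-command component
                                # [activation units]; keeps inverse-map steps
                                # through flat-slope map regions bounded
DEFAULT_UTTERANCE_MS = 3050.0   # sustained-vowel utterance duration


class TuningError(RuntimeError):
    """Target tuning failed to converge or baseline misses the region."""


@dataclass(frozen=True)
class ControllerGains:
    """Gain set of the control loop; all in [0, 1]."""

    g_fb_aud: float = 0.5
    g_fb_somat: float = 0.0
    g_ff_total: float = 1.0
    g_fb_total: float = 1.0
    lambda_ff: float = 0.1

    def __post_init__(self) -> None:
        for name in ("g_fb_aud", "g_fb_somat", "g_ff_total", "g_fb_total",
                     "lambda_ff"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class DelayConfig:
    """Intrinsic delays [s]; all must be multiples of the control step.

    The component delays follow the cortical-transmission values of the
    control architecture; ``loop_latency_aud`` is the effective
    perturbation-to-production latency the loop is padded to.
    """

    tau_aum: float = 0.005        # auditory error map -> motor cortex
    tau_som: float = 0.005        # somatosensory error map -> motor cortex
    tau_prem: float = 0.005       # premotor -> motor cortex
    tau_moac: float = 0.050       # motor command -> acoustic effect
    tau_acau: float = 0.050       # acoustics -> auditory cortex
    tau_socortex: float = 0.020   # periphery -> somatosensory cortex
    tau_learnt_aud: float = 0.055
    tau_learnt_som: float = 0.025
    tau_learned: float = 0.055    # motor state delay at the inverse map
    loop_latency_aud: float = 0.120
    control_step: float = CONTROL_STEP

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
            steps = v / self.control_step
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(f"{name}={v} not a multiple of the "
                                 f"{self.control_step*1e3:.0f}-ms control step")
        if self.loop_latency_aud < self.tau_moac + self.tau_acau + self.tau_aum:
            raise ValueError("loop latency shorter than the component delays")

    @property
    def actuation_steps(self) -> int:
        """Motor-to-acoustic leg in control steps."""
        return int(round(self.tau_moac / self.control_step))

    @property
    def sensing_steps(self) -> int:
        """Acoustic-to-corrective-command leg, padded so that the full
        loop equals ``loop_latency_aud``."""
        return int(round(self.loop_latency_aud / self.control_step)) - self.actuation_steps


@dataclass
class TargetRegion:
    """Min/max trajectories for (f_o, SPL) with JND = region half-width.

    Errors are gated by the region (dead zone) and referenced to the
    region midpoint once the produced value leaves it; a point target
    (min == max) yields the plain midpoint error.
    """

    f_min: np.ndarray      # [Hz] per control step
    f_max: np.ndarray
    spl_min: np.ndarray    # [dB]
    spl_max: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.f_min)
        if not (len(self.f_max) == len(self.spl_min) == len(self.spl_max) == n):
            raise ValueError("target trajectories must share length")
        if np.any(self.f_min > self.f_max) or np.any(self.spl_min > self.spl_max):
            raise ValueError("min trajectory above max trajectory")

    @property
    def n_steps(self) -> int:
        return len(self.f_min)

    @classmethod
    def sustained(cls, baseline_hz: float, n_steps: int,
                  half_width_cents: float = 5.0,
                  spl_range: tuple[float, float] = (68.0, 80.0)) -> "TargetRegion":
        """Sustained-vowel region: baseline +/- half_width_cents, fixed SPL band."""
        lo = cents_to_hz(-half_width_cents, baseline_hz)
        hi = cents_to_hz(+half_width_cents, baseline_hz)
        ones = np.ones(n_steps)
        return cls(f_min=lo * ones, f_max=hi * ones,
                   spl_min=spl_range[0] * ones, spl_max=spl_range[1] * ones)

    @classmethod
    def point_contour(cls, f_hz: np.ndarray,
                      spl_range: tuple[float, float] = (68.0, 80.0)) -> "TargetRegion":
        """Point trajectory in f_o (min == max), used for prosodic contours."""
        f = np.asarray(f_hz, dtype=float)
        ones = np.ones(len(f))
        return cls(f_min=f.copy(), f_max=f.copy(),
                   spl_min=spl_range[0] * ones, spl_max=spl_range[1] * ones)


def auditory_error(target: TargetRegion, f_o: float | None, spl: float,
                   step: int) -> tuple[np.ndarray, bool]:
    """JND-gated auditory error (f_o [Hz], SPL [dB]) at a control step.

    Inside the target region the error is zero; outside it is the distance
    to the region midpoint (full detected error).  An undefined f_o
    (unvoiced) contributes zero error and raises the unvoiced flag.
    """
    e = np.zeros(2)
    unvoiced = f_o is None
    if not unvoiced:
        lo, hi = target.f_min[step], target.f_max[step]
        if not (lo <= f_o <= hi):
            e[0] = 0.5 * (lo + hi) - f_o
    lo, hi = target.spl_min[step], target.spl_max[step]
    if not (lo <= spl <= hi):
        e[1] = 0.5 * (lo + hi) - spl
    return e, unvoiced


def feedback_command(e_aud: np.ndarray, fmap: LaryngealForwardMap,
                     x: np.ndarray, gains: ControllerGains,
                     jc: JacobianConfig | None = None) -> np.ndarray:
    """Mobility-space corrective command g_fb_aud * J^-1(x) e_aud.

    Returns the zero command when the state is unvoiced (no usable error
    signal there).  The somatosensory twin is handled by the caller with
    g_fb_somat (zero by default: no laryngeal somatosensory map).
    """
    if gains.g_fb_aud == 0.0 or not np.any(e_aud):
        return np.zeros(2)
    try:
        j_inv = fmap.jacobian_inverse(x, jc)
    except UnvoicedRegionError:
        return np.zeros(2)
    return gains.g_fb_aud * (j_inv @ e_aud)[:2]


def step_motor_command(ff: np.ndarray, fb_aud_vel: np.ndarray,
                       fb_somat_vel: np.ndarray, gains: ControllerGains,
                       integral_state: np.ndarray,
                       dt: float = CONTROL_STEP) -> tuple[np.ndarray, np.ndarray]:
    """One discrete step of the motor command combination.

    The feedback velocities are accumulated (rectangle rule) into the
    integral state; the next motor command is the feedforward command plus
    g_fb_total times the accumulated correction.  Returns (command,
    updated integral state).
    """
    integral = integral_state + (fb_aud_vel + fb_somat_vel) * dt
    return ff + gains.g_fb_total * integral, integral


@dataclass
class FeedforwardWeights:
    """Per-step multiplicative weights on the motor reference trajectory."""

    w: np.ndarray          # shape (n_steps, 2)

    @classmethod
    def unit(cls, n_steps: int) -> "FeedforwardWeights":
        return cls(w=np.ones((n_steps, 2)))

    def copy(self) -> "FeedforwardWeights":
        return FeedforwardWeights(w=self.w.copy())


def update_feedforward_weights(weights: FeedforwardWeights,
                               e_motor_x: np.ndarray,
                               r_motor: np.ndarray,
                               lambda_ff: float,
                               gate: np.ndarray | None = None,
                               bounds: tuple[np.ndarray, np.ndarray] | None = None,
                               ) -> FeedforwardWeights:
    """Trial-end weight update Delta w = lambda_ff * e_motor(x) * gate.

    ``e_motor_x`` is the per-step mobility-space error trajectory
    (n_steps, 2); the multiplicative weight increment is the additive
    mobility correction divided by the (guarded) reference trajectory.
    lambda_ff = 0 or a zero error leaves the weights untouched.

    ``bounds`` (lo, hi activation vectors) projects the weighted command
    w*r back into the realizable activation range: commands saturate at
    the physical bounds, so persistent errors against a saturated command
    cannot wind the weights up indefinitely.
    """
    if lambda_ff == 0.0 or not np.any(e_motor_x):
        return weights.copy()
    g = np.ones(len(weights.w)) if gate is None else np.asarray(gate, float)
    denom = np.where(np.abs(r_motor) < 1e-3, np.sign(r_motor + 1e-12) * 1e-3,
                     r_motor)
    new = weights.w + lambda_ff * (e_motor_x / denom) * g[:, None]
    if bounds is not None:
        lo, hi = bounds
        cmd = np.clip(new * r_motor, lo, hi)
        new = cmd / denom
    return FeedforwardWeights(w=new)


@dataclass
class TunedTarget:
    """A tuned speech-sound: motor reference, weights, targets, baseline."""

    r_motor: np.ndarray            # (n_steps, 2) mobility reference
    weights: FeedforwardWeights
    region: TargetRegion
    baseline_f0: float             # produced f_o of the tuned no-pert utterance
    ps: float = 800.0
    iterations: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.r_motor)


@dataclass
class UtteranceResult:
    """Per-5-ms-step record of one utterance simulation."""

    t_ms: np.ndarray
    x_cmd: np.ndarray          # motor command (n, 2)
    x_eff: np.ndarray          # state in effect at the folds (n, 2)
    f_produced: np.ndarray     # [Hz]; NaN when unvoiced
    spl_produced: np.ndarray   # [dB]
    f_heard: np.ndarray        # post-perturbation auditory state [Hz]
    pert_cents: np.ndarray
    e_aud: np.ndarray          # (n, 2) delayed, gated auditory error
    e_motor_x: np.ndarray      # (n, 2) inverse-mapped (mobility) error
    fb_correction: np.ndarray  # (n, 2) accumulated corrective command
    ff_motor: np.ndarray       # (n, 2)
    unvoiced: np.ndarray       # bool flags on the error signal
    clamped_steps: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t_ms,
            "a_CT_cmd": self.x_cmd[:, 0],
            "a_TA_cmd": self.x_cmd[:, 1],
            "a_CT": self.x_eff[:, 0],
            "a_TA": self.x_eff[:, 1],
            "f_o_hz": self.f_produced,
            "spl_db": self.spl_produced,
            "f_heard_hz": self.f_heard,
            "pert_cents": self.pert_cents,
            "e_f_hz": self.e_aud[:, 0],
            "e_spl_db": self.e_aud[:, 1],
        })

    def produced_cents(self, baseline_hz: float) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return 1200.0 * np.log2(self.f_produced / baseline_hz)


def run_utterance(sound: TunedTarget, gains: ControllerGains,
                  delays: DelayConfig, pert_cents: np.ndarray | float,
                  fmap: LaryngealForwardMap,
                  jc: JacobianConfig | None = None,
                  weights: FeedforwardWeights | None = None,
                  production_noise: np.ndarray | None = None,
                  check_tuning: bool = False) -> UtteranceResult:
    """Simulate one utterance through the 5-ms control loop.

    ``pert_cents`` is a scalar or per-step schedule applied to the fed-back
    f_o.  ``production_noise`` (optional, shape (2,)) offsets the
    feedforward activations for the whole trial.  Vocal-fold kinematics
    are implicit in the forward map, so every trial starts from identical
    initial conditions by construction.
    """
    n = sound.n_steps
    pert = np.broadcast_to(np.asarray(pert_cents, dtype=float), (n,)).copy() \
        if np.ndim(pert_cents) else np.full(n, float(pert_cents))
    weights = weights or sound.weights
    jc = jc or JacobianConfig()

    d_act = delays.actuation_steps
    d_sense = delays.sensing_steps

    ff = gains.g_ff_total * sound.r_motor * weights.w
    if production_noise is not None:
        ff = ff + production_noise

    x_cmd = np.zeros((n, 2))
    x_eff = np.zeros((n, 2))
    f_prod = np.full(n, np.nan)
    spl_prod = np.zeros(n)
    f_heard = np.full(n, np.nan)
    e_hist = np.zeros((n, 2))
    e_x_hist = np.zeros((n, 2))
    corr_hist = np.zeros((n, 2))
    unvoiced_flags = np.zeros(n, dtype=bool)

    lo = np.array([fmap.a_ct[0], fmap.a_ta[0]])
    hi = np.array([fmap.a_ct[-1], fmap.a_ta[-1]])
    clamped = 0

    correction = np.zeros(2)
    integral = np.zeros(2)
    alpha = FB_INTEGRATION_RATE

    for i in range(n):
        # ---- error from the delayed auditory feedback ------------------
        j = i - d_sense
        if j >= 0 and not math.isnan(f_heard[j]):
            e, unv = auditory_error(sound.region,
                                    None if math.isnan(f_heard[j]) else f_heard[j],
                                    spl_prod[j], j)
            unvoiced_flags[i] = unv
        elif j >= 0:
            e = np.zeros(2)
            unvoiced_flags[i] = True
        else:
            e = np.zeros(2)
        e_hist[i] = e

        # ---- feedback velocity realizing the corrective command --------
        x_state = np.array([x_eff[max(j, 0), 0], x_eff[max(j, 0), 1], sound.ps])
        if np.any(e):
            try:
                e_x_hist[i] = (fmap.jacobian_inverse(x_state, jc) @ e)[:2]
            except UnvoicedRegionError:
                pass
        fb_target = np.clip(gains.g_fb_aud * e_x_hist[i],
                            -FB_CORRECTION_CAP, FB_CORRECTION_CAP)
        # (somatosensory twin: gains.g_fb_somat is zero in this version)
        fb_vel = alpha * (fb_target - correction) / delays.control_step
        x_cmd[i], integral = step_motor_command(ff[i], fb_vel, np.zeros(2),
                                                gains, integral,
                                                delays.control_step)
        correction = gains.g_fb_total * integral
        corr_hist[i] = correction

        # ---- plant ------------------------------------------------------
        # the feedforward program is read out on the production timeline
        # (premotor preparation leads the acoustics); corrective commands
        # reach the folds one actuation delay after being issued
        xe = ff[i] + (corr_hist[i - d_act] if i >= d_act else np.zeros(2))
        xe_cl = np.clip(xe, lo, hi)
        if np.any(xe_cl != xe):
            clamped += 1
        x_eff[i] = xe_cl
        f, spl = fmap.lookup(xe_cl[0], xe_cl[1], sound.ps)
        spl_prod[i] = spl
        if f is not None:
            f_prod[i] = f
            f_heard[i] = f * 2.0 ** (pert[i] / 1200.0)

    if check_tuning:
        pre = f_prod[:max(d_sense + d_act, 8)]
        pre = pre[~np.isnan(pre)]
        if len(pre) == 0 or not (
                np.all(pre >= sound.region.f_min[0] - 1e-9)
                and np.all(pre <= sound.region.f_max[0] + 1e-9)):
            raise TuningError("baseline production outside the target region; "
                              "tune the target first")

    return UtteranceResult(
        t_ms=np.arange(n) * delays.control_step * 1e3,
        x_cmd=x_cmd, x_eff=x_eff, f_produced=f_prod, spl_produced=spl_prod,
        f_heard=f_heard, pert_cents=pert, e_aud=e_hist, e_motor_x=e_x_hist,
        fb_correction=corr_hist, ff_motor=ff, unvoiced=unvoiced_flags,
        clamped_steps=clamped)


def aligned_motor_error(res: UtteranceResult, delays: DelayConfig) -> np.ndarray:
    """Mobility-space error re-aligned to the commands that caused it.

    The error recorded at step i reflects the production one sensing leg
    earlier, i.e. the feedforward program step i - d_sense; learning must
    credit that step (the tau_learnt bookkeeping), so the trajectory is
    shifted back accordingly with a zero tail.
    """
    d = delays.sensing_steps
    out = np.zeros_like(res.e_motor_x)
    if d < len(out):
        out[:len(out) - d] = res.e_motor_x[d:]
    return out


def invert_f0_along_act(fmap: LaryngealForwardMap, f_hz: float,
                        a_ta: float, ps: float,
                        resolution: float = 0.002) -> float:
    """a_CT whose map f_o at fixed (a_TA, P_s) is closest to ``f_hz``.

    Scans the smoothed a_CT axis; used to seed motor trajectories for
    contour targets before learning polishes them.
    """
    grid = np.arange(fmap.a_ct[0], fmap.a_ct[-1] + 1e-12, resolution)
    best, best_err = float(fmap.a_ct[0]), np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ct in grid:
            f, _ = fmap.lookup(float(ct), a_ta, ps)
            if f is None:
                continue
            err = abs(f - f_hz)
            if err < best_err:
                best, best_err = float(ct), err
    return best


def _center_error_trajectory(sound: TunedTarget, res: UtteranceResult) -> np.ndarray:
    """Midpoint-referenced f_o error per step [Hz] (for tuning updates)."""
    mid = 0.5 * (sound.region.f_min + sound.region.f_max)
    e = mid - res.f_produced
    return np.nan_to_num(e, nan=0.0)


def tune_target(f_target_hz: np.ndarray | float, fmap: LaryngealForwardMap,
                gains: ControllerGains | None = None,
                delays: DelayConfig | None = None,
                x0: tuple[float, float] = (0.169, 0.175),
                ps: float = 800.0,
                n_steps: int | None = None,
                half_width_cents: float = 5.0,
                point_target: bool = False,
                tol_cents: float = 1.0,
                max_iter: int = 60,
                jc: JacobianConfig | None = None) -> TunedTarget:
    """Iteratively tune motor weights until the produced contour lies in
    the target region (or within ``tol_cents`` of a point target).

    The desired contour may be a constant (sustained vowel) or a per-step
    trajectory.  Raises :class:`TuningError` with the residual profile on
    non-convergence.
    """
    gains = gains or ControllerGains()
    delays = delays or DelayConfig()
    jc = jc or JacobianConfig()

    if np.ndim(f_target_hz) == 0:
        if n_steps is None:
            n_steps = int(round(DEFAULT_UTTERANCE_MS / 1e3 / delays.control_step))
        contour = np.full(n_steps, float(f_target_hz))
    else:
        contour = np.asarray(f_target_hz, dtype=float)
        n_steps = len(contour)

    if point_target:
        region = TargetRegion.point_contour(contour)
    else:
        region = TargetRegion(
            f_min=contour * 2.0 ** (-half_width_cents / 1200.0),
            f_max=contour * 2.0 ** (+half_width_cents / 1200.0),
            spl_min=np.full(n_steps, 68.0), spl_max=np.full(n_steps, 80.0))

    r_motor = np.tile(np.asarray(x0, dtype=float), (n_steps, 1))
    if point_target:
        # seed the motor trajectory by inverting the map along a_CT at the
        # initialization's a_TA; learning then polishes the residual
        grid = np.arange(fmap.a_ct[0], fmap.a_ct[-1] + 1e-12, 0.002)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_row = np.array([
                (lambda fv: np.nan if fv[0] is None else fv[0])(
                    fmap.lookup(float(ct), x0[1], ps))
                for ct in grid])
        valid = ~np.isnan(f_row)
        for t in range(n_steps):
            k = np.argmin(np.abs(np.where(valid, f_row, np.inf) - contour[t]))
            r_motor[t, 0] = grid[k]
    sound = TunedTarget(r_motor=r_motor, weights=FeedforwardWeights.unit(n_steps),
                        region=region, baseline_f0=float(contour[0]), ps=ps)

    lam = gains.lambda_ff if gains.lambda_ff > 0 else 0.5
    # learning iterations run open-loop (feedback off): the online
    # correction lags sloped targets by the loop latency and its transient
    # would be imprinted into the weights; once the feedforward program is
    # converged the engaged loop has (almost) no error left to act on
    gains_tune = replace(gains, g_fb_aud=0.0)
    residual = np.inf
    for it in range(1, max_iter + 1):
        res = run_utterance(sound, gains_tune, delays, 0.0, fmap, jc=jc)
        e_f = _center_error_trajectory(sound, res)
        with np.errstate(invalid="ignore", divide="ignore"):
            res_cents = 1200.0 * np.log2(
                np.where(np.isnan(res.f_produced), contour, res.f_produced)
                / contour)
        residual = float(np.max(np.abs(res_cents)))
        ok = residual <= tol_cents if point_target else np.all(
            (res.f_produced >= region.f_min - 1e-9)
            & (res.f_produced <= region.f_max + 1e-9)
            | np.isnan(res.f_produced))
        if ok and not np.isnan(res.f_produced).all():
            base = float(np.nanmean(res.f_produced))
            return replace(sound, baseline_f0=base, iterations=it)
        # mobility-space error per step through the Jacobian inverse.
        # Steps are trust-region-limited so flat-slope regions cannot
        # catapult the command into the unvoiced corner, and unvoiced
        # productions retreat toward the (voiced) motor reference.
        step_cap = 0.08
        e_x = np.zeros((n_steps, 2))
        for t in range(n_steps):
            t_prod = t
            if math.isnan(res.f_produced[t_prod]):
                e_x[t] = (sound.r_motor[t] - res.x_cmd[t]) / lam
                continue
            if e_f[t_prod] == 0.0:
                continue
            x_state = np.array([res.x_eff[t_prod, 0], res.x_eff[t_prod, 1], ps])
            try:
                j_inv = fmap.jacobian_inverse(x_state, jc)
            except UnvoicedRegionError:
                continue
            e_x[t] = np.clip((j_inv @ np.array([e_f[t_prod], 0.0]))[:2],
                             -step_cap, step_cap)
        bounds = (np.array([fmap.a_ct[0], fmap.a_ta[0]]),
                  np.array([fmap.a_ct[-1], fmap.a_ta[-1]]))
        sound = replace(sound, weights=update_feedforward_weights(
            sound.weights, e_x, sound.r_motor, lam, bounds=bounds))
    raise TuningError(f"no convergence in {max_iter} iterations; "
                      f"max residual {residual:.2f} cents")
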