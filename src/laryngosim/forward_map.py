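"""Tabulated auditory forward map and its regularized Jacobian inverse.

The forward map F{x} tabulates the steady-state auditory consequences
(f_o [Hz], SPL [dB]) of every mobility-space node (a_CT, a_TA, P_s),
each node obtained from a direct vocal-fold simulation.  Lookup is
(tri)linear interpolation inside the voiced region; unvoiced nodes carry
NaN f_o and propagate to undefined lookups.  The Jacobian inverse maps
small auditory errors to mobility corrections by finite differences on
the map followed by a damped (Tikhonov) least-squares pseudo-inverse:

    S[:, d] = F(x + xi e_d) - F(x)          (sensitivity per dimension)
    J(y)    = S S^T                          (task-space Gram matrix)
    J^-1(x) = xi S^T [J(y) + gamma xi^2 I]^+

which for gamma -> 0 approaches the Moore-Penrose pseudo-inverse of the
finite-difference Jacobian S/xi.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import bcm_params
from .acoustics import compute_spl, estimate_f0
from .bcm_core import (MuscleActivation, SimulationConfig, activation_to_params,
                       simulate_vocal_folds, steady_state_segment)

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "LaryngealForwardMap",
    "JacobianConfig",
    "UnvoicedRegionError",
    "IllConditionedError",
    "build_forward_map",
]


class UnvoicedRegionError(ValueError):
    """Jacobian or lookup requested where the map is unvoiced."""


class IllConditionedError(np.linalg.LinAlgError):
    """Unregularized inversion of a singular sensitivity system."""


@dataclass(frozen=True)
class GridSpec:
    """Axes of the forward-map grid.

    Activation axes span [0, 1] with a coarse (simulated) step of 0.02 and
    a smoothed (interpolated) step of 0.001; the pressure axis spans
    [10, 2010] Pa with steps of 100 / 5 Pa.  Reduced grids for fast runs
    are expressed through the same fields.  ``ps_values`` may hold a single
    pressure, collapsing the map to a constant-P_s slice.
    """

    a_ct_min: float = 0.0
    a_ct_max: float = 1.0
    a_ct_step: float = 0.02
    a_ta_min: float = 0.0
    a_ta_max: float = 1.0
    a_ta_step: float = 0.02
    ps_min: float = 10.0
    ps_max: float = 2010.0
    ps_step: float = 100.0
    smoothed_act_step: float = 0.001
    smoothed_ps_step: float = 5.0
    ps_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for lo, hi, st in ((self.a_ct_min, self.a_ct_max, self.a_ct_step),
                           (self.a_ta_min, self.a_ta_max, self.a_ta_step)):
            if hi <= lo or st <= 0:
                raise ValueError("activation axis must be increasing with positive step")
        if self.ps_values is None and (self.ps_max <= self.ps_min or self.ps_step <= 0):
            raise ValueError("pressure axis must be increasing with positive step")
        if self.ps_values is not None:
            object.__setattr__(self, "ps_values",
                               tuple(float(v) for v in self.ps_values))

    def axis_a_ct(self) -> np.ndarray:
        n = int(round((self.a_ct_max - self.a_ct_min) / self.a_ct_step))
        return self.a_ct_min + self.a_ct_step * np.arange(n + 1)

    def axis_a_ta(self) -> np.ndarray:
        n = int(round((self.a_ta_max - self.a_ta_min) / self.a_ta_step))
        return self.a_ta_min + self.a_ta_step * np.arange(n + 1)

    def axis_ps(self) -> np.ndarray:
        if self.ps_values is not None:
            return np.asarray(self.ps_values, dtype=float)
        n = int(round((self.ps_max - self.ps_min) / self.ps_step))
        return self.ps_min + self.ps_step * np.arange(n + 1)

    @classmethod
    def test_grid(cls, ps: float = 800.0) -> "GridSpec":
        """Reduced slice grid over the modal operating region."""
        return cls(a_ct_min=0.0, a_ct_max=0.6, a_ct_step=0.05,
                   a_ta_min=0.0, a_ta_max=0.7, a_ta_step=0.05,
                   ps_values=(ps,))


@dataclass(frozen=True)
class JacobianConfig:
    """Finite-difference step and Tikhonov factor for the inverse map."""

    xi: float = 0.01
    gamma: float = 2.0
    include_ps: bool = False    # P_s held by respiration, not corrected
    jnd_f0_hz: float = 0.39     # 5 cents at the 134-Hz modal baseline
    jnd_spl_db: float = 6.0     # half-width of the 68-80 dB target band

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class LaryngealForwardMap:
    """Tabulated F{x}: (a_CT, a_TA, P_s) -> (f_o, SPL) with voicing mask."""

    a_ct: np.ndarray
    a_ta: np.ndarray
    ps: np.ndarray
    f_o: np.ndarray        # NaN where unvoiced
    spl: np.ndarray
    voiced: np.ndarray     # bool
    provenance: str = ""

    def __post_init__(self) -> None:
        shape = (len(self.a_ct), len(self.a_ta), len(self.ps))
        for name in ("f_o", "spl", "voiced"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} table shape {getattr(self, name).shape} "
                                 f"!= axes shape {shape}")
        if not np.array_equal(self.voiced, ~np.isnan(self.f_o)):
            raise ValueError("voicing mask must match defined f_o entries")

    # ------------------------------------------------------------- lookup
    def _clamp(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([self.a_ct[0], self.a_ta[0], self.ps[0]])
        hi = np.array([self.a_ct[-1], self.a_ta[-1], self.ps[-1]])
        xc = np.clip(x, lo, hi)
        if np.any(xc != x):
            warnings.warn(f"mobility state {x} clamped to grid range", stacklevel=3)
        return xc

    def _interp(self, table: np.ndarray, x: np.ndarray) -> float:
        """Trilinear interpolation; NaN corners propagate to NaN."""
        idx = []
        frac = []
        for axis, v in zip((self.a_ct, self.a_ta, self.ps), x):
            if len(axis) == 1:
                idx.append(0)
                frac.append(0.0)
                continue
            i = int(np.searchsorted(axis, v, side="right") - 1)
            i = min(max(i, 0), len(axis) - 2)
            idx.append(i)
            frac.append((v - axis[i]) / (axis[i + 1] - axis[i]))
        out = 0.0
        for corner in range(8):
            w = 1.0
            pos = []
            for d in range(3):
                bit = (corner >> d) & 1
                if len((self.a_ct, self.a_ta, self.ps)[d]) == 1:
                    if bit:
                        w = 0.0
                    pos.append(0)
                    continue
                pos.append(idx[d] + bit)
                w *= frac[d] if bit else (1.0 - frac[d])
            if w == 0.0:
                continue
            out += w * table[pos[0], pos[1], pos[2]]
        return float(out)

    def lookup(self, a_ct: float, a_ta: float, ps: float) -> tuple[float | None, float]:
        """(f_o, SPL) at a mobility point; f_o None in/near unvoiced cells."""
        x = self._clamp(np.array([a_ct, a_ta, ps], dtype=float))
        f = self._interp(self.f_o, x)
        s = self._interp(self.spl, x)
        return (None if np.isnan(f) else f), s

    def is_voiced(self, a_ct: float, a_ta: float, ps: float) -> bool:
        f, _ = self.lookup(a_ct, a_ta, ps)
        return f is not None

    # ----------------------------------------------------------- jacobian
    def jacobian_inverse(self, x: np.ndarray, jc: JacobianConfig | None = None) -> np.ndarray:
        """Damped least-squares inverse mapping auditory errors (Hz, dB)
        to mobility corrections at state ``x`` = (a_CT, a_TA, P_s).

        Returns an (n_dims, 2) matrix, n_dims = 2 or 3 depending on
        ``jc.include_ps``.  Raises :class:`UnvoicedRegionError` if the
        state or any xi-perturbed probe falls in the unvoiced region.
        """
        jc = jc or JacobianConfig()
        x = np.asarray(x, dtype=float)
        base = self.lookup(*x)
        if base[0] is None:
            raise UnvoicedRegionError(f"state {x} is unvoiced")
        y0 = np.array([base[0], base[1]])
        ndim = 3 if jc.include_ps else 2
        steps = [jc.xi, jc.xi, jc.xi * 1000.0][:ndim]  # Pa-scale step for P_s
        S = np.empty((2, ndim))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # probe clamping is expected
            for d in range(ndim):
                xp = x.copy()
                xp[d] += steps[d]
                yp = self.lookup(*xp)
                if yp[0] is None:
                    xp[d] = x[d] - steps[d]     # fall back to a backward probe
                    yp = self.lookup(*xp)
                    if yp[0] is None:
                        raise UnvoicedRegionError(
                            f"xi-probe along dim {d} at {xp} is unvoiced")
                    S[:, d] = (y0 - np.array([yp[0], yp[1]])) / 1.0
                else:
                    S[:, d] = (np.array([yp[0], yp[1]]) - y0) / 1.0
        # normalize steps so S corresponds to a uniform xi step per dim
        S *= jc.xi / np.asarray(steps)
        # task dimensions are weighted by their perceptual salience (the
        # JND per dimension), so a 1-JND error contributes equally in f_o
        # and SPL and the weakly-sensed SPL direction is properly damped
        W = np.diag(1.0 / np.array([jc.jnd_f0_hz, jc.jnd_spl_db]))
        S_n = W @ S
        J_y = S_n @ S_n.T
        damped = J_y + jc.gamma * jc.xi ** 2 * np.eye(2)
        if jc.gamma == 0.0:
            cond = np.linalg.cond(damped)
            if not np.isfinite(cond) or cond > 1e12:
                raise IllConditionedError(
                    "sensitivity system is singular with gamma = 0; "
                    "use gamma > 0 for a damped inverse")
        inv = np.linalg.pinv(damped)
        return jc.xi * S_n.T @ inv @ W

    # -------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"),
                            a_ct=self.a_ct, a_ta=self.a_ta, ps=self.ps,
                            f_o=self.f_o, spl=self.spl, voiced=self.voiced)
        sidecar = {
            "provenance": self.provenance,
            "axes": {"a_ct": len(self.a_ct), "a_ta": len(self.a_ta),
                     "ps": len(self.ps)},
            "voiced_fraction": float(self.voiced.mean()),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LaryngealForwardMap":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        sidecar = path.with_suffix(".json")
        prov = ""
        if sidecar.exists():
            prov = json.loads(sidecar.read_text()).get("provenance", "")
        return cls(a_ct=data["a_ct"], a_ta=data["a_ta"], ps=data["ps"],
                   f_o=data["f_o"], spl=data["spl"], voiced=data["voiced"],
                   provenance=prov)


def _provenance_hash(spec: GridSpec) -> str:
    payload = json.dumps({"grid": asdict(spec),
                          "params": bcm_params.as_dict()},
                         sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_forward_map(spec: GridSpec | None = None, *,
                      duration: float = 0.5,
                      onset_discard: float = 0.2,
                      a_lc: float = 0.5,
                      condition_tables: bool = True,
                      progress: bool = False) -> LaryngealForwardMap:
    """Simulate every coarse node to steady state and tabulate (f_o, SPL).

    A node whose simulation fails or does not sustain oscillation is
    recorded as unvoiced (NaN f_o) with a logged warning, never a crash.
    Smoothed-step queries are served by linear interpolation at lookup
    time, so only the coarse nodes are simulated.
    """
    spec = spec or GridSpec()
    ax_ct, ax_ta, ax_ps = spec.axis_a_ct(), spec.axis_a_ta(), spec.axis_ps()
    shape = (len(ax_ct), len(ax_ta), len(ax_ps))
    f_o = np.full(shape, np.nan)
    spl = np.full(shape, np.nan)
    voiced = np.zeros(shape, dtype=bool)

    iterator = enumerate(ax_ct)
    for i, ct in iterator:
        if progress:
            print(f"  forward map row {i + 1}/{len(ax_ct)}", flush=True)
        for j, ta in enumerate(ax_ta):
            params = activation_to_params(MuscleActivation(ct, ta, a_lc))
            for k, ps in enumerate(ax_ps):
                try:
                    cfg = SimulationConfig(P_s=ps, duration=duration,
                                           onset_discard=onset_discard)
                    w = simulate_vocal_folds(params, cfg)
                    seg = steady_state_segment(w, onset_discard)
                    s = compute_spl(seg)
                    f = estimate_f0(seg) if w.oscillating else None
                except Exception as exc:  # unstable node -> unvoiced
                    logger.warning("node (%.3f, %.3f, %.0f Pa) failed: %s",
                                   ct, ta, ps, exc)
                    continue
                spl[i, j, k] = s
                if f is not None:
                    f_o[i, j, k] = f
                    voiced[i, j, k] = True
    # SPL of failed nodes: fill with the quietest computed level so the
    # table stays finite (they are unvoiced and never drive control)
    if np.isnan(spl).any():
        spl[np.isnan(spl)] = np.nanmin(spl)
    if condition_tables:
        spl = _condition_table(spl, voiced)
        f_o = _condition_table(f_o, voiced)
    return LaryngealForwardMap(a_ct=ax_ct, a_ta=ax_ta, ps=ax_ps,
                               f_o=f_o, spl=spl, voiced=voiced,
                               provenance=_provenance_hash(spec))


def _condition_table(table: np.ndarray, voiced: np.ndarray) -> np.ndarray:
    """Voiced-aware 3-node box smoothing over the activation axes.

    Both output surfaces carry node-scale roughness where the oscillation
    changes regime between neighbouring nodes (waveform-shape ridges in
    SPL, mode-locking wiggle in f_o); a light local average conditions
    the tables for interpolation and finite differencing.  Unvoiced
    entries are untouched and excluded from the averages.
    """
    from scipy import ndimage

    out = table.copy()
    for k in range(table.shape[2]):
        v = voiced[:, :, k].astype(float)
        if not v.any():
            continue
        num = ndimage.uniform_filter(np.nan_to_num(table[:, :, k]) * v,
                                     size=3, mode="nearest")
        den = ndimage.uniform_filter(v, size=3, mode="nearest")
        out[:, :, k] = np.where(v > 0, num / np.maximum(den, 1e-12),
                                table[:, :, k])
    return out
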