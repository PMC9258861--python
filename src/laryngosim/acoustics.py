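"""Auditory task-space variables from glottal waveforms.

f_o by autocorrelation (peak in the 50-500 Hz range, parabolic and
lag-multiple refinement), SPL from the radiated-pressure surrogate
20*log10(rms(Z_v * dU_g) / 2e-5), cents/Hz conversions, and synthesis of
audio through a fixed single-vowel all-pole filter.

The SPL derivative dU_g is the per-sample first difference of the glottal
flow, i.e. the time derivative referenced to the simulation sampling
interval (SPL_FS_REF = 44.1 kHz).  This is the convention under which a
male modal voice at P_s = 800 Pa sits in the low-to-mid 70 dB range; an
absolute (per-second) derivative would shift every level by a constant
+20*log10(fs) dB without affecting any controller behaviour.
"""

from __future__ import annotations

import math
import wave
from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import bcm_params as P
from .bcm_core import GlottalWaveforms, InsufficientDataError

__all__ = [
    "AuditoryState",
    "UndefinedSPLError",
    "estimate_f0",
    "compute_spl",
    "auditory_state",
    "hz_to_cents",
    "cents_to_hz",
    "vowel_filter_coefficients",
    "synthesize_utterance",
    "synthesizer_flow",
    "write_wav",
]

F0_SEARCH_MIN = 50.0
F0_SEARCH_MAX = 500.0

#: formant frequencies / bandwidths (Hz) for the fixed /a/ vowel filter
VOWEL_A_FORMANTS = ((700.0, 60.0), (1220.0, 70.0), (2600.0, 110.0))


class UndefinedSPLError(ValueError):
    """SPL requested for an all-zero (silent) flow segment."""


@dataclass(frozen=True)
class AuditoryState:
    """Auditory task-space point: (f_o [Hz] or None when unvoiced, SPL [dB])."""

    f_o: float | None
    spl: float

    def __post_init__(self) -> None:
        if self.f_o is not None and not (F0_SEARCH_MIN <= self.f_o <= F0_SEARCH_MAX):
            raise ValueError(f"f_o={self.f_o} outside the [{F0_SEARCH_MIN:g}, "
                             f"{F0_SEARCH_MAX:g}] Hz search range")
        if not math.isfinite(self.spl):
            raise ValueError("SPL must be finite")


def hz_to_cents(f: float, f_ref: float) -> float:
    """Pitch offset of ``f`` relative to ``f_ref``: 1200*log2(f/f_ref)."""
    if f <= 0 or f_ref <= 0:
        raise ValueError("frequencies must be positive")
    return 1200.0 * math.log2(f / f_ref)


def cents_to_hz(c: float, f_ref: float) -> float:
    """Inverse of :func:`hz_to_cents`."""
    if f_ref <= 0:
        raise ValueError("reference frequency must be positive")
    return f_ref * 2.0 ** (c / 1200.0)


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    X = np.fft.rfft(x, nfft)
    r = np.fft.irfft(X * np.conj(X), nfft)[:n]
    return r


def _parabolic_peak(r: np.ndarray, i: int) -> float:
    """Sub-sample peak location around index i by parabolic interpolation."""
    if i <= 0 or i >= len(r) - 1:
        return float(i)
    denom = r[i - 1] - 2.0 * r[i] + r[i + 1]
    if denom == 0.0:
        return float(i)
    return i + 0.5 * (r[i - 1] - r[i + 1]) / denom


def estimate_f0(segment: GlottalWaveforms | np.ndarray,
                fs: float | None = None) -> float | None:
    """Fundamental frequency of a steady waveform segment, or None.

    Accepts a :class:`GlottalWaveforms` (the glottal area carries the
    clean periodicity) or a bare signal with ``fs``.  Returns None when
    the segment is flagged non-oscillating or no autocorrelation peak
    exists inside the search band.
    """
    if isinstance(segment, GlottalWaveforms):
        if not segment.oscillating:
            return None
        x = segment.a_g
        fs = segment.fs_sim
    else:
        if fs is None:
            raise ValueError("fs required for array input")
        x = np.asarray(segment, dtype=float)

    if len(x) < 2 * fs / F0_SEARCH_MIN:
        raise InsufficientDataError(
            "segment shorter than two periods at the 50 Hz search floor")

    x = x - x.mean()
    if not np.any(x):
        return None
    r = _autocorr(x)
    lag_min = int(fs / F0_SEARCH_MAX)
    lag_max = int(fs / F0_SEARCH_MIN)
    if lag_max >= len(r):
        lag_max = len(r) - 1
    band = r[lag_min:lag_max + 1]
    if band.size == 0:
        return None
    i = lag_min + int(np.argmax(band))
    if r[i] <= 0.5 * r[0]:  # weak periodicity -> treat as unvoiced
        return None
    lag = _parabolic_peak(r, i)

    # refine using the furthest clean multiple of the period inside the
    # window; dividing the high-order lag by its multiplicity sharpens the
    # period estimate well below one cent
    m_max = int((len(r) - 2) / lag)
    m = max(1, min(m_max, int(0.5 * len(x) / lag)))
    if m > 1:
        i_m = int(round(m * lag))
        lo = max(i_m - int(0.4 * lag), 1)
        hi = min(i_m + int(0.4 * lag), len(r) - 2)
        if hi > lo:
            j = lo + int(np.argmax(r[lo:hi + 1]))
            if r[j] > 0.2 * r[0]:
                lag = _parabolic_peak(r, j) / m
    f0 = fs / lag
    if not (F0_SEARCH_MIN <= f0 <= F0_SEARCH_MAX):
        return None
    return float(f0)


def synthesizer_flow(w: GlottalWaveforms) -> np.ndarray:
    """Flow signal of the synthesis chain: U_syn = K_FLOW * d a_g/dt.

    The level convention derives the radiated-pressure surrogate from the
    rate of change of the glottal area scaled by an effective depth
    (:data:`laryngosim.bcm_params.K_FLOW`); the cross-configuration SPL
    contrast then tracks closure sharpness rather than mean Bernoulli flow.
    """
    return P.K_FLOW * np.gradient(w.a_g, 1.0 / w.fs_sim)


def compute_spl(segment: GlottalWaveforms | np.ndarray,
                fs: float | None = None) -> float:
    """SPL [dB] = 20*log10(rms(Z_v * dU_g) / 2e-5).

    For a :class:`GlottalWaveforms` the flow is the synthesis-chain signal
    (:func:`synthesizer_flow`); a bare array is treated as the flow signal
    itself.  dU_g is the central-difference derivative scaled by the
    sampling interval of ``SPL_FS_REF`` (see module docstring), so the
    value is independent of an oversampled fs.
    """
    if isinstance(segment, GlottalWaveforms):
        u = synthesizer_flow(segment)
        fs = segment.fs_sim
    else:
        if fs is None:
            raise ValueError("fs required for array input")
        u = np.asarray(segment, dtype=float)
    if len(u) < 3:
        raise InsufficientDataError("need at least 3 samples for the derivative")
    du_dt = np.gradient(u, 1.0 / fs)          # true derivative [m^3/s^2]
    du = du_dt / P.SPL_FS_REF                 # referenced to the 44.1 kHz interval
    rms = math.sqrt(float(np.mean((P.Z_V * du) ** 2)))
    if rms == 0.0:
        raise UndefinedSPLError("all-zero flow derivative: SPL undefined")
    return 20.0 * math.log10(rms / P.P_REF)


def auditory_state(segment: GlottalWaveforms) -> AuditoryState:
    """Auditory task-space point (f_o, SPL) of a steady segment."""
    return AuditoryState(f_o=estimate_f0(segment), spl=compute_spl(segment))


def vowel_filter_coefficients(fs: float,
                              formants=VOWEL_A_FORMANTS) -> tuple[np.ndarray, np.ndarray]:
    """All-pole cascade of second-order resonators for the fixed vowel."""
    b = np.array([1.0])
    a = np.array([1.0])
    for f, bw in formants:
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * f / fs
        a_sec = np.array([1.0, -2.0 * r * math.cos(theta), r * r])
        # unity gain at DC per section
        b_sec = np.array([float(a_sec.sum())])
        b = np.convolve(b, b_sec)
        a = np.convolve(a, a_sec)
    return b, a


def synthesize_utterance(w: GlottalWaveforms,
                         formants=VOWEL_A_FORMANTS) -> np.ndarray:
    """Peak-normalized audio: radiated source (dU_g) through the vowel filter.

    Passing ``formants=None`` skips the filter, returning the bare
    differentiated source (all-pass contract).  The output preserves the
    source periodicity, so its f_o matches the input within a cent.
    """
    if len(w.U_g) == 0:
        raise ValueError("empty input waveform")
    source = np.gradient(w.U_g, 1.0 / w.fs_sim)
    if formants is None:
        audio = source
    else:
        b, a = vowel_filter_coefficients(w.fs_sim, formants)
        audio = signal.lfilter(b, a, source)
    peak = float(np.max(np.abs(audio)))
    return audio / peak if peak > 0 else audio


def write_wav(path: str, audio: np.ndarray, fs: float) -> None:
    """16-bit PCM WAV export."""
    x = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    pcm = (x * 32767.0).astype("<i2")
    with wave.open(path, "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(int(round(fs)))
        fh.writeframes(pcm.tobytes())
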