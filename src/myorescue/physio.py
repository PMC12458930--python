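"""Muscle force-trace and EMG quantification.

Implements the contraction-side readouts of myotonia: specific force via
cross-sectional area, the post-tetanic "impulse" (time integral of the
peak-normalized force trace after stimulus cessation — zero for a muscle
that relaxes promptly, positive for a myotonic after-contraction),
force–frequency Boltzmann-sigmoid fitting with its half-maximal frequency,
and EMG demodulation by rectification plus a zero-phase second-order
Butterworth low-pass (the linear envelope) with FFT amplitude spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

__all__ = [
    "ForceTrace",
    "EMGTrace",
    "ImpulseResult",
    "ForceFrequencyFit",
    "specific_force",
    "cross_sectional_area",
    "myotonia_impulse",
    "fit_force_frequency",
    "force_frequency_sigmoid",
    "linear_envelope",
    "amplitude_spectrum",
    "post_stimulus_activity",
]

SOLEUS_FIBER_RATIO = 0.71  # fiber-length to optimal-length ratio for soleus
MUSCLE_DENSITY_G_CM3 = 1.06


@dataclass
class ForceTrace:
    """Uniformly sampled force trace with its stimulus interval."""

    time_s: np.ndarray
    force_mn: np.ndarray
    stim_start_s: float
    stim_end_s: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_mn = np.asarray(self.force_mn, dtype=float)
        if self.time_s.shape != self.force_mn.shape:
            raise ValueError("time and force must have the same length")
        if not self.stim_start_s < self.stim_end_s:
            raise ValueError("stimulus end must follow stimulus start")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("force trace must be uniformly sampled")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass
class EMGTrace:
    time_s: np.ndarray
    voltage_mv: np.ndarray
    artifact_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.time_s.shape != self.voltage_mv.shape:
            raise ValueError("time and voltage must have the same length")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass
class ImpulseResult:
    auc: float  # normalized-force × s
    window_s: tuple[float, float]
    truncated: bool = False


@dataclass
class ForceFrequencyFit:
    f_half: float
    k_f: float
    bottom: float
    top: float
    sse: float = float("nan")
    converged: bool = True

    def predict(self, freq_hz):
        return force_frequency_sigmoid(freq_hz, self.bottom, self.top, self.f_half, self.k_f)


def cross_sectional_area(
    mass_mg: float,
    lo_mm: float,
    fiber_ratio: float = SOLEUS_FIBER_RATIO,
    density_g_cm3: float = MUSCLE_DENSITY_G_CM3,
) -> float:
    """Physiologic CSA in mm²: mass / (Lo × fiber-length ratio × density).

    1 g/cm³ equals 1 mg/mm³, so the expression is unit-consistent with mass
    in mg and lengths in mm.
    """
    for name, v in (("mass_mg", mass_mg), ("lo_mm", lo_mm),
                    ("fiber_ratio", fiber_ratio), ("density_g_cm3", density_g_cm3)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return mass_mg / (lo_mm * fiber_ratio * density_g_cm3)


def specific_force(
    peak_mn: float,
    mass_mg: float,
    lo_mm: float,
    fiber_ratio: float = SOLEUS_FIBER_RATIO,
    density_g_cm3: float = MUSCLE_DENSITY_G_CM3,
) -> float:
    """Peak force normalized to estimated cross-sectional area (mN/mm²)."""
    if peak_mn <= 0:
        raise ValueError("peak_mn must be positive")
    return peak_mn / cross_sectional_area(mass_mg, lo_mm, fiber_ratio, density_g_cm3)


def myotonia_impulse(
    trace: ForceTrace,
    window_s: float = 2.0,
    baseline_s: float = 0.1,
) -> ImpulseResult:
    """Impulse of myotonia: ∫ max(normalized force − baseline, 0) dt after the stimulus.

    The trace is normalized so the tetanic peak (within the stimulus
    interval) equals 1 AU; baseline is the mean of the ``baseline_s``
    pre-stimulus segment.  Trapezoidal integration from stimulus end over
    ``window_s`` (truncated, with a flag, if the trace ends sooner).
    """
    t, f = trace.time_s, trace.force_mn
    stim = (t >= trace.stim_start_s) & (t <= trace.stim_end_s)
    peak = float(np.max(f[stim]))
    if peak <= 0:
        raise ValueError("no positive force during the stimulus; cannot normalize")
    pre = (t >= trace.stim_start_s - baseline_s) & (t < trace.stim_start_s)
    baseline = float(np.mean(f[pre])) if pre.any() else 0.0
    norm = (f - baseline) / (peak - baseline)

    t_end = trace.stim_end_s + window_s
    truncated = t_end > t[-1]
    post = (t >= trace.stim_end_s) & (t <= t_end)
    if post.sum() < 2:
        return ImpulseResult(auc=0.0, window_s=(trace.stim_end_s, min(t_end, t[-1])),
                             truncated=truncated)
    auc = float(np.trapezoid(np.maximum(norm[post], 0.0), t[post]))
    return ImpulseResult(auc=auc, window_s=(trace.stim_end_s, min(t_end, float(t[-1]))),
                         truncated=truncated)


def force_frequency_sigmoid(freq_hz, bottom: float, top: float, f_half: float, k_f: float):
    freq_hz = np.asarray(freq_hz, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.exp((f_half - freq_hz) / k_f))


def fit_force_frequency(freq_hz: Sequence[float], norm_force: Sequence[float]) -> ForceFrequencyFit:
    """Boltzmann-sigmoid fit of normalized force vs stimulation frequency.

    Forces should be normalized to the per-muscle maximum across all tested
    frequencies.  Returns the half-maximal frequency f_half (the summary
    statistic of frequency sensitivity) with fit diagnostics.
    """
    f = np.asarray(freq_hz, dtype=float)
    y = np.asarray(norm_force, dtype=float)
    if len(f) < 5:
        raise ValueError("need at least 5 stimulation frequencies")
    order = np.argsort(f)
    f, y = f[order], y[order]
    bottom0, top0 = float(y.min()), float(y.max())
    f_half0 = f[np.argmin(np.abs(y - (bottom0 + top0) / 2))]
    p0 = [bottom0, top0, f_half0, max((f[-1] - f[0]) / 10.0, 1.0)]
    bounds = ([-np.inf, -np.inf, f[0], 1e-3], [np.inf, np.inf, f[-1], np.inf])
    try:
        popt, _ = curve_fit(force_frequency_sigmoid, f, y, p0=p0, bounds=bounds, maxfev=20000)
        sse = float(np.sum((force_frequency_sigmoid(f, *popt) - y) ** 2))
        ok = True
    except (RuntimeError, ValueError):
        popt, sse, ok = p0, float("inf"), False
    return ForceFrequencyFit(bottom=popt[0], top=popt[1], f_half=popt[2], k_f=popt[3],
                             sse=sse, converged=ok)


def linear_envelope(emg: EMGTrace, cutoff_hz: float = 10.0, order: int = 2) -> np.ndarray:
    """Linear envelope: zero-phase Butterworth low-pass of the rectified EMG.

    Forward–backward (zero-phase) filtering keeps envelope timing unbiased;
    any small filter-transient negative values are clipped at zero.
    """
    nyquist = emg.sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at/above Nyquist ({nyquist} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=emg.sample_rate_hz, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(emg.voltage_mv))
    return np.maximum(env, 0.0)


def amplitude_spectrum(emg: EMGTrace) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT amplitude spectrum of the raw EMG signal."""
    n = len(emg.voltage_mv)
    amp = np.abs(np.fft.rfft(emg.voltage_mv)) / n
    amp[1:] *= 2.0  # fold negative frequencies into the one-sided spectrum
    freqs = np.fft.rfftfreq(n, d=1.0 / emg.sample_rate_hz)
    return freqs, amp


def post_stimulus_activity(
    emg: EMGTrace,
    envelope: np.ndarray,
    artifact_time_s: float | None = None,
    baseline_window_s: float = 0.1,
    quiet_s: float = 0.05,
    n_sd: float = 3.0,
) -> tuple[float, float, bool]:
    """Duration and AUC of post-stimulus envelope activity (electrical myotonia).

    The activity threshold is baseline mean + ``n_sd``×SD, estimated from the
    ``baseline_window_s`` segment at the start of the trace.  Duration runs
    from the stimulus artifact until the envelope stays below threshold for
    at least ``quiet_s``; AUC is the above-baseline envelope integral over
    that span.  Returns (duration_s, auc, flagged) where ``flagged`` marks an
    envelope that never settles within the recording.
    """
    t = emg.time_s
    if artifact_time_s is None:
        artifact_time_s = emg.artifact_time_s
    base = envelope[t < t[0] + baseline_window_s]
    if base.size == 0:
        raise ValueError("no baseline segment before the stimulus artifact")
    threshold = float(np.mean(base) + n_sd * np.std(base))
    post = t >= artifact_time_s
    tp, ep = t[post], envelope[post]
    below = ep <= threshold
    quiet_n = max(1, int(round(quiet_s * emg.sample_rate_hz)))

    end_idx = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= quiet_n:
            end_idx = i - quiet_n + 1
            break
    if end_idx is None:
        duration = float(tp[-1] - artifact_time_s)
        flagged = True
        span = slice(None)
    else:
        duration = float(tp[end_idx] - artifact_time_s)
        flagged = False
        span = slice(0, max(end_idx, 2))
    auc = float(np.trapezoid(np.maximum(ep[span] - np.mean(base), 0.0), tp[span])) if len(tp) > 1 else 0.0
    return duration, auc, flagged
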