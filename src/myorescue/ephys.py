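"""Whole-cell ClC-1 current analysis.

Covers the standard voltage-clamp workflow for the muscle chloride channel:
capacitance from an integrated 10-mV transient, offline subtraction of
9-AC-insensitive current, extraction of instantaneous and steady-state
current densities from a −140..+60 mV step family, Boltzmann fits of the
instantaneous IV and of tail-current relative open probability, and the
Nernst reversal potential of the recording solutions.

The instantaneous IV is fit with a modified Boltzmann

    I(Vm) = (Imax − Io) / (1 + exp((V1/2 − Vm)/kv)) + Io

where Imax is the saturating current, Io a constant offset, V1/2 the
half-activation voltage and kv the slope factor.  Note on the sign of kv:
the parameterization is sign-degenerate — (Imax, Io, kv) and (Io, Imax,
−kv) are the same curve — and the ClC-1 instantaneous IV (measured after a
fully-activating +60 mV prepulse) peaks inward at the most hyperpolarized
step, which corresponds to kv < 0 when Imax labels the inward plateau.  The
fit therefore tries both signs and canonicalizes its result so Imax is the
larger-magnitude plateau.  The relative-Po equation

    Po,rel(Vm) = (1 − Pmin) / (1 + exp((V1/2 − Vm)/kv)) + Pmin

is internally consistent with kv > 0 (activation grows with depolarization),
so that fit constrains kv > 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IVRecording",
    "BoltzmannIVParams",
    "RelPoParams",
    "SolutionSpec",
    "boltzmann_iv",
    "rel_po",
    "capacitance_from_transient",
    "subtract_blocker",
    "extract_iv",
    "fit_boltzmann_iv",
    "fit_rel_po",
    "nernst_potential",
    "total_ion_concentration",
]

R_GAS = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


def boltzmann_iv(vm: np.ndarray | float, imax: float, io: float, v_half: float, kv: float) -> np.ndarray | float:
    """Modified Boltzmann current: I(Vm) = (Imax−Io)/(1+exp((V1/2−Vm)/kv)) + Io."""
    vm = np.asarray(vm, dtype=float)
    return (imax - io) / (1.0 + np.exp((v_half - vm) / kv)) + io


def rel_po(vm: np.ndarray | float, p_min: float, v_half: float, kv: float) -> np.ndarray | float:
    """Relative open probability: Po,rel(Vm) = (1−Pmin)/(1+exp((V1/2−Vm)/kv)) + Pmin."""
    vm = np.asarray(vm, dtype=float)
    return (1.0 - p_min) / (1.0 + np.exp((v_half - vm) / kv)) + p_min


@dataclass
class IVRecording:
    """Voltage-step family: one current trace per test potential.

    ``currents`` has shape (n_steps, n_samples) in pA; ``time`` in seconds
    starts at the transition from the +60 mV activating prepulse into each
    test step.  ``cap_time``/``cap_current`` hold the baseline-subtracted
    capacitive transient recorded from a ``cap_dv`` depolarization at
    holding potential.
    """

    voltages_mv: np.ndarray
    time_s: np.ndarray
    currents_pa: np.ndarray
    cap_time_s: np.ndarray
    cap_current_pa: np.ndarray
    cap_dv_mv: float = 10.0
    holding_mv: float = -50.0

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        if len(np.unique(self.voltages_mv)) != len(self.voltages_mv):
            raise ValueError("voltage steps must be unique")
        if self.currents_pa.shape != (len(self.voltages_mv), len(self.time_s)):
            raise ValueError("currents array must be (n_steps, n_samples)")


@dataclass
class BoltzmannIVParams:
    imax: float
    io: float
    v_half: float
    kv: float
    sse: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kv == 0:
            raise ValueError("kv must be nonzero")

    def predict(self, vm):
        return boltzmann_iv(vm, self.imax, self.io, self.v_half, self.kv)


@dataclass
class RelPoParams:
    p_min: float
    v_half: float
    kv: float
    imax_tail: float
    sse: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_min <= 1.0:
            raise ValueError("p_min must lie in [0, 1]")

    def predict(self, vm):
        return rel_po(vm, self.p_min, self.v_half, self.kv)


def capacitance_from_transient(time_s: np.ndarray, current_pa: np.ndarray, dv_mv: float = 10.0) -> float:
    """Membrane capacitance from an integrated capacitive transient.

    C = Q/ΔV with Q = ∫ I dt over the (baseline-subtracted) transient.
    pA·s = pC and pC/mV = nF, so the result is scaled to pF.
    """
    time_s = np.asarray(time_s, dtype=float)
    current_pa = np.asarray(current_pa, dtype=float)
    if time_s.shape != current_pa.shape:
        raise ValueError("time and current must have the same length")
    charge_pc = np.trapezoid(current_pa, time_s)
    return float(charge_pc / dv_mv * 1000.0)


def subtract_blocker(trace_pre: np.ndarray, trace_post_9ac: np.ndarray) -> np.ndarray:
    """Pointwise pre-minus-post difference: the 9-AC-sensitive (ClC-1) current."""
    pre = np.asarray(trace_pre, dtype=float)
    post = np.asarray(trace_post_9ac, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre- and post-9-AC traces must share a time base")
    return pre - post


def extract_iv(
    rec: IVRecording,
    capacitance_pf: float,
    inst_window_s: tuple[float, float] = (0.001, 0.005),
    ss_fraction: float = 0.1,
    smooth_s: float = 0.002,
) -> "pd.DataFrame":
    """Per-step instantaneous and steady-state current densities (pA/pF).

    Instantaneous current is the signed extremum within ``inst_window_s``
    after the transition from the activating prepulse (the first millisecond
    is skipped to avoid residual capacitive artifact); the trace is boxcar-
    smoothed over ``smooth_s`` first so the extremum is not dominated by
    single-sample noise excursions.  Steady-state current is the mean over
    the final ``ss_fraction`` of the step.  Both are normalized by the
    fiber capacitance.
    """
    import pandas as pd

    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    t = rec.time_s
    lo, hi = inst_window_s
    if lo < t[0] or hi > t[-1]:
        raise ValueError("instantaneous window lies outside the recorded step")
    win = (t >= lo) & (t <= hi)
    if not win.any():
        raise ValueError("instantaneous window contains no samples")
    dt = float(t[1] - t[0])
    n_smooth = max(1, int(round(smooth_s / dt)))
    kernel = np.ones(n_smooth) / n_smooth
    n_ss = max(1, int(round(ss_fraction * len(t))))
    rows = []
    for vm, trace in zip(rec.voltages_mv, rec.currents_pa):
        smoothed = np.convolve(trace, kernel, mode="same") if n_smooth > 1 else trace
        seg = smoothed[win]
        inst = seg[np.argmax(np.abs(seg))]  # signed extremum
        ss = float(np.mean(trace[-n_ss:]))
        rows.append({"vm_mv": vm, "inst_cd_pa_pf": inst / capacitance_pf,
                     "ss_cd_pa_pf": ss / capacitance_pf})
    return pd.DataFrame(rows)


def _fit_sigmoid(func, x, y, p0, bounds):
    try:
        popt, _ = curve_fit(func, x, y, p0=p0, bounds=bounds, maxfev=20000)
        sse = float(np.sum((func(x, *popt) - y) ** 2))
        return popt, sse, True
    except (RuntimeError, ValueError):
        return np.asarray(p0, dtype=float), float("inf"), False


def fit_boltzmann_iv(vm_mv: Sequence[float], cd_pa_pf: Sequence[float]) -> BoltzmannIVParams:
    """Least-squares modified-Boltzmann fit of an instantaneous IV curve.

    Initialization: Imax = extremal current density, Io = density at the most
    depolarized step, V1/2 = voltage nearest the half-range crossing,
    |kv| = 15 mV.  Both signs of kv are tried and the better fit kept; a
    non-converged fit is returned flagged rather than raised.
    """
    vm = np.asarray(vm_mv, dtype=float)
    cd = np.asarray(cd_pa_pf, dtype=float)
    if len(vm) < 5:
        raise ValueError("need at least 5 voltage points spanning the transition")
    order = np.argsort(vm)
    vm, cd = vm[order], cd[order]

    imax0 = cd[np.argmax(np.abs(cd))]
    io0 = cd[-1]  # most depolarized step
    half = (imax0 + io0) / 2.0
    v_half0 = vm[np.argmin(np.abs(cd - half))]
    span = vm[-1] - vm[0]

    best = None
    for kv0 in (15.0, -15.0):
        bounds = (
            [-np.inf, -np.inf, vm[0] - span, 0.1 if kv0 > 0 else -200.0],
            [np.inf, np.inf, vm[-1] + span, 200.0 if kv0 > 0 else -0.1],
        )
        popt, sse, ok = _fit_sigmoid(boltzmann_iv, vm, cd, [imax0, io0, v_half0, kv0], bounds)
        cand = (sse, ok, popt)
        if best is None or (ok and cand[0] < best[0]):
            best = cand
    sse, ok, popt = best
    imax, io, v_half, kv = popt
    # The parameterization is sign-degenerate: (Imax, Io, kv) and
    # (Io, Imax, −kv) describe the same sigmoid.  Canonicalize so that Imax
    # is the larger-magnitude plateau (the "maximal current").
    if abs(io) > abs(imax):
        imax, io, kv = io, imax, -kv
    return BoltzmannIVParams(imax=imax, io=io, v_half=v_half, kv=kv,
                             sse=sse, converged=ok)


def fit_rel_po(vm_mv: Sequence[float], tail_pa: Sequence[float]) -> RelPoParams:
    """Relative-open-probability Boltzmann fit of tail currents.

    Tails are referenced to the fiber's absolute maximal tail current
    (reported as ``imax_tail``); the least-squares fit itself carries a free
    amplitude so that Pmin is not biased by the maximal observed tail lying
    slightly below the sigmoid's asymptote.  Po,rel(Vm) =
    (1−Pmin)/(1+exp((V1/2−Vm)/kv)) + Pmin with Pmin ∈ [0, 1] and kv > 0.
    """
    vm = np.asarray(vm_mv, dtype=float)
    tails = np.asarray(tail_pa, dtype=float)
    if len(vm) < 5:
        raise ValueError("need at least 5 voltage points spanning the transition")
    imax_tail = tails[np.argmax(np.abs(tails))]
    po = tails / imax_tail
    order = np.argsort(vm)
    vm, po = vm[order], po[order]
    span = vm[-1] - vm[0]

    def scaled(v, amp, p_min, v_half, kv):
        return amp * rel_po(v, p_min, v_half, kv)

    p00 = max(0.0, min(1.0, float(po.min())))
    v_half0 = vm[np.argmin(np.abs(po - (1 + p00) / 2))]
    popt, sse, ok = _fit_sigmoid(
        scaled, vm, po, [1.0, p00, v_half0, 15.0],
        ([0.5, 0.0, vm[0] - span, 0.1], [2.0, 1.0, vm[-1] + span, 200.0]),
    )
    return RelPoParams(p_min=float(np.clip(popt[1], 0.0, 1.0)), v_half=popt[2], kv=popt[3],
                       imax_tail=float(imax_tail), sse=sse, converged=ok)


_CL_PATTERN = re.compile(r"Cl(\d*)(?![a-z])")


@dataclass(frozen=True)
class SolutionSpec:
    """Recording-solution composition: salt → concentration (mM) per side.

    Salt names carry their stoichiometry (e.g. ``MgCl2`` contributes two
    chloride per formula unit, ``TEA-Cl`` one); free-ion entries like ``Cl``
    are also accepted.
    """

    internal_mm: Mapping[str, float]
    external_mm: Mapping[str, float]
    temperature_k: float = 295.0

    def __post_init__(self) -> None:
        for side in (self.internal_mm, self.external_mm):
            for salt, conc in side.items():
                if conc < 0:
                    raise ValueError(f"negative concentration for {salt!r}")


def _ion_count(salt: str, ion: str) -> int:
    if ion != "Cl":
        # generic: element symbol followed by optional count, not inside a longer symbol
        pattern = re.compile(rf"{ion}(\d*)(?![a-z])")
    else:
        pattern = _CL_PATTERN
    m = pattern.search(salt)
    if m is None:
        return 0
    return int(m.group(1)) if m.group(1) else 1


def total_ion_concentration(side_mm: Mapping[str, float], ion: str = "Cl") -> float:
    """Total concentration of ``ion`` (mM) tallied over all salts in one compartment."""
    return sum(conc * _ion_count(salt, ion) for salt, conc in side_mm.items())


def nernst_potential(solution: SolutionSpec, ion: str = "Cl", valence: int = -1) -> float:
    """Nernst equilibrium potential in mV: E = (RT/zF)·ln([ion]_out/[ion]_in)."""
    c_in = total_ion_concentration(solution.internal_mm, ion)
    c_out = total_ion_concentration(solution.external_mm, ion)
    if c_in <= 0 or c_out <= 0:
        raise ValueError(f"{ion} must be present on both sides for a defined Nernst potential")
    rt_zf = R_GAS * solution.temperature_k / (valence * FARADAY)
    return float(rt_zf * np.log(c_out / c_in) * 1000.0)
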