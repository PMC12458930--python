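"""Synthetic-data generators for every input the pipeline consumes.

Each generator is seeded and bit-reproducible, returns its planted truth
alongside the data, and emulates the statistical structure the downstream
analysis assumes: isoform pools drawn from the splicing+NMD steady state,
ClC-1 voltage-step currents obeying the modified Boltzmann IV with
exponential deactivation, tetanic force traces with or without a myotonic
after-contraction, EMG burst runs, and two-contrast dPSI / log2FC tables
with planted rescue and attenuation structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bedio import BedRead
from .ephys import BoltzmannIVParams, IVRecording, boltzmann_iv, rel_po
from .physio import EMGTrace, ForceTrace
from .quant import CtSet
from .splicemodel import (
    CASSETTE_EXON,
    RETAINED_INTRON,
    SpliceModel,
    ToyGeneModel,
    expected_stability_ratio,
    isoform_key,
    steady_state_isoform_freqs,
)

__all__ = [
    "isoform_blocks",
    "simulate_long_reads",
    "simulate_iv_recording",
    "simulate_tail_currents",
    "simulate_force_trace",
    "simulate_emg",
    "simulate_dpsi_table",
    "simulate_de_table",
    "simulate_qpcr_cts",
]


# ---------------------------------------------------------------------------
# long reads

def isoform_blocks(gene: ToyGeneModel, subset: Sequence[str]) -> tuple[tuple[int, int], ...]:
    """Block structure of the isoform containing exactly ``subset``.

    Constitutive exons, plus each included cassette exon as its own block;
    an included retained intron merges its two flanking blocks.
    """
    intervals = list(gene.exons)
    retained: list[tuple[int, int]] = []
    for ev in subset:
        if ev not in gene.event_map:
            raise ValueError(f"event {ev!r} not placed on the gene model")
        start, end, cls = gene.event_map[ev]
        if cls == CASSETTE_EXON:
            intervals.append((start, end))
        else:
            retained.append((start, end))
    intervals.sort()
    retained_set = set(retained)
    merged: list[list[int]] = [list(intervals[0])]
    for s, e in intervals[1:]:
        gap = (merged[-1][1], s)
        if gap in retained_set:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def simulate_long_reads(
    model: SpliceModel,
    gene: ToyGeneModel,
    n_reads: int,
    seed: int | np.random.Generator = 0,
    truncation_rate: float = 0.0,
    read_prefix: str = "read",
) -> tuple[list[BedRead], pd.DataFrame]:
    """Draw full-gene long reads i.i.d. from the steady-state isoform law.

    Returns the BED12-ready reads and a truth table with each read's event
    subset (per-event booleans) and truncation flag.  Truncation (off by
    default) removes a random 3' portion of the read's blocks, emulating
    incomplete cDNAs.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    for ev in model.events:
        if ev not in gene.event_map:
            raise ValueError(f"model event {ev!r} missing from the gene model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    freqs = steady_state_isoform_freqs(model)
    keys = list(freqs)
    subsets = {k: tuple() if k == "canonical" else tuple(k.split("+")) for k in keys}
    blocks_by_key = {k: isoform_blocks(gene, subsets[k]) for k in keys}
    draws = rng.choice(len(keys), size=n_reads, p=[freqs[k] for k in keys])
    truncate = (
        rng.random(n_reads) < truncation_rate
        if truncation_rate > 0
        else np.zeros(n_reads, dtype=bool)
    )

    reads: list[BedRead] = []
    truth_rows = []
    span_lo, span_hi = gene.span
    for i, (ki, trunc) in enumerate(zip(draws, truncate)):
        key = keys[ki]
        blocks = blocks_by_key[key]
        if trunc:
            cut = int(rng.integers(span_lo + 1, span_hi))
            clipped = tuple((s, min(e, cut)) for s, e in blocks if s < cut)
            blocks = clipped if clipped else (blocks[0],)
        name = f"{read_prefix}{i:06d}"
        reads.append(BedRead(chrom=gene.chrom, name=name, blocks=blocks, strand=gene.strand))
        row = {"read_id": name, "isoform": key, "truncated": bool(trunc)}
        row.update({ev: ev in subsets[key] for ev in model.events})
        truth_rows.append(row)
    return reads, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# electrophysiology

DEFAULT_STEP_VOLTAGES = tuple(range(-140, 61, 10))


def simulate_iv_recording(
    params: BoltzmannIVParams,
    voltages_mv: Sequence[float] = DEFAULT_STEP_VOLTAGES,
    noise_sd_pa_pf: float = 0.0,
    capacitance_pf: float = 2000.0,
    seed: int | np.random.Generator = 0,
    sample_rate_hz: float = 10_000.0,
    step_duration_s: float = 0.5,
    deact_tau_s: float = 0.15,
    ss_p_min: float = 0.3,
    ss_v_half_mv: float = -80.0,
    ss_kv_mv: float = 20.0,
    cap_tau_s: float = 1e-3,
    cap_dv_mv: float = 10.0,
    cap_noise_sd_pa: float = 0.0,
) -> IVRecording:
    """Synthesize a ClC-1 voltage-step family.

    Per step, the current density starts at the modified-Boltzmann
    instantaneous value for that potential (channels fully activated by the
    +60 mV prepulse) and deactivates exponentially (τ = ``deact_tau_s``)
    toward a steady-state fraction given by a relative-Po law with floor
    ``ss_p_min``.  Gaussian noise of ``noise_sd_pa_pf`` is added per sample.
    A separate baseline-subtracted capacitive transient for a ``cap_dv_mv``
    step is synthesized consistent with ``capacitance_pf``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    voltages = np.asarray(voltages_mv, dtype=float)
    t = np.arange(0.0, step_duration_s, 1.0 / sample_rate_hz)

    inst_cd = boltzmann_iv(voltages, params.imax, params.io, params.v_half, params.kv)
    ss_frac = rel_po(voltages, ss_p_min, ss_v_half_mv, ss_kv_mv)
    decay = np.exp(-t / deact_tau_s)
    cd = inst_cd[:, None] * (ss_frac[:, None] + (1.0 - ss_frac[:, None]) * decay[None, :])
    currents = cd * capacitance_pf
    if noise_sd_pa_pf > 0:
        currents = currents + rng.normal(0.0, noise_sd_pa_pf * capacitance_pf, currents.shape)

    cap_t = np.arange(0.0, 20.0 * cap_tau_s, 1.0 / sample_rate_hz)
    # charge C*dV: pF * mV = 1e-3 pC, so peak current in pA is C*dV*1e-3 / tau.
    amp_pa = capacitance_pf * cap_dv_mv * 1e-3 / cap_tau_s
    cap_i = amp_pa * np.exp(-cap_t / cap_tau_s)
    if cap_noise_sd_pa > 0:
        cap_i = cap_i + rng.normal(0.0, cap_noise_sd_pa, cap_i.shape)
    return IVRecording(
        voltages_mv=voltages, time_s=t, currents_pa=currents,
        cap_time_s=cap_t, cap_current_pa=cap_i, cap_dv_mv=cap_dv_mv,
    )


def simulate_tail_currents(
    p_min: float,
    v_half_mv: float,
    kv_mv: float,
    imax_tail_pa: float,
    voltages_mv: Sequence[float] = DEFAULT_STEP_VOLTAGES,
    noise_sd_pa: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Tail-current amplitudes at a fixed post-step potential, proportional
    to the open fraction reached at each step potential."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.asarray(voltages_mv, dtype=float)
    tails = imax_tail_pa * rel_po(v, p_min, v_half_mv, kv_mv)
    if noise_sd_pa > 0:
        tails = tails + rng.normal(0.0, noise_sd_pa, tails.shape)
    return pd.DataFrame({"vm_mv": v, "tail_pa": tails})


# ---------------------------------------------------------------------------
# contraction / EMG

def simulate_force_trace(
    peak_mn: float = 300.0,
    stim_start_s: float = 0.5,
    stim_end_s: float = 1.0,
    myotonia_amp: float = 0.0,
    myotonia_tau_s: float = 0.25,
    sample_rate_hz: float = 1000.0,
    duration_s: float | None = None,
    rise_tau_s: float = 0.03,
    relax_tau_s: float = 0.02,
    noise_sd_mn: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ForceTrace:
    """Tetanic force trace with an optional myotonic after-contraction.

    Force rises exponentially to a plateau during the stimulus; after
    stimulus end it is the sum of a fast relaxation component (amplitude
    1 − ``myotonia_amp``, τ = ``relax_tau_s``) and a slow after-contraction
    (amplitude ``myotonia_amp``, τ = ``myotonia_tau_s``).  With
    ``myotonia_amp = 0`` the muscle relaxes promptly.
    """
    if stim_end_s <= stim_start_s:
        raise ValueError("stim_end must follow stim_start")
    if myotonia_amp < 0:
        raise ValueError("myotonia_amp must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration_s is None:
        duration_s = stim_end_s + max(3.0, 8.0 * myotonia_tau_s)
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    f = np.zeros_like(t)
    during = (t >= stim_start_s) & (t <= stim_end_s)
    f[during] = peak_mn * (1.0 - np.exp(-(t[during] - stim_start_s) / rise_tau_s))
    level = peak_mn * (1.0 - np.exp(-(stim_end_s - stim_start_s) / rise_tau_s))
    after = t > stim_end_s
    dt_after = t[after] - stim_end_s
    f[after] = level * (
        (1.0 - myotonia_amp) * np.exp(-dt_after / relax_tau_s)
        + myotonia_amp * np.exp(-dt_after / myotonia_tau_s)
    )
    if noise_sd_mn > 0:
        f = f + rng.normal(0.0, noise_sd_mn, f.shape)
    return ForceTrace(time_s=t, force_mn=f, stim_start_s=stim_start_s, stim_end_s=stim_end_s)


def _spike_train(t: np.ndarray, spike_times: np.ndarray, amps: np.ndarray, width_s: float) -> np.ndarray:
    """Sum of biphasic (Gaussian-derivative) motor-unit potentials."""
    v = np.zeros_like(t)
    for ts, a in zip(spike_times, amps):
        rel = t - ts
        mask = np.abs(rel) < 5 * width_s
        v[mask] += a * (rel[mask] / width_s) * np.exp(-0.5 * (rel[mask] / width_s) ** 2)
    return v


def simulate_emg(
    burst_rate_hz: float = 120.0,
    run_duration_s: float = 0.8,
    stim_start_s: float = 0.3,
    stim_end_s: float = 0.8,
    stim_rate_hz: float = 150.0,
    spike_amp_mv: float = 1.0,
    spike_width_s: float = 0.0015,
    noise_sd_mv: float = 0.01,
    sample_rate_hz: float = 5000.0,
    tail_s: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[EMGTrace, dict]:
    """EMG trace: tetanic burst during the stimulus, then (for a myotonic
    muscle) a continued run of action potentials for ``run_duration_s``.

    Returns the trace (artifact time set to stimulus end, the alignment
    point for post-stimulus activity) and the planted truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = stim_end_s + max(run_duration_s, 0.0) + tail_s
    t = np.arange(0.0, duration, 1.0 / sample_rate_hz)

    stim_times = np.arange(stim_start_s, stim_end_s, 1.0 / stim_rate_hz)
    v = _spike_train(t, stim_times, np.full(stim_times.shape, spike_amp_mv), spike_width_s)
    if run_duration_s > 0:
        run_times = np.arange(stim_end_s, stim_end_s + run_duration_s, 1.0 / burst_rate_hz)
        jitter = rng.normal(0.0, 0.2 / burst_rate_hz, run_times.shape)
        amps = spike_amp_mv * (0.5 + 0.5 * rng.random(run_times.shape))
        v += _spike_train(t, run_times + jitter, amps, spike_width_s)
    if noise_sd_mv > 0:
        v = v + rng.normal(0.0, noise_sd_mv, v.shape)
    trace = EMGTrace(time_s=t, voltage_mv=v, artifact_time_s=stim_end_s)
    truth = {"run_duration_s": run_duration_s, "stim_start_s": stim_start_s,
             "stim_end_s": stim_end_s}
    return trace, truth


# ---------------------------------------------------------------------------
# dPSI / differential-expression tables

def _stat(rng: np.random.Generator, passing: bool, mode: str, n: int) -> np.ndarray:
    if mode == "fdr":
        return rng.uniform(1e-4, 0.02, n) if passing else rng.uniform(0.2, 0.9, n)
    return rng.uniform(0.96, 0.999, n) if passing else rng.uniform(0.1, 0.8, n)


def simulate_dpsi_table(
    n_events: int,
    n_complete: int,
    n_partial: int,
    n_shared: int,
    n_unchanged: int,
    seed: int | np.random.Generator = 0,
    stat_mode: str = "fdr",
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-contrast dPSI table with planted rescue labels.

    Rows beyond the four stated classes are planted as ``novel_in_DKO``.
    All planted rows sit away from the decision thresholds (|dPSI| = 0.1,
    shift = 0.15) so recovery is exact.  Returns (table, truth labels).
    """
    counts = {"complete_rescue": n_complete, "partial_rescue": n_partial,
              "mis_spliced_shared": n_shared, "unchanged": n_unchanged}
    if any(c < 0 for c in counts.values()) or n_events < sum(counts.values()):
        raise ValueError("class counts must be >= 0 and sum to at most n_events")
    counts["novel_in_DKO"] = n_events - sum(counts.values())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows, labels = [], []
    idx = 0
    for label, n in counts.items():
        signs = rng.choice([-1.0, 1.0], n)
        if label == "complete_rescue":
            ko = signs * rng.uniform(0.3, 0.7, n)
            dko = rng.uniform(-0.05, 0.05, n)
            s_ko, s_dko = _stat(rng, True, stat_mode, n), _stat(rng, False, stat_mode, n)
        elif label == "partial_rescue":
            ko = signs * rng.uniform(0.45, 0.8, n)
            dko = signs * (np.abs(ko) - rng.uniform(0.2, 0.25, n))
            s_ko, s_dko = _stat(rng, True, stat_mode, n), _stat(rng, True, stat_mode, n)
        elif label == "mis_spliced_shared":
            ko = signs * rng.uniform(0.25, 0.6, n)
            dko = signs * (np.abs(ko) - rng.uniform(0.0, 0.08, n))
            s_ko, s_dko = _stat(rng, True, stat_mode, n), _stat(rng, True, stat_mode, n)
        elif label == "unchanged":
            ko = rng.uniform(-0.05, 0.05, n)
            dko = rng.uniform(-0.05, 0.05, n)
            s_ko, s_dko = _stat(rng, False, stat_mode, n), _stat(rng, False, stat_mode, n)
        else:  # novel_in_DKO
            ko = rng.uniform(-0.05, 0.05, n)
            dko = rng.choice([-1.0, 1.0], n) * rng.uniform(0.2, 0.5, n)
            s_ko, s_dko = _stat(rng, False, stat_mode, n), _stat(rng, True, stat_mode, n)
        for j in range(n):
            rows.append({
                "gene": f"gene_{idx:04d}", "event_id": f"event_{idx:04d}",
                "dPSI_KO": float(ko[j]), "stat_KO": float(s_ko[j]),
                "dPSI_DKO": float(dko[j]), "stat_DKO": float(s_dko[j]),
            })
            labels.append(label)
            idx += 1
    order = rng.permutation(len(rows))
    table = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    truth = pd.Series([labels[i] for i in order], index=table.index, name="label")
    return table, truth


def simulate_de_table(
    n_genes: int,
    n_dysregulated: int,
    n_closer: int | None = None,
    n_half: int | None = None,
    attenuation: float | tuple[float, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-contrast log2FC/padj gene table with planted attenuation structure.

    Either give ``attenuation`` (a scalar or uniform (lo, hi) range applied
    to every dysregulated gene: log2FC_DKO = attenuation × log2FC_KO), or
    plant exact counts ``n_closer`` (|log2FC_DKO| < |log2FC_KO|) of which
    ``n_half`` are attenuated to ≤ half.  Returns (table, truth flags).
    """
    if n_dysregulated > n_genes:
        raise ValueError("n_dysregulated cannot exceed n_genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if attenuation is not None:
        if isinstance(attenuation, tuple):
            att = rng.uniform(attenuation[0], attenuation[1], n_dysregulated)
        else:
            att = np.full(n_dysregulated, float(attenuation))
    else:
        if n_closer is None or n_half is None:
            raise ValueError("give either attenuation or both n_closer and n_half")
        if not 0 <= n_half <= n_closer <= n_dysregulated:
            raise ValueError("need 0 <= n_half <= n_closer <= n_dysregulated")
        att = np.concatenate([
            rng.uniform(0.05, 0.45, n_half),                      # attenuated to <= half
            rng.uniform(0.55, 0.95, n_closer - n_half),           # closer, but > half
            rng.uniform(1.05, 1.40, n_dysregulated - n_closer),   # further from WT
        ])

    sign = rng.choice([-1.0, 1.0], n_dysregulated)
    fc_ko = sign * rng.uniform(0.6, 3.0, n_dysregulated)
    fc_dko = fc_ko * att
    padj_ko = rng.uniform(1e-6, 0.01, n_dysregulated)
    padj_dko = rng.uniform(1e-6, 0.9, n_dysregulated)

    n_null = n_genes - n_dysregulated
    fc_ko = np.concatenate([fc_ko, rng.uniform(-0.3, 0.3, n_null)])
    fc_dko = np.concatenate([fc_dko, rng.uniform(-0.3, 0.3, n_null)])
    padj_ko = np.concatenate([padj_ko, rng.uniform(0.1, 1.0, n_null)])
    padj_dko = np.concatenate([padj_dko, rng.uniform(0.1, 1.0, n_null)])

    table = pd.DataFrame({
        "gene": [f"gene_{i:05d}" for i in range(n_genes)],
        "log2FC_KO": fc_ko, "padj_KO": padj_ko,
        "log2FC_DKO": fc_dko, "padj_DKO": padj_dko,
        "base_count": rng.integers(50, 5000, n_genes),
    })
    truth = pd.DataFrame({
        "gene": table["gene"],
        "dysregulated": np.arange(n_genes) < n_dysregulated,
        "closer": np.concatenate([np.abs(fc_dko[:n_dysregulated]) < np.abs(fc_ko[:n_dysregulated]),
                                  np.zeros(n_null, dtype=bool)]),
    })
    order = rng.permutation(n_genes)
    return table.iloc[order].reset_index(drop=True), truth.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr_cts(
    model: SpliceModel,
    calibrator: SpliceModel,
    transcription_rate: float = 1.0,
    ct_scale: float = 24.0,
    ct_ref: float = 20.0,
    noise_sd_cycles: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[CtSet, CtSet]:
    """Ct replicate sets for mature and pre-mRNA assays of a genotype
    against a calibrator genotype.

    Pre-mRNA abundance tracks transcription alone; mature abundance is
    transcription × mean NMD survival of the nascent pool, so the
    mature/pre relative-expression ratio recovers the model's expected
    stability ratio.  Ct = ct_scale − log2(abundance) plus optional
    Gaussian replicate noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def cts(abundance: float) -> tuple[float, ...]:
        base = ct_scale - np.log2(abundance)
        vals = base + (rng.normal(0.0, noise_sd_cycles, n_replicates) if noise_sd_cycles > 0 else np.zeros(n_replicates))
        return tuple(float(v) for v in vals)

    def ref_cts() -> tuple[float, ...]:
        vals = ct_ref + (rng.normal(0.0, noise_sd_cycles, n_replicates) if noise_sd_cycles > 0 else np.zeros(n_replicates))
        return tuple(float(v) for v in vals)

    mature = CtSet(
        target_test=cts(transcription_rate * expected_stability_ratio(model)),
        reference_test=ref_cts(),
        target_calibrator=cts(transcription_rate * expected_stability_ratio(calibrator)),
        reference_calibrator=ref_cts(),
    )
    pre = CtSet(
        target_test=cts(transcription_rate),
        reference_test=ref_cts(),
        target_calibrator=cts(transcription_rate),
        reference_calibrator=ref_cts(),
    )
    return mature, pre
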