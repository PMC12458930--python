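# Methods

## The splicing + NMD steady-state model

A transcript isoform is identified with the subset of alternative splice
elements it retains. Four elements mirror the Clcn1 situation in DM1
muscle: retained intron 2 (I2), cassette exon 7a (E7a), retained intron 6
(I6) and cassette exon 8a (E8a); all four disrupt the reading frame and so
create premature termination codons (PTCs).

Assumptions, in order of importance:

1. **Nascent independence.** Elements are included independently at the
   nascent stage with probabilities `p_e`. Any dependence observed in the
   steady-state pool therefore arises downstream, not from co-regulated
   splicing. This is the parsimony hypothesis the long-read analysis is
   designed to test: the alternative (direct co-regulation of every
   aberrant event) would require a dependence structure at the nascent
   stage.
2. **A single survival factor.** A transcript carrying ≥ 1 PTC-inducing
   element survives NMD with probability δ ∈ (0, 1], the same δ
   regardless of how many such elements it carries — a second
   NMD-triggering event does not further destabilize an already-targeted
   transcript. The `constitutive_ptc` flag (the ADR frameshift genotype)
   applies δ to every transcript.
3. **Steady state = survival-reweighted nascent law**, renormalized to
   sum to 1. The mature/pre-mRNA "stability ratio" is the mean survival
   of the nascent pool, `Σ_S nascent(S)·survival(S)`, which equals δ
   exactly under constitutive PTC.

A useful consequence: for two frame-disrupting events A and B with δ < 1,
`PSI(A | B included) > PSI(A | B excluded)` in the steady state (both
events' inclusion conditions the transcript into the same δ-weighted
stratum), with equality iff δ = 1 or PTC is constitutive. The pipeline's
qualitative target — conditional coupling in the Mbnl1 knockout,
no coupling in ADR — follows directly.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `p_E7a` (WT / KO) | 0.066 / 0.74 | — | anchored to the measured E7a PSI of wild-type and knockout muscle |
| `p` other events | 0.01–0.05 | — | rare aberrant events |
| δ (`nmd_survival`) | 0.25 | — | free calibration; no measured NMD efficiency exists for this transcript, 0.25 yields a knockout stability ratio ≈ 0.46× WT, in the qualitative range of the qPCR data |
| ΔE7a presets | `p_E7a = 0` | — | the exon is deleted from the gene |
| ADR preset | `constitutive_ptc` | — | frameshift upstream of all events |

The preset inclusion probabilities are nascent-stage quantities; with
δ < 1 the *observed* steady-state PSI sits below the nascent probability
(≈ 0.44 for the knockout's E7a at δ = 0.25). The presets deliberately
anchor the nascent probability to the measured values and leave δ as the
single stability dial.

## Synthetic data: what it emulates and what it does not

* **Long reads** are drawn i.i.d. from the steady-state law and rendered
  as exact BED12 block structures (cassette exon → extra block; retained
  intron → merged flanking blocks) spanning the whole gene. An optional
  truncation rate clips random 3′ tails for robustness tests; base-level
  sequence, alignment and chemistry error models are out of scope. Passing
  tests therefore demonstrate correctness of classification and of the
  statistical machinery, not robustness to alignment artifacts.
* **IV recordings** start each step at the modified-Boltzmann
  instantaneous value (fully activated by the +60 mV prepulse) and decay
  exponentially (τ = 150 ms) toward a steady-state open fraction given by
  a relative-Po law (floor 0.3); Gaussian current noise is white, which is
  optimistic relative to real line/seal noise. The capacitive transient is
  a clean exponential of known charge.
* **Force traces** rise exponentially to plateau; after the stimulus the
  force is a fast relaxation (τ = 20 ms) plus, for myotonic presets, a
  slow after-contraction `a·exp(−t/τ_m)` whose normalized integral is
  `a·τ_m` — the analytic anchor for the impulse computation.
* **EMG** is a sum of biphasic (Gaussian-derivative) motor-unit potentials
  at the stimulus rate, followed by a jittered post-stimulus run for
  myotonic presets, plus white noise.
* **dPSI / log2FC tables** plant labels with margins around every decision
  threshold so recovery is exact by construction; real data concentrate
  near thresholds and recovery there depends on the stated tie convention.

## Electrophysiology analysis

* Capacitance: `C = ∫I dt / ΔV` over the baseline-subtracted 10-mV
  transient (trapezoid).
* ClC-1 isolation: pointwise subtraction of the post-9-AC trace.
* Instantaneous current: signed extremum in a configurable window
  (default 1–5 ms after the step, skipping residual capacitive artifact)
  of the trace boxcar-smoothed over 2 ms — smoothing keeps the extremum
  estimator from tracking single-sample noise peaks. Steady-state
  current: mean of the final 10% of the step. Both divided by capacitance.
* **IV Boltzmann fit.** `I(Vm) = (Imax−Io)/(1+exp((V1/2−Vm)/kv)) + Io` by
  least squares (initialization: Imax = extremal CD, Io = CD at the most
  depolarized step, V1/2 = half-range crossing, |kv| = 15 mV). The
  parameterization is sign-degenerate — (Imax, Io, kv) ≡ (Io, Imax, −kv) —
  so both signs are tried and the result canonicalized with Imax the
  larger-magnitude plateau. For the inwardly rectifying instantaneous IV
  measured after a fully activating prepulse this lands on kv < 0 (Imax is
  the hyperpolarized inward plateau), while the relative-Po fit keeps
  kv > 0, the convention under which activation grows with depolarization.
  Non-convergence is flagged on the result, never raised.
* **Relative-Po fit.** Tails are referenced to the absolute maximal tail
  current; the least-squares model carries a free amplitude so Pmin is not
  biased by the maximal observed tail sitting slightly below the sigmoid
  asymptote (without it, a noiseless Pmin = 0.1 fit returns ≈ 0.1004).
* Nernst: `E = (RT/zF)·ln([Cl]_out/[Cl]_in)`, chloride tallied from salt
  stoichiometry (MgCl₂ contributes 2, etc.). The study's solutions give
  20 mM internal vs 165.5 mM external chloride → −53.7 mV at 295 K.

## Contraction and EMG analysis

* Specific force: `CSA = mass/(Lo × fiber_ratio × density)` with density
  1.06 g/cm³ and the muscle-specific fiber-length ratio (0.71 for
  soleus); peak force / CSA in mN/mm².
* Impulse: trapezoidal integral of `max(F_norm − baseline, 0)` from
  stimulus end over a 2-s window (the after-contraction tail is fully
  decayed well within it); baseline is the mean of 100 ms pre-stimulus;
  peak within the stimulus normalized to 1 AU, making the impulse
  scale-invariant.
* Force–frequency: `N(f) = bottom + (top−bottom)/(1+exp((f_half−f)/k_f))`
  by least squares on per-muscle-normalized forces; `f_half` is the
  summary statistic.
* Linear envelope: |EMG| through a second-order Butterworth low-pass
  (default 10 Hz — unspecified in standard protocols, chosen to pass
  burst-rate modulation while suppressing spike carriers) applied
  forward–backward, so the envelope is zero-phase/zero-lag.
  Post-stimulus activity ends when the envelope stays below
  baseline mean + 3 SD for ≥ 50 ms; an envelope that never settles is
  returned flagged with the full window duration.

## Rescue classification

Strict inequalities at every threshold (|dPSI| > 0.1 for a change,
shift > 0.15 for a partial rescue), implemented with a 10⁻⁹ guard so
exact boundary values never qualify regardless of float representation.
"Shift toward control" is `|dPSI_KO| − |dPSI_DKO|` when both contrasts
deviate the same way and `|dPSI_KO − dPSI_DKO|` when the double mutant
overshoots past control. "Non-changing in the double mutant" (the
complete-rescue condition) is judged on dPSI magnitude alone. The
significance column accepts an FDR (smaller is better, cutoff 0.05) or a
posterior confidence (larger is better, cutoff 0.95) via an explicit mode
flag, since both conventions appear in practice for this kind of table;
neither is privileged. Differential isoform usage is a per-isoform
two-sided Fisher exact test against the pooled remainder with BH
correction — a deliberate exact-test simplification of model-based
negative-binomial count testing, which is out of scope.

## Problem sizes and numerics

Simulated studies use 10⁴ reads per genotype for isoform tables
(10⁵ for conditional-PSI convergence checks), 21-step voltage families at
5–10 kHz, 100-replicate noise ensembles for fit-recovery statistics, and
200-row planted dPSI tables — sizes at which every binomial standard
error relevant to an assertion is at least three times smaller than the
effect asserted. All integration is trapezoidal; all generators accept
either an integer seed or a `numpy.random.Generator` so that ensembles
can be driven from a single spawning `SeedSequence`.

## Known limitations

* Nascent independence and the single-δ rule are modeling idealizations;
  the pipeline tests their *consequences*, it cannot validate them
  against real nascent-RNA measurements.
* Read classification assumes block-accurate alignments; splice-site
  wobble and alignment soft-clipping are not modeled.
* The exact-test differential-usage stand-in ignores biological
  replicate dispersion (samples are pooled within groups).
* The EMG generator produces stereotyped motor-unit potentials; spectra
  of real myotonic runs (waning frequency, dive-bomber pattern) are only
  coarsely approximated by the jittered constant-rate run.
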