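# myorescue

Quantitative analysis pipeline for studying whether **myotonia** — the
delayed relaxation of skeletal muscle caused by loss of the ClC-1 chloride
channel — drives the downstream myopathy of myotonic dystrophy type 1
(DM1) mouse models. The study system contrasts a myotonic *Mbnl1* knockout
with a non-myotonic double mutant in which the frameshift-inducing
alternative exon 7a (E7a) has been deleted from *Clcn1*, plus a
constitutive-NMD frameshift control (ADR). Every analysis stage runs on
seeded synthetic data with the statistical structure the real assays
assume, so the whole pipeline is testable on a laptop with no downloads.

## What's in the box

| module | what it does |
|---|---|
| `myorescue.splicemodel` | Generative splicing+NMD model: independent per-event inclusion probabilities, a single NMD survival factor δ for PTC-bearing transcripts, closed-form steady-state isoform frequencies and mature/pre-mRNA stability ratio |
| `myorescue.simulate` | Seeded generators for every input: BED12 long-read libraries, whole-cell voltage-step families, tetanic force traces, EMG burst runs, two-contrast dPSI and log2FC tables with planted truth |
| `myorescue.isoforms` | Block-coverage read classification, isoform count tables (≥100-read support), marginal/conditional PSI, exact-test differential isoform usage with BH correction |
| `myorescue.quant` | Densitometry PSI, 2^−ΔΔCt relative expression, mature/pre-mRNA stability ratio |
| `myorescue.ephys` | Capacitance from an integrated 10-mV transient, 9-AC offline subtraction, IV extraction, modified-Boltzmann IV fit, tail-current relative-Po fit, Nernst reversal potential |
| `myorescue.physio` | Specific force via cross-sectional area, myotonia impulse (post-tetanic normalized-force AUC), force–frequency Boltzmann fit, rectified + zero-phase Butterworth EMG linear envelope, FFT spectra |
| `myorescue.rescue` | Splicing-event rescue classification (unchanged / shared / partial / complete / novel), gene-overlap and expression-attenuation summaries |
| `myorescue.workflows` | End-to-end drivers wiring generators to analyses per genotype |
| `analysis/01…06_*.py` | Numbered narrative scripts writing tables under `results/` |

## The models at the core

**Splicing + NMD.** A transcript is the subset *S* of alternative elements
it retains (intron 2, E7a, intron 6, exon 8a). Elements splice
independently at the nascent stage, `P(S) = Π_{e∈S} p_e Π_{e∉S} (1−p_e)`;
any frame-disrupting element creates a premature termination codon, and
such transcripts survive nonsense-mediated decay with probability δ. The
observed steady state is the survival-reweighted nascent law. This one
mechanism makes independent NMD-inducing events *look* coupled in the
steady-state pool — `PSI(I2 | E7a+) > PSI(I2 | E7a−)` whenever δ < 1 — and
the coupling provably vanishes when every transcript is an NMD target
(the ADR control), which is exactly the dissociation the long-read data
show.

**Electrophysiology.** Instantaneous current densities are fit with the
modified Boltzmann `I(Vm) = (Imax − Io)/(1 + exp((V1/2 − Vm)/kv)) + Io`
and tail currents with
`Po,rel(Vm) = (1 − Pmin)/(1 + exp((V1/2 − Vm)/kv)) + Pmin`.

**Myotonia quantification.** Mechanical: the impulse
`∫ max(F_norm − baseline, 0) dt` after tetanus end, with the tetanic peak
normalized to 1 AU. Electrical: duration of the rectified, low-passed EMG
envelope above baseline + 3 SD after the stimulus artifact.

**Rescue classification.** An event mis-spliced in the knockout
(|dPSI| > 0.1, significant) is a *complete rescue* if non-changing in the
double mutant, a *partial rescue* if shifted toward control by > 0.15
dPSI, otherwise shared.

## Worked example

```python
from myorescue.workflows import e7a_dpsi_row
from myorescue.rescue import classify_event

row = e7a_dpsi_row(n_reads=10_000, seed=6)
print(row["dPSI_KO"], row["dPSI_DKO"], classify_event(row).label)
```

prints

```
0.4272 -0.0191 complete_rescue
```

— in 10,000 simulated reads per genotype, E7a inclusion rises by 43 PSI
points in the myotonic knockout versus wild type, is absent in the double
mutant (dPSI −1.9 points, within the non-changing band), and the event is
classified as a complete rescue, as the real E7a event must be.

Running the numbered analyses end to end:

```bash
for s in analysis/0*.py; do python "$s"; done
```

writes the PSI, IV-fit, myotonia and rescue tables under `results/` and
narrates each finding (NMD-driven conditional-PSI coupling in the knockout
but not ADR; knockout current density roughly half of wild type with the
double mutant above wild type; positive impulse and prolonged EMG envelope
only in the myotonic condition; 85% of dysregulated genes closer to wild
type without myotonia).

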