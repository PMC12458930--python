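"""Generative model of Clcn1-like transcript isoform pools under splicing + NMD.

A transcript is described by the subset of alternative splice elements it
contains (e.g. retained intron 2, cassette exon 7a).  Elements are spliced
independently at the nascent stage with per-element inclusion probabilities;
transcripts carrying at least one reading-frame-disrupting element acquire a
premature termination codon and survive nonsense-mediated decay (NMD) with
probability ``delta`` relative to frame-preserving transcripts.  The observed
steady-state isoform pool is the nascent product law reweighted by survival.

This single mechanism reproduces the key qualitative signature of the study
system: apparent co-enrichment (conditional dependence) of independent
NMD-inducing splice events in the steady-state pool, which disappears when
every transcript is an NMD target regardless of splicing (the ADR frameshift
genotype, ``constitutive_ptc=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Mapping

__all__ = [
    "SpliceModel",
    "ToyGeneModel",
    "GenotypePreset",
    "PRESETS",
    "steady_state_isoform_freqs",
    "expected_stability_ratio",
    "isoform_key",
    "toy_clcn1_gene",
    "default_model",
    "preset_model",
]

CASSETTE_EXON = "cassette_exon"
RETAINED_INTRON = "retained_intron"


def isoform_key(events: Iterable[str]) -> str:
    """Canonical string key for an event subset; the empty subset is 'canonical'."""
    ev = sorted(set(events))
    return "+".join(ev) if ev else "canonical"


@dataclass(frozen=True)
class SpliceModel:
    """Per-element inclusion probabilities plus an NMD survival factor.

    Parameters
    ----------
    events:
        Ordered alternative splice-element identifiers (unique).
    inclusion_prob:
        Nascent inclusion probability per element, each in [0, 1].
    frame_disrupting:
        Whether inclusion of the element shifts the downstream reading frame
        (and therefore creates a PTC / NMD target).
    nmd_survival:
        δ in (0, 1]: steady-state survival of a PTC-bearing transcript
        relative to a frame-preserving one.
    constitutive_ptc:
        If True, every transcript is an NMD target regardless of splice
        pattern (frameshift-mutant genotype); survival is δ uniformly.
    """

    events: tuple[str, ...]
    inclusion_prob: Mapping[str, float]
    frame_disrupting: Mapping[str, bool]
    nmd_survival: float = 1.0
    constitutive_ptc: bool = False

    def __post_init__(self) -> None:
        if len(set(self.events)) != len(self.events):
            raise ValueError("event identifiers must be unique")
        if not 0.0 < self.nmd_survival <= 1.0:
            raise ValueError("nmd_survival must lie in (0, 1]")
        for e in self.events:
            p = self.inclusion_prob[e]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"inclusion_prob[{e!r}]={p} outside [0, 1]")
            if e not in self.frame_disrupting:
                raise ValueError(f"missing frame_disrupting flag for {e!r}")

    def survival(self, subset: Iterable[str]) -> float:
        """NMD survival of a transcript containing exactly ``subset``.

        A single δ applies no matter how many PTC-inducing elements the
        transcript carries: a second NMD-triggering event does not further
        destabilize an already-targeted transcript.
        """
        if self.constitutive_ptc:
            return self.nmd_survival
        if any(self.frame_disrupting[e] for e in subset):
            return self.nmd_survival
        return 1.0

    def nascent_prob(self, subset: Iterable[str]) -> float:
        s = set(subset)
        p = 1.0
        for e in self.events:
            pe = self.inclusion_prob[e]
            p *= pe if e in s else (1.0 - pe)
        return p


def _subsets(events: tuple[str, ...]) -> Iterable[tuple[str, ...]]:
    return chain.from_iterable(combinations(events, k) for k in range(len(events) + 1))


def steady_state_isoform_freqs(model: SpliceModel) -> dict[str, float]:
    """Steady-state isoform frequencies: nascent product law × NMD survival.

    Returns a mapping from canonical isoform key (see :func:`isoform_key`) to
    frequency.  Frequencies sum to 1.  With no events the canonical isoform
    has frequency 1.
    """
    raw: dict[str, float] = {}
    for subset in _subsets(model.events):
        raw[isoform_key(subset)] = model.nascent_prob(subset) * model.survival(subset)
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def expected_stability_ratio(model: SpliceModel) -> float:
    """Mean NMD survival of the nascent pool.

    This is the model counterpart of the measured ratio of steady-state
    (mature) mRNA to pre-mRNA: pre-mRNA abundance tracks transcription while
    mature abundance is the survival-weighted output, so their ratio (up to a
    genotype-independent constant) equals Σ_S nascent(S)·survival(S).  Equals
    δ exactly when every transcript is a PTC target.
    """
    return sum(
        model.nascent_prob(subset) * model.survival(subset)
        for subset in _subsets(model.events)
    )


@dataclass(frozen=True)
class ToyGeneModel:
    """Minimal single-gene model hosting the alternative splice elements.

    ``exons`` are 0-based half-open genomic intervals (BED convention),
    sorted and non-overlapping.  ``event_map`` places each alternative
    element: a cassette exon is an extra exonic interval between two
    constitutive exons; a retained intron is the intron between two adjacent
    constitutive exons.
    """

    chrom: str
    exons: tuple[tuple[int, int], ...]
    event_map: Mapping[str, tuple[int, int, str]]  # event -> (start, end, class)
    strand: str = "+"

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError("exons must be sorted, non-overlapping, non-empty")
        span = (self.exons[0][0], self.exons[-1][1])
        for ev, (s, e, cls) in self.event_map.items():
            if cls not in (CASSETTE_EXON, RETAINED_INTRON):
                raise ValueError(f"unknown event class {cls!r} for {ev!r}")
            if not (span[0] <= s < e <= span[1]):
                raise ValueError(f"event {ev!r} outside gene span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def event_interval(self, event: str) -> tuple[int, int]:
        s, e, _ = self.event_map[event]
        return s, e

    def event_class(self, event: str) -> str:
        return self.event_map[event][2]


def toy_clcn1_gene(chrom: str = "chr6") -> ToyGeneModel:
    """Eight constitutive exons with four event slots mirroring the Clcn1
    alternative elements: retained intron 2 (I2), cassette exon 7a (E7a),
    retained intron 6 (I6), cassette exon 8a (E8a)."""
    exons = (
        (100, 300),    # exon 1
        (500, 700),    # exon 2
        (900, 1100),   # exon 3
        (1300, 1500),  # exon 4  ("exon 6" side of the E7a slot)
        (1900, 2100),  # exon 5
        (2500, 2700),  # exon 6
        (2900, 3100),  # exon 7
        (3300, 3500),  # exon 8
    )
    event_map = {
        "I2": (700, 900, RETAINED_INTRON),       # intron between exons 2 and 3
        "E7a": (1600, 1700, CASSETTE_EXON),      # cassette between exons 4 and 5
        "I6": (2100, 2500, RETAINED_INTRON),     # intron between exons 5 and 6
        "E8a": (3150, 3250, CASSETTE_EXON),      # cassette between exons 7 and 8
    }
    return ToyGeneModel(chrom=chrom, exons=exons, event_map=event_map)


DEFAULT_EVENTS = ("I2", "E7a", "I6", "E8a")
# All four Clcn1-like elements disrupt reading frame (PTC / NMD targets).
DEFAULT_FRAME_DISRUPTING = {e: True for e in DEFAULT_EVENTS}
DEFAULT_DELTA = 0.25

# Nascent E7a inclusion anchored to measured steady-state PSIs
# (wildtype 6.65%, Mbnl1 knockout 73.7%); other elements rare.
_PRESET_PROBS: dict[str, dict[str, float]] = {
    "WT": {"I2": 0.02, "E7a": 0.066, "I6": 0.02, "E8a": 0.01},
    "Mbnl1KO": {"I2": 0.05, "E7a": 0.74, "I6": 0.05, "E8a": 0.03},
    "dE7a": {"I2": 0.02, "E7a": 0.0, "I6": 0.02, "E8a": 0.01},
    "Mbnl1KO_dE7a": {"I2": 0.05, "E7a": 0.0, "I6": 0.05, "E8a": 0.03},
    "ADR": {"I2": 0.05, "E7a": 0.066, "I6": 0.05, "E8a": 0.01},
}


@dataclass(frozen=True)
class GenotypePreset:
    name: str
    model: SpliceModel = field(repr=False)


def default_model(
    inclusion_prob: Mapping[str, float],
    nmd_survival: float = DEFAULT_DELTA,
    constitutive_ptc: bool = False,
) -> SpliceModel:
    return SpliceModel(
        events=DEFAULT_EVENTS,
        inclusion_prob=dict(inclusion_prob),
        frame_disrupting=dict(DEFAULT_FRAME_DISRUPTING),
        nmd_survival=nmd_survival,
        constitutive_ptc=constitutive_ptc,
    )


def preset_model(name: str, nmd_survival: float = DEFAULT_DELTA) -> SpliceModel:
    """Genotype presets: WT, Mbnl1KO, dE7a, Mbnl1KO_dE7a, ADR.

    ΔE7a genotypes cannot include E7a (the exon is deleted from the gene);
    ADR is the constitutive-NMD frameshift control in which every transcript
    is degraded at rate 1−δ regardless of splice pattern.
    """
    if name not in _PRESET_PROBS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESET_PROBS)}")
    return default_model(
        _PRESET_PROBS[name],
        nmd_survival=nmd_survival,
        constitutive_ptc=(name == "ADR"),
    )


PRESETS = tuple(_PRESET_PROBS)
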