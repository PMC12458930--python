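"""Long-read isoform classification and conditional PSI analysis.

Block-aligned full-gene reads are classified per splice element by coverage
of the element's genomic interval: a cassette exon (or retained intron) is
called included when the read's blocks cover at least ``incl_frac`` of the
interval and excluded when they cover at most ``excl_frac``; anything in
between is ambiguous and is kept out of PSI denominators rather than forced
to a call.  Reads must cover both terminal anchor exons to count as
full-length.  Classified reads are collapsed into an isoform-by-sample count
table (isoforms under a support threshold pooled into "other"), from which
marginal and conditional PSI and differential isoform usage are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .bedio import BedRead
from .splicemodel import RETAINED_INTRON, ToyGeneModel, isoform_key

__all__ = [
    "ClassifyThresholds",
    "ReadClassification",
    "IsoformTable",
    "PsiEstimate",
    "UndefinedPsiError",
    "classify_read",
    "classify_reads",
    "build_isoform_table",
    "marginal_psi",
    "conditional_psi",
    "differential_isoform_usage",
]

INCLUDED = "included"
EXCLUDED = "excluded"
AMBIGUOUS = "ambiguous"

OTHER_ROW = "other"


class UndefinedPsiError(ValueError):
    """Raised when a (conditioned) PSI pool is empty."""


@dataclass(frozen=True)
class ClassifyThresholds:
    incl_frac: float = 0.9
    excl_frac: float = 0.1
    anchor_frac: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.excl_frac < self.incl_frac <= 1.0:
            raise ValueError("need 0 <= excl_frac < incl_frac <= 1")
        if not 0.0 < self.anchor_frac <= 1.0:
            raise ValueError("anchor_frac must lie in (0, 1]")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    event_status: Mapping[str, str]  # event -> included | excluded | ambiguous
    full_length: bool

    @property
    def unambiguous(self) -> bool:
        return all(s != AMBIGUOUS for s in self.event_status.values())

    @property
    def included_events(self) -> tuple[str, ...]:
        return tuple(sorted(e for e, s in self.event_status.items() if s == INCLUDED))

    @property
    def isoform(self) -> str:
        return isoform_key(self.included_events)


def _covered_fraction(blocks: Sequence[tuple[int, int]], interval: tuple[int, int]) -> float:
    lo, hi = interval
    covered = sum(max(0, min(e, hi) - max(s, lo)) for s, e in blocks)
    return covered / (hi - lo)


def classify_read(
    read: BedRead,
    gene: ToyGeneModel,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> ReadClassification:
    """Classify one block-aligned read against the gene's splice elements.

    Block order in the input record is irrelevant (``BedRead`` sorts and
    rejects zero-length blocks on construction).  Reads on another
    chromosome are a configuration error.
    """
    if read.chrom != gene.chrom:
        raise ValueError(f"read {read.name!r} on {read.chrom}, gene on {gene.chrom}")
    status: dict[str, str] = {}
    for event in gene.event_map:
        frac = _covered_fraction(read.blocks, gene.event_interval(event))
        if frac >= thresholds.incl_frac:
            status[event] = INCLUDED
        elif frac <= thresholds.excl_frac:
            status[event] = EXCLUDED
        else:
            status[event] = AMBIGUOUS
    first_exon, last_exon = gene.exons[0], gene.exons[-1]
    full_length = (
        _covered_fraction(read.blocks, first_exon) >= thresholds.anchor_frac
        and _covered_fraction(read.blocks, last_exon) >= thresholds.anchor_frac
    )
    return ReadClassification(read_id=read.name, event_status=status, full_length=full_length)


def classify_reads(
    reads: Iterable[BedRead],
    gene: ToyGeneModel,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> list[ReadClassification]:
    """Classify many reads, memoizing on block structure (synthetic libraries
    contain few distinct structures, so this is far cheaper than per-read work)."""
    cache: dict[tuple, tuple[Mapping[str, str], bool]] = {}
    out: list[ReadClassification] = []
    for read in reads:
        key = read.blocks
        hit = cache.get(key)
        if hit is None:
            cls = classify_read(read, gene, thresholds)
            cache[key] = (cls.event_status, cls.full_length)
            out.append(cls)
        else:
            out.append(ReadClassification(read_id=read.name, event_status=hit[0], full_length=hit[1]))
    return out


@dataclass
class IsoformTable:
    """Isoform (event-subset) × sample read-count table.

    ``counts`` rows are canonical isoform keys (plus an ``other`` row pooling
    isoforms below the support threshold); ``excluded`` tallies reads per
    sample that were not counted (not full-length or ambiguous).
    """

    counts: pd.DataFrame
    min_support: int
    excluded: pd.Series
    sample_meta: pd.DataFrame | None = None


def build_isoform_table(
    classifications: Mapping[str, Sequence[ReadClassification]],
    min_support: int = 100,
    sample_meta: pd.DataFrame | None = None,
) -> IsoformTable:
    """Collapse per-sample read classifications into an isoform count table.

    Only full-length, unambiguous reads are counted; isoforms whose total
    support across samples is below ``min_support`` are pooled into the
    ``other`` row.  The default threshold of 100 supporting reads matches
    standard long-read isoform-collapsing practice.
    """
    samples = list(classifications)
    tallies: dict[str, dict[str, int]] = {}
    excluded = {}
    for sample in samples:
        n_excluded = 0
        for cls in classifications[sample]:
            if not (cls.full_length and cls.unambiguous):
                n_excluded += 1
                continue
            tallies.setdefault(cls.isoform, dict.fromkeys(samples, 0))[sample] += 1
        excluded[sample] = n_excluded
    counts = pd.DataFrame(tallies).T.reindex(columns=samples).fillna(0).astype(int)
    if counts.empty:
        counts = pd.DataFrame(columns=samples, dtype=int)

    keep = counts.sum(axis=1) >= min_support
    kept = counts.loc[keep]
    pooled = counts.loc[~keep].sum(axis=0)
    if (pooled > 0).any() or (~keep).any():
        kept = pd.concat([kept, pooled.rename(OTHER_ROW).to_frame().T])
    kept = kept.sort_values(by=list(kept.columns), ascending=False, kind="stable")
    return IsoformTable(counts=kept.astype(int), min_support=min_support,
                        excluded=pd.Series(excluded), sample_meta=sample_meta)


@dataclass(frozen=True)
class PsiEstimate:
    event: str
    psi: float
    n_inclusion: int
    n_total: int
    conditioning: tuple[str, str] | None = None  # (event, included|excluded)

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")


def _counted(classifications: Iterable[ReadClassification]) -> list[ReadClassification]:
    return [c for c in classifications if c.full_length and c.unambiguous]


def marginal_psi(classifications: Iterable[ReadClassification], event: str) -> PsiEstimate:
    """PSI of one event over all countable (full-length, unambiguous) reads."""
    pool = _counted(classifications)
    if not pool:
        raise UndefinedPsiError(f"empty read pool for event {event!r}")
    n_inc = sum(c.event_status[event] == INCLUDED for c in pool)
    return PsiEstimate(event=event, psi=n_inc / len(pool), n_inclusion=n_inc, n_total=len(pool))


def conditional_psi(
    classifications: Iterable[ReadClassification],
    event: str,
    given_event: str,
    given_state: str = INCLUDED,
) -> PsiEstimate:
    """PSI of ``event`` within the stratum of reads where ``given_event`` has
    ``given_state`` — the transcript-pool "sorting" that exposes NMD-driven
    co-enrichment of independent splice events."""
    if given_state not in (INCLUDED, EXCLUDED):
        raise ValueError("given_state must be 'included' or 'excluded'")
    pool = [c for c in _counted(classifications) if c.event_status[given_event] == given_state]
    if not pool:
        raise UndefinedPsiError(
            f"empty stratum: no reads with {given_event!r} {given_state}"
        )
    n_inc = sum(c.event_status[event] == INCLUDED for c in pool)
    return PsiEstimate(event=event, psi=n_inc / len(pool), n_inclusion=n_inc,
                       n_total=len(pool), conditioning=(given_event, given_state))


def differential_isoform_usage(
    table: IsoformTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-isoform differential usage between two sample groups.

    For each isoform, a two-sided Fisher exact test of (isoform count vs all
    remaining counts) on group-pooled totals, Benjamini–Hochberg corrected
    across isoforms, with direction as the log2 ratio of group proportions.
    A deliberate exact-test simplification of model-based count testing.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    counts = table.counts
    a = counts[list(group_a)].sum(axis=1)
    b = counts[list(group_b)].sum(axis=1)
    na, nb = int(a.sum()), int(b.sum())
    present = (a + b) > 0
    rows = []
    for iso in counts.index[present]:
        ka, kb = int(a[iso]), int(b[iso])
        _, p = fisher_exact([[ka, na - ka], [kb, nb - kb]], alternative="two-sided")
        with np.errstate(divide="ignore"):
            log2_ratio = float(np.log2((ka / na) / (kb / nb))) if ka and kb else (
                np.inf if ka else -np.inf
            )
        rows.append({"isoform": iso, "count_a": ka, "count_b": kb, "p_value": p,
                     "log2_proportion_ratio": log2_ratio})
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["q_value"] = []
    return result.set_index("isoform")
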