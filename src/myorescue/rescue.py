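"""Classification of splicing-event rescue and expression attenuation.

Given per-event dPSI statistics for two contrasts against wild type — the
myotonic knockout (KO vs WT) and the non-myotonic double mutant (DKO vs WT)
— each event is labeled:

* ``unchanged``           — not significantly changed in either contrast;
* ``mis_spliced_shared``  — changed in KO and still changed, with little
                            shift toward control, in DKO;
* ``partial_rescue``      — changed in KO, still changing in DKO but shifted
                            toward control by more than ``partial_shift``;
* ``complete_rescue``     — changed in KO and non-changing (|dPSI| within
                            the change threshold) in DKO;
* ``novel_in_DKO``        — changed only in DKO.

All thresholds compare with strict inequalities so boundary ties are
deterministic.  Significance columns accept either an FDR (smaller is
better, cutoff 0.05) or a posterior confidence (larger is better, cutoff
0.95) via an explicit mode flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RescueThresholds",
    "RescueCall",
    "LABELS",
    "classify_event",
    "classify_table",
    "overlap_summary",
    "attenuation_summary",
    "bh_adjust",
    "toward_control_shift",
]

LABELS = ("unchanged", "mis_spliced_shared", "partial_rescue", "complete_rescue", "novel_in_DKO")

STAT_FDR = "fdr"
STAT_CONFIDENCE = "confidence"

# strict ">" at a threshold, robust to float roundoff so that exact boundary
# values (|dPSI| = 0.1, shift = 0.15) never qualify
_EPS = 1e-9


def _exceeds(value: float, threshold: float) -> bool:
    return value - threshold > _EPS


@dataclass(frozen=True)
class RescueThresholds:
    dpsi_change: float = 0.1
    partial_shift: float = 0.15
    stat_cutoff: float = 0.05
    stat_mode: str = STAT_FDR

    def __post_init__(self) -> None:
        if self.dpsi_change <= 0 or self.partial_shift <= 0 or self.stat_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if self.stat_mode not in (STAT_FDR, STAT_CONFIDENCE):
            raise ValueError("stat_mode must be 'fdr' or 'confidence'")

    def stat_passes(self, stat: float) -> bool:
        if np.isnan(stat):
            raise ValueError("missing significance statistic")
        if self.stat_mode == STAT_FDR:
            return stat < self.stat_cutoff
        return stat > self.stat_cutoff


@dataclass(frozen=True)
class RescueCall:
    event_id: str
    gene: str
    label: str
    shift: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def toward_control_shift(dpsi_ko: float, dpsi_dko: float) -> float:
    """Signed dPSI shift toward control (WT) between the two contrasts.

    When both contrasts deviate in the same direction the shift is the drop
    in magnitude |dPSI_KO| − |dPSI_DKO|; when the double mutant crosses to
    the other side of control, the full distance |dPSI_KO − dPSI_DKO|
    counts as movement toward (and past) control.
    """
    if dpsi_ko == 0.0 or dpsi_dko == 0.0 or np.sign(dpsi_ko) == np.sign(dpsi_dko):
        return abs(dpsi_ko) - abs(dpsi_dko)
    return abs(dpsi_ko - dpsi_dko)


def classify_event(
    row: Mapping[str, float | str],
    thresholds: RescueThresholds = RescueThresholds(),
) -> RescueCall:
    """Label one splicing event from its two-contrast dPSI statistics.

    ``row`` must provide gene, event_id, dPSI_KO, stat_KO, dPSI_DKO,
    stat_DKO.  A missing statistic raises; callers that want to drop such
    rows should use :func:`classify_table`.
    """
    dpsi_ko = float(row["dPSI_KO"])
    dpsi_dko = float(row["dPSI_DKO"])
    changed_ko = _exceeds(abs(dpsi_ko), thresholds.dpsi_change) and thresholds.stat_passes(float(row["stat_KO"]))
    changed_dko = _exceeds(abs(dpsi_dko), thresholds.dpsi_change) and thresholds.stat_passes(float(row["stat_DKO"]))
    shift = toward_control_shift(dpsi_ko, dpsi_dko)

    if changed_ko:
        if not _exceeds(abs(dpsi_dko), thresholds.dpsi_change):  # non-changing in DKO
            label = "complete_rescue"
        elif _exceeds(shift, thresholds.partial_shift):
            label = "partial_rescue"
        else:
            label = "mis_spliced_shared"
    elif changed_dko:
        label = "novel_in_DKO"
    else:
        label = "unchanged"
    return RescueCall(event_id=str(row["event_id"]), gene=str(row["gene"]),
                      label=label, shift=shift)


def classify_table(
    table: pd.DataFrame,
    thresholds: RescueThresholds = RescueThresholds(),
) -> pd.DataFrame:
    """Classify every event row; rows with missing statistics are dropped
    (and reported in the ``excluded`` attribute of the result)."""
    required = {"gene", "event_id", "dPSI_KO", "stat_KO", "dPSI_DKO", "stat_DKO"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dPSI table missing columns: {sorted(missing)}")
    complete = table.dropna(subset=["dPSI_KO", "stat_KO", "dPSI_DKO", "stat_DKO"])
    calls = [classify_event(row, thresholds) for row in complete.to_dict("records")]
    out = pd.DataFrame(
        {
            "event_id": [c.event_id for c in calls],
            "gene": [c.gene for c in calls],
            "label": [c.label for c in calls],
            "shift": [c.shift for c in calls],
        }
    )
    out.attrs["excluded"] = int(len(table) - len(complete))
    return out


def overlap_summary(
    genes_ko: Iterable[str],
    genes_dko: Iterable[str],
) -> dict[str, float]:
    """Set overlap of mis-spliced genes between the two contrasts.

    Gene identity deduplicates events: a gene with several qualifying events
    counts once.  ``shared_pct`` is shared / union × 100.
    """
    a, b = set(genes_ko), set(genes_dko)
    shared = a & b
    union = a | b
    return {
        "shared": len(shared),
        "unique_KO": len(a - b),
        "unique_DKO": len(b - a),
        "shared_pct": 100.0 * len(shared) / len(union) if union else 0.0,
    }


def attenuation_summary(
    table: pd.DataFrame,
    fc_cut: float = 0.5,
    padj_cut: float = 0.05,
) -> dict[str, float]:
    """Expression attenuation of KO-dysregulated genes in the double mutant.

    Dysregulated: |log2FC_KO| > ``fc_cut`` and padj_KO < ``padj_cut``.
    Among those, ``closer`` genes have |log2FC_DKO| < |log2FC_KO| (DKO
    expression nearer wild type) and ``half`` genes are attenuated to at
    most half the KO fold change, |log2FC_DKO| ≤ 0.5·|log2FC_KO|.
    """
    required = {"log2FC_KO", "padj_KO", "log2FC_DKO", "padj_DKO"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    dys = table[(table["log2FC_KO"].abs() > fc_cut) & (table["padj_KO"] < padj_cut)]
    n_dys = len(dys)
    if n_dys == 0:
        raise ValueError("no dysregulated genes at the stated thresholds; fractions undefined")
    closer = dys["log2FC_DKO"].abs() < dys["log2FC_KO"].abs()
    half = dys["log2FC_DKO"].abs() <= 0.5 * dys["log2FC_KO"].abs()
    return {
        "n_dysregulated": n_dys,
        "n_closer": int(closer.sum()),
        "frac_closer": float(closer.mean()),
        "n_half_attenuated": int(half.sum()),
        "frac_half_attenuated": float(half.mean()),
    }


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
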