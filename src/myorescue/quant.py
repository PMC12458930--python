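"""RT-PCR densitometry and qPCR relative quantification.

PSI from gel band densitometry (optionally length-normalized, since ethidium
bromide intercalation scales with amplicon length), relative expression by
the 2^−ΔΔCt method, and the mature/pre-mRNA stability ratio used as a proxy
for transcript survival of nonsense-mediated decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BandDensities",
    "CtSet",
    "StabilityRatio",
    "UndefinedPsiError",
    "psi_from_densities",
    "relative_expression",
    "stability_ratio",
]


class UndefinedPsiError(ValueError):
    """Raised when a PSI denominator is empty (both band intensities zero)."""


@dataclass(frozen=True)
class BandDensities:
    """Inclusion/exclusion band intensities (arbitrary units, ≥ 0) with
    optional amplicon lengths for EtBr length normalization."""

    inclusion_intensity: float
    exclusion_intensity: float
    inclusion_length: float | None = None
    exclusion_length: float | None = None

    def __post_init__(self) -> None:
        if self.inclusion_intensity < 0 or self.exclusion_intensity < 0:
            raise ValueError("band intensities must be non-negative")
        if (self.inclusion_length is None) != (self.exclusion_length is None):
            raise ValueError("supply both amplicon lengths or neither")


def psi_from_densities(bands: BandDensities) -> float:
    """PSI = inclusion / (inclusion + exclusion) after optional length
    normalization (each intensity divided by its amplicon length)."""
    inc, exc = bands.inclusion_intensity, bands.exclusion_intensity
    if bands.inclusion_length is not None:
        if bands.inclusion_length <= 0 or bands.exclusion_length <= 0:
            raise ValueError("amplicon lengths must be positive")
        inc /= bands.inclusion_length
        exc /= bands.exclusion_length
    total = inc + exc
    if total == 0:
        raise UndefinedPsiError("both band intensities are zero; PSI undefined")
    return inc / total


@dataclass(frozen=True)
class CtSet:
    """Ct cycles for a 2^−ΔΔCt computation.

    Each field holds one or more technical replicates; replicates are
    arithmetically averaged on the cycle scale (i.e. a geometric mean on the
    linear expression scale) before ΔCt is formed.
    """

    target_test: Sequence[float]
    reference_test: Sequence[float]
    target_calibrator: Sequence[float]
    reference_calibrator: Sequence[float]

    def __post_init__(self) -> None:
        for name in ("target_test", "reference_test", "target_calibrator", "reference_calibrator"):
            vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if vals.size == 0:
                raise ValueError(f"{name} has no Ct values")
            if np.any(vals <= 0):
                raise ValueError(f"{name} contains non-positive Ct cycles")
            object.__setattr__(self, name, tuple(vals))


def relative_expression(cts: CtSet) -> float:
    """Relative expression by 2^−ΔΔCt.

    ΔCt = mean Ct(target) − mean Ct(reference) per sample;
    ΔΔCt = ΔCt(test) − ΔCt(calibrator); returns 2^−ΔΔCt, so the calibrator
    measured against itself is exactly 1.
    """
    d_test = float(np.mean(cts.target_test)) - float(np.mean(cts.reference_test))
    d_cal = float(np.mean(cts.target_calibrator)) - float(np.mean(cts.reference_calibrator))
    return float(2.0 ** (-(d_test - d_cal)))


@dataclass(frozen=True)
class StabilityRatio:
    mature_rel_expr: float
    pre_rel_expr: float

    def __post_init__(self) -> None:
        if self.mature_rel_expr <= 0:
            raise ValueError("mature relative expression must be positive")
        if self.pre_rel_expr <= 0:
            raise ValueError("pre-mRNA relative expression must be positive")

    @property
    def ratio(self) -> float:
        return self.mature_rel_expr / self.pre_rel_expr


def stability_ratio(mature_rel_expr: float, pre_rel_expr: float) -> StabilityRatio:
    """Ratio of relative steady-state (mature) to pre-mRNA expression.

    Pre-mRNA abundance tracks transcription while mature abundance reflects
    post-splicing survival, so the ratio indexes transcript stability: in
    the generative splicing+NMD model it tracks the mean nascent-pool
    survival up to a genotype-independent constant.
    """
    return StabilityRatio(mature_rel_expr=mature_rel_expr, pre_rel_expr=pre_rel_expr)
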