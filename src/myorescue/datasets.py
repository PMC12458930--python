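"""Published summary measurements from the myotonia-rescue mouse study.

These are the study's printed group-level numbers (means, counts, solution
compositions).  They serve two roles: as inputs to the desk-scale arithmetic
reproductions (specific-force deficit, mis-spliced gene overlap, expression
attenuation fractions, Nernst reversal potential of the recording
solutions) and as anchors for the synthetic-data genotype presets.
"""

from __future__ import annotations

import numpy as np

from .ephys import BoltzmannIVParams, SolutionSpec

__all__ = [
    "SOLEUS_SPECIFIC_FORCE_MN_MM2",
    "E7A_PSI_PERCENT",
    "PEAK_INSTANTANEOUS_CD_PA_PF",
    "MISSPLICED_GENE_OVERLAP",
    "DE_ATTENUATION_COUNTS",
    "RECORDING_SOLUTIONS",
    "iv_params_for_genotype",
]

# Peak soleus specific force (mN/mm²) under 150 Hz / 500 ms tetani,
# 4-6-month-old mice (group means).
SOLEUS_SPECIFIC_FORCE_MN_MM2 = {
    "WT": 201.3,
    "Mbnl1KO": 144.9,
    "Mbnl1KO_dE7a": 178.0,
}

# Clcn1 exon 7a percent spliced in by RT-PCR densitometry at P18 (means).
E7A_PSI_PERCENT = {"WT": 6.65, "Mbnl1KO": 73.7}

# Peak inward instantaneous ClC-1 current density at the −140 mV step (pA/pF),
# P18 FDB fibers (group means).
PEAK_INSTANTANEOUS_CD_PA_PF = {
    "WT": -42.1,
    "Mbnl1KO": -25.3,
    "Mbnl1KO_dE7a": -56.4,
    "ADR": 0.03,
}

# Genes mis-spliced vs wild type (|dPSI| > 0.1, significant) in the myotonic
# knockout only, the non-myotonic double mutant only, and both.
MISSPLICED_GENE_OVERLAP = {"shared": 340, "unique_KO": 207, "unique_DKO": 113}

# Differential-expression attenuation counts (KO vs WT dysregulated genes and
# how many sit closer to wild type / at most half the fold change in the
# non-myotonic double mutant).
DE_ATTENUATION_COUNTS = {"n_dysregulated": 1983, "n_closer": 1686, "n_half": 782}

# Whole-cell recording solutions (mM).  Chloride tallies: internal
# 10 (CsCl) + 2×5 (MgCl2) = 20 mM; external 145 (TEA-Cl) + 2×10 (CaCl2)
# + 2×0.25 (CdCl2) = 165.5 mM.
RECORDING_SOLUTIONS = SolutionSpec(
    internal_mm={"Cs-aspartate": 130.0, "CsCl": 10.0, "MgCl2": 5.0,
                 "Cs2-EGTA": 10.0, "HEPES": 10.0},
    external_mm={"TEA-Cl": 145.0, "CaCl2": 10.0, "HEPES": 10.0,
                 "CdCl2": 0.25, "nifedipine": 0.003},
    temperature_k=295.0,  # room temperature
)


def iv_params_for_genotype(
    genotype: str,
    io_pa_pf: float = 15.0,
    v_half_mv: float = -80.0,
    kv_mv: float = -20.0,
) -> BoltzmannIVParams:
    """Modified-Boltzmann IV parameters whose value at −140 mV matches the
    genotype's measured peak instantaneous current density.

    kv is negative so that the sigmoid saturates toward Imax at
    hyperpolarized potentials (inwardly rectifying instantaneous IV after a
    fully activating prepulse) and relaxes to the offset Io at +60 mV.
    """
    target = PEAK_INSTANTANEOUS_CD_PA_PF[genotype]
    gate = 1.0 / (1.0 + np.exp((v_half_mv + 140.0) / kv_mv))
    imax = io_pa_pf + (target - io_pa_pf) / gate
    params = BoltzmannIVParams(imax=imax, io=io_pa_pf, v_half=v_half_mv, kv=kv_mv)
    assert abs(float(params.predict(-140.0)) - target) < 1e-9
    return params
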