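#!/usr/bin/env python
"""Long-read isoform analysis across genotypes.

Simulates 10,000 full-length reads per genotype preset, classifies them,
and computes: marginal PSI per splice event, conditional PSI of intron 2
given E7a status (the NMD-dissociation signature separating the Mbnl1
knockout from the constitutive-NMD ADR control), the isoform count table,
and differential isoform usage between knockout and wild type.
"""

from pathlib import Path

import pandas as pd

from myorescue.isoforms import (
    EXCLUDED,
    INCLUDED,
    build_isoform_table,
    conditional_psi,
    differential_isoform_usage,
)
from myorescue.workflows import psi_summary, simulate_isoform_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

N_READS = 10_000
study = simulate_isoform_study(N_READS, seed=2)

psi = psi_summary(study)
psi.to_csv(OUT / "isoform_psi.tsv", sep="\t", index=False)
wide = psi.pivot(index="event", columns="genotype", values="psi").round(4)
print("marginal PSI (steady-state pool):")
print(wide.to_string(), "\n")

rows = []
for genotype in ("Mbnl1KO", "ADR"):
    inc = conditional_psi(study[genotype], "I2", "E7a", INCLUDED)
    exc = conditional_psi(study[genotype], "I2", "E7a", EXCLUDED)
    rows.append({"genotype": genotype, "psi_I2_given_E7a_inc": inc.psi,
                 "psi_I2_given_E7a_exc": exc.psi, "gap": inc.psi - exc.psi})
cond = pd.DataFrame(rows)
cond.to_csv(OUT / "conditional_psi.tsv", sep="\t", index=False)
print("conditional PSI of intron 2 by E7a status:")
print(cond.round(4).to_string(index=False))
print("-> NMD couples independent events in the knockout; the coupling "
      "vanishes when every transcript is an NMD target (ADR).\n")

table = build_isoform_table(study, min_support=100)
table.counts.to_csv(OUT / "isoform_counts.tsv", sep="\t")
print(f"isoform table: {len(table.counts)} rows at >=100 supporting reads")

diff = differential_isoform_usage(table, ["Mbnl1KO"], ["WT"])
diff.to_csv(OUT / "differential_isoform_usage.tsv", sep="\t")
top = diff.sort_values("q_value").head(5)
print("top differential isoforms, Mbnl1KO vs WT:")
print(top.round(6).to_string())
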