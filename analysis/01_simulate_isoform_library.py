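#!/usr/bin/env python
"""Generate a small demonstration long-read library per genotype.

Writes the toy Clcn1-like gene model (GTF), its splice-event definitions
(TSV), and a 100-read BED12 library plus truth table per genotype preset
under results/simulated/.  The downstream analyses regenerate larger
libraries in memory; these files document the on-disk formats.
"""

from pathlib import Path

from myorescue.bedio import write_bed12, write_events_tsv, write_gene_gtf
from myorescue.simulate import simulate_long_reads
from myorescue.splicemodel import PRESETS, preset_model, toy_clcn1_gene

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

gene = toy_clcn1_gene()
write_gene_gtf(gene, OUT / "toygene.gtf")
write_events_tsv(gene, OUT / "splice_events.tsv")

for seed, name in enumerate(PRESETS, start=100):
    reads, truth = simulate_long_reads(preset_model(name), gene, 100, seed=seed)
    write_bed12(reads, OUT / f"reads_{name}.bed")
    truth.to_csv(OUT / f"truth_{name}.tsv", sep="\t", index=False)
    n_e7a = int(truth["E7a"].sum())
    print(f"{name:>14s}: 100 reads, {n_e7a:3d} contain E7a, "
          f"{truth['isoform'].nunique()} distinct isoforms")

print(f"\nwrote gene model, event definitions and per-genotype libraries to {OUT}")
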