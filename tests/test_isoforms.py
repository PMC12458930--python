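"""Read classification, isoform tables, conditional PSI, differential usage."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from myorescue.bedio import BedRead
from myorescue.isoforms import (
    AMBIGUOUS,
    EXCLUDED,
    INCLUDED,
    OTHER_ROW,
    ClassifyThresholds,
    ReadClassification,
    UndefinedPsiError,
    build_isoform_table,
    classify_read,
    classify_reads,
    conditional_psi,
    differential_isoform_usage,
    marginal_psi,
)
from myorescue.simulate import isoform_blocks, simulate_long_reads
from myorescue.splicemodel import preset_model



def mk_classifications(isoform_events, n, offset=0):
    status = {e: (INCLUDED if e in isoform_events else EXCLUDED)
              for e in ("I2", "E7a", "I6", "E8a")}
    return [
        ReadClassification(read_id=f"r{offset + i}", event_status=status, full_length=True)
        for i in range(n)
    ]

def make_read(gene, subset, name="r0"):
    return BedRead(chrom=gene.chrom, name=name, blocks=isoform_blocks(gene, subset))


class TestClassifyRead:
    def test_canonical_read_excludes_all_full_length(self, gene):
        cls = classify_read(make_read(gene, ()), gene)
        assert all(s == EXCLUDED for s in cls.event_status.values())
        assert cls.full_length

    def test_constructed_inclusion_calls(self, gene):
        cls = classify_read(make_read(gene, ("E7a", "I6")), gene)
        assert cls.event_status["E7a"] == INCLUDED
        assert cls.event_status["I6"] == INCLUDED
        assert cls.event_status["I2"] == EXCLUDED

    def test_block_order_invariance(self, gene):
        blocks = isoform_blocks(gene, ("E7a",))
        shuffled = BedRead(chrom=gene.chrom, name="r", blocks=tuple(reversed(blocks)))
        a = classify_read(shuffled, gene)
        b = classify_read(BedRead(chrom=gene.chrom, name="r", blocks=blocks), gene)
        assert a.event_status == b.event_status

    def test_zero_length_block_rejected(self, gene):
        with pytest.raises(ValueError):
            BedRead(chrom=gene.chrom, name="bad", blocks=((100, 100), (200, 300)))

    def test_wrong_chromosome_rejected(self, gene):
        read = BedRead(chrom="chrX", name="r", blocks=gene.exons)
        with pytest.raises(ValueError):
            classify_read(read, gene)

    def test_partial_coverage_is_ambiguous(self, gene):
        s, e = gene.event_interval("E7a")
        mid = (s + e) // 2  # covers half the cassette: between 0.1 and 0.9
        blocks = tuple(b for b in gene.exons) + ((s, mid),)
        cls = classify_read(BedRead(chrom=gene.chrom, name="r", blocks=blocks), gene)
        assert cls.event_status["E7a"] == AMBIGUOUS
        assert not cls.unambiguous

    def test_truncated_read_not_full_length(self, gene):
        blocks = gene.exons[:-2]  # missing the terminal anchor exon
        cls = classify_read(BedRead(chrom=gene.chrom, name="r", blocks=blocks), gene)
        assert not cls.full_length

    def test_simulated_reads_match_generator_truth(self, gene, ko_model):
        reads, truth = simulate_long_reads(ko_model, gene, 10_000, seed=13)
        cls = classify_reads(reads, gene)
        truth_iso = dict(zip(truth["read_id"], truth["isoform"]))
        assert all(c.isoform == truth_iso[c.read_id] and c.full_length for c in cls)


class TestIsoformTable:
    def test_counts_without_support_threshold(self):
        cls = mk_classifications((), 7) + mk_classifications(("E7a",), 3, 100)
        table = build_isoform_table({"s1": cls}, min_support=0)
        assert table.counts.loc["canonical", "s1"] == 7
        assert table.counts.loc["E7a", "s1"] == 3

    def test_low_support_collapsed_to_other(self):
        cls = mk_classifications((), 7) + mk_classifications(("E7a",), 3, 100)
        table = build_isoform_table({"s1": cls}, min_support=5)
        assert table.counts.loc[OTHER_ROW, "s1"] == 3
        assert "E7a" not in table.counts.index

    def test_ambiguous_and_truncated_reads_tallied_separately(self):
        good = mk_classifications((), 4)
        bad = [ReadClassification(read_id="t0", event_status={"E7a": AMBIGUOUS},
                                  full_length=True),
               ReadClassification(read_id="t1", event_status={"E7a": EXCLUDED},
                                  full_length=False)]
        table = build_isoform_table({"s1": good + bad}, min_support=0)
        assert table.counts["s1"].sum() == 4
        assert table.excluded["s1"] == 2

    def test_simulated_multi_genotype_rows_match_planted_isoforms(self, gene):
        classifications = {}
        expected = set()
        for seed, name in enumerate(("WT", "Mbnl1KO", "dE7a"), start=31):
            reads, truth = simulate_long_reads(preset_model(name), gene, 4000, seed=seed)
            classifications[name] = classify_reads(reads, gene)
            expected |= set(truth["isoform"].value_counts().pipe(lambda s: s[s >= 100]).index)
        table = build_isoform_table(classifications, min_support=100)
        rows = set(table.counts.index) - {OTHER_ROW}
        # every planted isoform with >=100 reads in one sample is present
        assert expected <= rows


class TestPsi:
    def _pool(self):
        return (mk_classifications(("E7a", "I2"), 10, 0)
                + mk_classifications(("E7a",), 10, 100)
                + mk_classifications(("I2",), 5, 200)
                + mk_classifications((), 75, 300))

    def test_counting_example(self):
        pool = self._pool()
        assert marginal_psi(pool, "E7a").psi == pytest.approx(0.20)
        assert conditional_psi(pool, "I2", "E7a", INCLUDED).psi == pytest.approx(0.50)
        assert conditional_psi(pool, "I2", "E7a", EXCLUDED).psi == pytest.approx(0.0625)

    def test_marginal_count_decomposition(self):
        pool = self._pool()
        marg = marginal_psi(pool, "I2")
        inc = conditional_psi(pool, "I2", "E7a", INCLUDED)
        exc = conditional_psi(pool, "I2", "E7a", EXCLUDED)
        assert marg.n_inclusion == inc.n_inclusion + exc.n_inclusion

    def test_never_included_event_zero(self):
        pool = self._pool()
        assert marginal_psi(pool, "E8a").psi == 0.0

    def test_self_conditioning_is_one(self):
        pool = self._pool()
        assert conditional_psi(pool, "E7a", "E7a", INCLUDED).psi == 1.0

    def test_empty_stratum_raises(self):
        pool = self._pool()
        with pytest.raises(UndefinedPsiError):
            conditional_psi(pool, "I2", "E8a", INCLUDED)


class TestDifferentialUsage:
    def _table(self, counts_a, counts_b):
        cls = {}
        for sample, counts in (("a", counts_a), ("b", counts_b)):
            pool = []
            off = 0
            for iso, n in counts.items():
                pool += mk_classifications(iso, n, off)
                off += n
            cls[sample] = pool
        return build_isoform_table(cls, min_support=0)

    def test_identical_proportions_give_p_one(self):
        t = self._table({(): 50, ("E7a",): 50}, {(): 100, ("E7a",): 100})
        res = differential_isoform_usage(t, ["a"], ["b"])
        assert np.allclose(res["p_value"], 1.0)

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summing hypergeometric pmfs <= observed."""
        t = self._table({(): 50, ("E7a",): 50}, {(): 90, ("E7a",): 10})
        res = differential_isoform_usage(t, ["a"], ["b"])
        ka, na, kb, nb = 50, 100, 10, 100
        k_total = ka + kb
        dist = hypergeom(na + nb, k_total, na)
        p_obs = dist.pmf(ka)
        oracle = sum(dist.pmf(k) for k in range(max(0, k_total - nb), min(k_total, na) + 1)
                     if dist.pmf(k) <= p_obs * (1 + 1e-9))
        assert res.loc["E7a", "p_value"] == pytest.approx(oracle, rel=1e-6)

    def test_planted_enrichment_detected(self, gene):
        ko = preset_model("Mbnl1KO")
        wt = preset_model("WT")
        cls = {}
        for name, model, seed in (("ko", ko, 21), ("wt", wt, 22)):
            reads, _ = simulate_long_reads(model, gene, 5000, seed=seed)
            cls[name] = classify_reads(reads, gene)
        table = build_isoform_table(cls, min_support=50)
        res = differential_isoform_usage(table, ["ko"], ["wt"])
        assert res.loc["E7a", "q_value"] < 0.05
        assert res.loc["E7a", "log2_proportion_ratio"] > 1.0

    def test_empty_group_rejected(self):
        t = self._table({(): 10}, {(): 10})
        with pytest.raises(ValueError):
            differential_isoform_usage(t, [], ["b"])
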