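"""Fold-enrichment formulas, TSS assignment and cell-type sharing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from relascape.enrichment import (
    assign_to_tss,
    classify_cell_sharing,
    fe_conserved_within_type,
    fe_tss_bias_corrected,
    fe_tss_general,
    fe_variant_overlap,
    fe_within_se,
    fe_within_shared_class,
    fe_mode_harboring_se,
    fold_enrichment,
    peaks_with_variants,
    sharing_class,
)
from relascape.intervals import GenomicInterval, Peak, PeakSet
from relascape.simulate import promoter_bias_fixture
from relascape.stats import fisher_two_sided


def spaced_peaks(n, width=500, spacing=25_000, prefix="p", species="human"):
    peaks = [
        Peak(
            GenomicInterval("chr1", (i + 1) * spacing, (i + 1) * spacing + width),
            f"{prefix}{i:05d}", 1.0, (i + 1) * spacing + width // 2,
        )
        for i in range(n)
    ]
    return PeakSet(species, "RELA", "stimulated", peaks)


class TestFoldEnrichment:
    def test_formula_arithmetic(self):
        fold, undefined = fold_enrichment(8, 10, 20, 100)
        assert fold == pytest.approx(4.0) and not undefined

    def test_null_value(self):
        fold, _ = fold_enrichment(5, 10, 50, 100)
        assert fold == pytest.approx(1.0)

    def test_zero_baseline_flagged(self):
        fold, undefined = fold_enrichment(3, 10, 0, 100)
        assert fold == float("inf") and undefined

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fold_enrichment(11, 10, 5, 100)
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 5, 100)


class TestSetBasedFE:
    def test_all_conserved_gives_one(self):
        all_ids = {f"p{i}" for i in range(100)}
        type_ids = {f"p{i}" for i in range(30)}
        res = fe_conserved_within_type(all_ids, type_ids, all_ids)
        assert res.fold == pytest.approx(1.0)

    def test_type_equals_special_gives_d_over_c(self):
        all_ids = {f"p{i}" for i in range(100)}
        conserved = {f"p{i}" for i in range(25)}
        res = fe_conserved_within_type(conserved, conserved, all_ids)
        assert res.fold == pytest.approx(100 / 25)

    def test_planted_two_fold(self, rng):
        # conservation planted at 60% inside the type, 30% overall
        all_ids = {f"p{i}" for i in range(10_000)}
        type_ids = {f"p{i}" for i in range(500)}
        conserved = {f"p{i}" for i in range(300)}  # 300/500 = 0.6 in type
        conserved |= {f"p{i}" for i in range(500, 3200)}  # total 3000
        res = fe_conserved_within_type(conserved, type_ids, all_ids)
        assert res.fold == pytest.approx(2.0)
        assert res.p_adj < 1e-10

    def test_within_se_identities(self):
        all_ids = {f"p{i}" for i in range(200)}
        se = {f"p{i}" for i in range(40)}
        res = fe_within_se(se, se, all_ids)
        assert res.fold == pytest.approx(200 / 40)
        balanced = {f"p{i}" for i in range(0, 200, 5)}  # 20% everywhere
        res2 = fe_within_se(se, balanced, all_ids)
        assert res2.fold == pytest.approx(1.0)

    def test_shared_class_structure(self):
        all_ids = {f"p{i}" for i in range(100)}
        cls = {f"p{i}" for i in range(20)}
        typ = {f"p{i}" for i in range(10, 30)}
        res = fe_within_shared_class(cls, typ, all_ids)
        assert res.fold == pytest.approx((10 / 20) / (20 / 100))

    def test_mode_harboring_se(self):
        all_se = {f"se{i}" for i in range(50)}
        shared = {f"se{i}" for i in range(10)}
        harboring = {f"se{i}" for i in range(5)} | {f"se{i}" for i in range(20, 35)}
        res = fe_mode_harboring_se(shared, harboring, all_se)
        assert res.fold == pytest.approx((5 / 10) / (20 / 50))
        res_all = fe_mode_harboring_se(shared, all_se, all_se)
        assert res_all.fold == pytest.approx(1.0)


class TestVariantOverlap:
    def test_half_open_boundaries(self):
        peaks = PeakSet("human", "RELA", "stimulated", [
            Peak(GenomicInterval("chr1", 100, 200), "a", 1.0, 150),
            Peak(GenomicInterval("chr1", 300, 400), "b", 1.0, 350),
        ])
        variants = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 400], "id": ["v1", "v2"]}
        )
        assert peaks_with_variants(peaks, variants) == {"a"}  # start in, end out

    def test_planted_fold_recovered(self):
        peaks = spaced_peaks(2_000)
        ids = peaks.ids()
        conserved = set(ids[:160])  # 8%
        # 50 variant peaks, 16 conserved => FE = (16/50)/(160/2000) = 4
        chosen = ids[:16] + ids[1000:1034]
        variants = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [peaks.by_id()[pid].summit for pid in chosen],
                "id": [f"v{i}" for i in range(len(chosen))],
            }
        )
        res = fe_variant_overlap(peaks, variants, conserved)
        assert res.fold == pytest.approx(4.0, rel=1e-9)
        assert res.p_raw < 1e-6


def brute_force_tss(peaks, genes, w):
    rows = []
    for p in peaks:
        for g in genes.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            if g.tss - w < p.end and p.start < g.tss + w:
                rows.append((p.id, g.gene_id, g.expr_class))
    return sorted(rows)


class TestAssignToTss:
    def test_window_boundaries(self):
        peaks = PeakSet("human", "RELA", "stimulated", [
            Peak(GenomicInterval("chr1", 0, 1_000), "a", 1.0, 500),
        ])
        w = 10_000
        genes = pd.DataFrame({
            "gene_id": ["g_edge", "g_in"],
            "chrom": ["chr1", "chr1"],
            "tss": [1_000 + w, 1_000 + w - 1],  # peak end == tss - w excluded
            "strand": ["+", "+"],
            "expr_class": ["up", "up"],
        })
        out = assign_to_tss(peaks, genes, w)
        assert sorted(out["gene_id"]) == ["g_in"]

    def test_peak_spanning_two_windows(self):
        peaks = PeakSet("human", "RELA", "stimulated", [
            Peak(GenomicInterval("chr1", 9_000, 12_000), "a", 1.0, 10_000),
        ])
        genes = pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "tss": [1_000, 20_000],
            "strand": ["+", "+"],
            "expr_class": ["up", "down"],
        })
        out = assign_to_tss(peaks, genes, 10_000)
        assert sorted(out["gene_id"]) == ["g1", "g2"]

    def test_matches_brute_force(self, rng):
        peaks = []
        pos = 0
        for i in range(1_000):
            pos += int(rng.integers(100, 30_000))
            width = int(rng.integers(100, 2_000))
            peaks.append(
                Peak(GenomicInterval("chr1", pos, pos + width), f"p{i}", 1.0,
                     pos + width // 2)
            )
            pos += width
        pset = PeakSet("human", "RELA", "stimulated", peaks)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(1_000)],
            "chrom": "chr1",
            "tss": rng.integers(0, pos, size=1_000),
            "strand": "+",
            "expr_class": rng.choice(["up", "down", "constitutive"], size=1_000),
        })
        out = assign_to_tss(pset, genes, 10_000)
        got = sorted(map(tuple, out.to_numpy()))
        assert got == brute_force_tss(pset, genes, 10_000)


class TestTssEnrichment:
    def test_null_gives_one(self):
        peaks = spaced_peaks(1_000)
        ids = peaks.ids()
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(100)],
            "chrom": "chr1",
            # one gene inside each of the first 100 peaks
            "tss": [peaks.by_id()[ids[i]].summit for i in range(100)],
            "strand": "+",
            "expr_class": "up",
        })
        assignments = assign_to_tss(peaks, genes)
        type_ids = set(ids[::2])  # alternating halves: balanced w.r.t. genes
        res = fe_tss_general(assignments, type_ids, set(ids), "up")
        assert res.fold == pytest.approx(1.0)

    def test_promoter_bias_construction(self):
        # conserved peaks cluster near TSSs of ALL classes: the general
        # formula inflates, the corrected formula returns ~1
        peaks, genes, conserved = promoter_bias_fixture(seed=5)
        assignments = assign_to_tss(peaks, genes)
        all_ids = set(peaks.ids())
        general = fe_tss_general(assignments, conserved, all_ids, "up")
        corrected = fe_tss_bias_corrected(assignments, conserved, "up")
        assert general.fold > 1.5
        assert abs(corrected.fold - 1.0) <= 0.1

    def test_corrected_requires_type_near_genes(self):
        peaks, genes, conserved = promoter_bias_fixture(seed=5)
        assignments = assign_to_tss(peaks, genes)
        with pytest.raises(ValueError):
            fe_tss_bias_corrected(assignments, {"absent_peak"}, "up")


class TestCellSharing:
    def _celltype_sets(self):
        base = [(1_000, 1_500), (10_000, 10_500), (20_000, 20_500)]
        ref = PeakSet("HAEC", "RELA", "stimulated", [
            Peak(GenomicInterval("chr1", s, e), f"h{i}", 1.0, (s + e) // 2)
            for i, (s, e) in enumerate(base)
        ])
        def other(name, which):
            return PeakSet(name, "RELA", "stimulated", [
                Peak(GenomicInterval("chr1", base[i][0] + 100, base[i][1] + 100),
                     f"{name}{i}", 1.0, base[i][0] + 300)
                for i in which
            ])
        others = {
            "HUVEC": other("HUVEC", [0, 1]),
            "LCL": other("LCL", [0]),
            "Adipocyte": other("Adipocyte", [0]),
        }
        return ref, others

    def test_classes(self):
        ref, others = self._celltype_sets()
        out = classify_cell_sharing(ref, others).set_index("peak_id")
        assert out.loc["h0", "class"] == "pan-cell"
        assert out.loc["h1", "class"] == "2-EC-specific"
        assert out.loc["h2", "class"] == "reference-specific"

    def test_sharing_class_vocabulary(self):
        assert sharing_class({"HAEC", "LCL"}, "HAEC", ("HAEC", "HUVEC")) == "2-other"
        assert sharing_class({"HAEC", "HUVEC", "LCL"}, "HAEC", ("HAEC", "HUVEC")) == "3-shared"


class TestNullCalibration:
    def test_fisher_pvalues_super_uniform_under_permutation(self, rng):
        # permute a fixed special-label vector against a fixed type vector;
        # exact-test p-values must be (super-)uniform: the one-sided KS
        # statistic against Uniform(0,1) must not reject
        n, n_special, n_type = 400, 120, 90
        ps = []
        for _ in range(500):
            a = rng.hypergeometric(n_special, n - n_special, n_type)
            table = [[a, n_special - a], [n_type - a, n - n_special - n_type + a]]
            ps.append(fisher_two_sided(table))
        stat = kstest(ps, "uniform", alternative="greater")
        assert stat.pvalue > 0.01
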