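"""Binding-mode classification and the cross-species preservation model."""

import numpy as np
import pandas as pd
import pytest

from relascape.intervals import GenomicInterval, Peak, PeakSet
from relascape.modes import (
    MODE_LABELS,
    MODES,
    PreservationModel,
    classify_modes,
    fit_preservation_model,
    preservation_expected,
    preservation_expected_bruteforce,
    preservation_observed,
    preservation_test,
)
from relascape.orthology import ConservationLabels, OrthologyMap, classify_conservation
from relascape.simulate import build_landscape

from .conftest import small_config


def _set(species, assay, cond, intervals, prefix):
    peaks = [
        Peak(GenomicInterval("chr1", s, e), f"{prefix}{i}", 1.0, (s + e) // 2)
        for i, (s, e) in enumerate(intervals)
    ]
    return PeakSet(species, assay, cond, peaks)


class TestClassifyModes:
    def test_truth_table(self):
        # four RELA peaks, one per mode; accessibility placed accordingly
        rela = _set("human", "RELA", "stimulated",
                    [(0, 400), (1000, 1400), (2000, 2400), (3000, 3400)], "r")
        atac_basal = _set("human", "ATAC", "basal", [(100, 300), (2100, 2300)], "ab")
        atac_stim = _set("human", "ATAC", "stimulated", [(100, 300), (1100, 1300)], "as")
        rela_basal = _set("human", "RELA", "basal", [(0, 400)], "b")
        out = classify_modes(rela, atac_basal, atac_stim, rela_basal)
        got = out.set_index("peak_id")
        assert got.loc["r0", "mode"] == "O"       # open before and after
        assert got.loc["r1", "mode"] == "OA"      # opens after stimulation
        assert got.loc["r2", "mode"] == "CA"      # closes after stimulation
        assert got.loc["r3", "mode"] == "C"       # never accessible
        assert bool(got.loc["r0", "prebound"]) and not got.loc["r1", "prebound"]

    def test_species_mismatch_rejected(self):
        rela = _set("human", "RELA", "stimulated", [(0, 400)], "r")
        wrong = _set("mouse", "ATAC", "basal", [(0, 400)], "a")
        ok = _set("human", "ATAC", "stimulated", [(0, 400)], "s")
        basal = _set("human", "RELA", "basal", [], "b")
        with pytest.raises(ValueError, match="species"):
            classify_modes(rela, wrong, ok, basal)

    def test_partition_property(self, small_landscape):
        land = small_landscape
        out = classify_modes(
            land.peaksets[("human", "RELA", "stimulated")],
            land.peaksets[("human", "ATAC", "basal")],
            land.peaksets[("human", "ATAC", "stimulated")],
            land.peaksets[("human", "RELA", "basal")],
        )
        assert set(out["mode"]) <= set(MODES)
        assert len(out) == len(land.peaksets[("human", "RELA", "stimulated")])
        assert not out["peak_id"].duplicated().any()

    def test_prebound_subset_of_open(self, small_landscape):
        # the generator plants prebound regions in constitutively open
        # chromatin, so recovery must put every prebound peak in Mode O
        land = small_landscape
        out = classify_modes(
            land.peaksets[("human", "RELA", "stimulated")],
            land.peaksets[("human", "ATAC", "basal")],
            land.peaksets[("human", "ATAC", "stimulated")],
            land.peaksets[("human", "RELA", "basal")],
        )
        assert (out.loc[out["prebound"], "mode"] == "O").all()

    def test_exact_recovery_of_planted_modes(self, small_landscape):
        land = small_landscape
        out = classify_modes(
            land.peaksets[("human", "RELA", "stimulated")],
            land.peaksets[("human", "ATAC", "basal")],
            land.peaksets[("human", "ATAC", "stimulated")],
            land.peaksets[("human", "RELA", "basal")],
        )
        merged = out.merge(land.truth, on="peak_id", suffixes=("_got", "_true"))
        assert (merged["mode_got"] == merged["mode_true"]).all()
        assert (merged["prebound_got"] == merged["prebound_true"]).all()


def random_model(rng) -> PreservationModel:
    cats = rng.dirichlet([1, 1, 1])
    p_mode = {}
    for label in MODE_LABELS:
        for g, species in (("B", ("human", "mouse", "cow")),
                           ("C", ("human", "mouse")),
                           ("D", ("human", "cow"))):
            for sp in species:
                p_mode[(label, sp, g)] = float(rng.uniform(0, 1))
    return PreservationModel(
        reference="human",
        partner_order=("mouse", "cow"),
        p_category={"B": cats[0], "C": cats[1], "D": cats[2]},
        p_mode=p_mode,
    )


def monte_carlo_pa(model, label, n_draws, rng):
    cats = np.array([model.p_category[g] for g in ("B", "C", "D")])
    draws = rng.choice(3, size=n_draws, p=cats)
    partner_sets = {0: ("mouse", "cow"), 1: ("mouse",), 2: ("cow",)}
    g_names = {0: "B", 1: "C", 2: "D"}
    hits = 0
    for gi in (0, 1, 2):
        mask = draws == gi
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        g = g_names[gi]
        ref_ok = rng.random(n_g) < model.p_mode[(label, "human", g)]
        partner_ok = np.zeros(n_g, dtype=bool)
        for sp in partner_sets[gi]:
            partner_ok |= rng.random(n_g) < model.p_mode[(label, sp, g)]
        hits += int((ref_ok & partner_ok).sum())
    return hits / n_draws


class TestPreservationExpected:
    def test_certainty_gives_one(self):
        model = random_model(np.random.default_rng(0))
        for key in list(model.p_mode):
            model.p_mode[key] = 1.0
        out = preservation_expected(model, "O")
        assert out["p_a"] == pytest.approx(1.0)
        assert out["conditional"] == pytest.approx(1.0)

    def test_single_term_product(self):
        # everything conserved human-mouse only: P(A) = p(H,C) * p(M,C)
        model = PreservationModel(
            reference="human",
            partner_order=("mouse", "cow"),
            p_category={"B": 0.0, "C": 1.0, "D": 0.0},
            p_mode={("O", "human", "C"): 0.5, ("O", "mouse", "C"): 0.4},
        )
        out = preservation_expected(model, "O")
        assert out["p_a"] == pytest.approx(0.20)
        assert out["conditional"] == pytest.approx(0.4)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(50):
            model = random_model(rng)
            for label in MODE_LABELS:
                closed = preservation_expected(model, label)["p_a"]
                assert closed == pytest.approx(
                    preservation_expected_bruteforce(model, label), abs=1e-12
                )

    def test_matches_monte_carlo(self, rng):
        n_draws = 100_000
        for _ in range(5):
            model = random_model(rng)
            pa = preservation_expected(model, "O")["p_a"]
            mc = monte_carlo_pa(model, "O", n_draws, rng)
            se = np.sqrt(max(pa * (1 - pa), 1e-12) / n_draws)
            assert abs(mc - pa) <= 3 * se + 1e-9

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            PreservationModel(
                "human", ("mouse", "cow"),
                p_category={"B": 1.0, "C": 0.0, "D": 0.0},
                p_mode={("O", "human", "B"): 1.5},
            )


class TestPreservationTest:
    def test_central_p_one(self):
        res = preservation_test("O", 5, 10, 0.5)
        assert res.p_raw == pytest.approx(1.0)
        assert res.fold == pytest.approx(1.0)

    def test_extreme_exact_value(self):
        res = preservation_test("O", 10, 10, 0.5)
        assert res.p_raw == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_bonferroni_capped(self):
        res = preservation_test("O", 6, 10, 0.55, n_tests=5)
        assert res.p_adj == min(1.0, res.p_raw * 5)
        assert preservation_test("O", 5, 10, 0.5, n_tests=5).p_adj == 1.0

    def test_degenerate_expected_flagged(self):
        res = preservation_test("O", 3, 10, 0.0)
        assert res.degenerate and res.p_raw == 0.0


def _single_peak_case(preserved: bool):
    """One three-species-conserved peak, Mode O everywhere or not."""
    ref = pd.DataFrame({"peak_id": ["h0"], "mode": ["O"], "prebound": [True]})
    partner_mode = "O" if preserved else "C"
    partner = {
        "mouse": pd.DataFrame({"peak_id": ["m0"], "mode": [partner_mode],
                               "prebound": [preserved]}),
        "cow": pd.DataFrame({"peak_id": ["c0"], "mode": [partner_mode],
                             "prebound": [preserved]}),
    }
    labels = ConservationLabels(
        "human",
        pd.DataFrame({"peak_id": ["h0"], "n_species": [3],
                      "present_in": ["cow,mouse"]}),
        {"h0": {"mouse": ["m0"], "cow": ["c0"]}},
    )
    return ref, partner, labels


class TestPreservationObserved:
    def test_preserved_in_both_counts_once(self):
        ref, partner, labels = _single_peak_case(True)
        obs = preservation_observed(ref, partner, labels, ("mouse", "cow"))
        row = obs.set_index("label").loc["O"]
        assert (row["k"], row["n"], row["k_both"]) == (1, 1, 1)
        p_row = obs.set_index("label").loc["P"]
        assert (p_row["k"], p_row["n"]) == (1, 1)

    def test_not_preserved(self):
        ref, partner, labels = _single_peak_case(False)
        obs = preservation_observed(ref, partner, labels, ("mouse", "cow"))
        row = obs.set_index("label").loc["O"]
        assert (row["k"], row["n"]) == (0, 1)

    def test_planted_rate_recovered(self):
        # two-species landscape (no three-way conservation), flat planted
        # per-partner preservation probability 0.6 for every label
        cfg = small_config(
            n_ref_peaks=5_000,
            three_species_fraction=0.0,
            mode_preservation_rate=0.6,
            n_up_genes=200, n_down_genes=80, n_constitutive_genes=400,
            n_variant_peaks=100, sharing_counts=(250, 500, 750, 250),
        )
        land = build_landscape(cfg, 99)
        ref_modes = classify_modes(
            land.peaksets[("human", "RELA", "stimulated")],
            land.peaksets[("human", "ATAC", "basal")],
            land.peaksets[("human", "ATAC", "stimulated")],
            land.peaksets[("human", "RELA", "basal")],
        )
        partner_modes = {
            sp: classify_modes(
                land.peaksets[(sp, "RELA", "stimulated")],
                land.peaksets[(sp, "ATAC", "basal")],
                land.peaksets[(sp, "ATAC", "stimulated")],
                land.peaksets[(sp, "RELA", "basal")],
            )
            for sp in ("mouse", "cow")
        }
        labels = classify_conservation(
            land.peaksets[("human", "RELA", "stimulated")],
            {sp: land.peaksets[(sp, "RELA", "stimulated")] for sp in ("mouse", "cow")},
            land.omap,
        )
        obs = preservation_observed(ref_modes, partner_modes, labels, ("mouse", "cow"))
        row = obs.set_index("label").loc["O"]
        assert row["n"] > 500
        assert abs(row["k"] / row["n"] - 0.6) <= 0.03

    def test_model_fit_consistency(self, small_landscape):
        land = small_landscape
        ref_modes = classify_modes(
            land.peaksets[("human", "RELA", "stimulated")],
            land.peaksets[("human", "ATAC", "basal")],
            land.peaksets[("human", "ATAC", "stimulated")],
            land.peaksets[("human", "RELA", "basal")],
        )
        partner_modes = {
            sp: classify_modes(
                land.peaksets[(sp, "RELA", "stimulated")],
                land.peaksets[(sp, "ATAC", "basal")],
                land.peaksets[(sp, "ATAC", "stimulated")],
                land.peaksets[(sp, "RELA", "basal")],
            )
            for sp in ("mouse", "cow")
        }
        labels = classify_conservation(
            land.peaksets[("human", "RELA", "stimulated")],
            {sp: land.peaksets[(sp, "RELA", "stimulated")] for sp in ("mouse", "cow")},
            land.omap,
        )
        model = fit_preservation_model(ref_modes, partner_modes, labels, ("mouse", "cow"))
        assert sum(model.p_category.values()) == pytest.approx(1.0)
        for label in MODE_LABELS:
            out = preservation_expected(model, label)
            assert 0.0 <= out["p_a"] <= 1.0
            for t in out["terms"]:
                assert 0.0 <= t <= 1.0
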