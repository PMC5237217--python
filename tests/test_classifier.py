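"""Binomial generation classifier: probabilities, intervals, oracle
agreement, and dual-ancestry detection."""
import math

import numpy as np
import pytest
from scipy.stats import multinomial

from hybridpanel.classifier import (HetModel, classification_table, classify,
                                    dual_ancestry_expected_fractions,
                                    dual_ancestry_test,
                                    dual_detection_probability,
                                    f1_lower_bound, het_probability,
                                    log_likelihoods)
from hybridpanel.panel import HetCounts


class TestHetProbability:
    def test_f1_diagnostic(self):
        assert het_probability(1, HetModel(n=50)) == 1.0

    def test_introgressing_formula(self):
        m = HetModel(n=50, scenario="introgressing_maf", m=0.05)
        assert abs(het_probability(3, m) - 0.2375) < 1e-12

    def test_symmetric_g2_exactly_half(self):
        m = HetModel(n=50, scenario="symmetric_maf", m=0.05)
        assert abs(het_probability(2, m) - 0.5) < 1e-12

    def test_native_probability(self):
        assert HetModel(n=50).p_native == 0.0
        sym = HetModel(n=50, scenario="symmetric_maf", m=0.05)
        assert abs(sym.p_native - 2 * 0.05 * 0.95) < 1e-12


class TestClassificationTable:
    def test_single_marker_partition(self):
        t = classification_table(HetModel(n=1))
        assert (t.interval("F1").k_lo, t.interval("F1").k_hi) == (1, 1)
        assert (t.interval("Native").k_lo, t.interval("Native").k_hi) == (0, 0)
        for g in range(2, 9):
            assert t.interval(f"F{g}").empty

    @pytest.mark.parametrize("n", [1, 5, 12, 50])
    @pytest.mark.parametrize("scenario,m", [
        ("diagnostic", 0.0), ("introgressing_maf", 0.02),
        ("introgressing_maf", 0.05), ("symmetric_maf", 0.05),
    ])
    def test_interval_partition(self, n, scenario, m):
        # non-empty intervals are disjoint and cover 0..n exactly once
        t = classification_table(HetModel(n=n, scenario=scenario, m=m))
        claimed = np.zeros(n + 1, dtype=int)
        for iv in t.intervals:
            if iv.empty:
                continue
            assert 0 <= iv.k_lo <= iv.k_hi <= n
            claimed[iv.k_lo:iv.k_hi + 1] += 1
        assert (claimed == 1).all()

    def test_lower_bounds_decrease_with_generation(self):
        t = classification_table(HetModel(n=50))
        los = [t.interval(f"F{g}").k_lo for g in range(1, 8)]
        assert los == sorted(los, reverse=True)

    def test_brute_force_oracle_agreement(self):
        # independent oracle: per-k argmax of comb-based binomial pmfs,
        # F1 boundary convention applied; no interval construction involved
        def oracle(k, n, model):
            if k >= f1_lower_bound(n):
                return "F1"
            best, best_l = None, -1.0
            for c in [f"F{g}" for g in range(2, model.max_generation + 1)] + ["Native"]:
                p = (model.p_native if c == "Native"
                     else het_probability(int(c[1:]), model))
                if p == 0.0:
                    like = 1.0 if k == 0 else 0.0
                else:
                    like = math.comb(n, k) * p ** k * (1 - p) ** (n - k)
                if like > best_l + 1e-15:
                    best, best_l = c, like
            return best

        for n in range(1, 13):
            for scenario, m in [("diagnostic", 0.0),
                                ("introgressing_maf", 0.05),
                                ("symmetric_maf", 0.05)]:
                model = HetModel(n=n, scenario=scenario, m=m)
                for k in range(n + 1):
                    counts = HetCounts("x", n_obs=n, k_het=k,
                                       k_hom_local=n - k, k_hom_foreign=0)
                    got, _ = classify(counts, model)
                    assert got == oracle(k, n, model), (n, k, scenario)

    def test_monte_carlo_consistency_with_crossing(self):
        # classifying simulated Fg backcrosses reproduces prob_correct
        from hybridpanel.crossing import simulate_category
        from hybridpanel.genotypes import GenotypeMatrix
        from hybridpanel.synthetic import default_loci
        n_sim = 10_000
        loci = default_loci(50)
        a = GenotypeMatrix(loci, [f"a{i}" for i in range(30)], ["A"] * 30,
                           np.zeros((30, 50), dtype=np.int8))
        b = GenotypeMatrix(loci, [f"b{i}" for i in range(30)], ["B"] * 30,
                           np.full((30, 50), 2, dtype=np.int8))
        table = classification_table(HetModel(n=50))
        for g in range(2, 6):
            sim = simulate_category(a, b, f"F{g}A", n_sim, seed=500 + g)
            ks = (sim.calls == 1).sum(axis=1)
            iv = table.interval(f"F{g}")
            hit = float(((ks >= iv.k_lo) & (ks <= iv.k_hi)).mean())
            se = math.sqrt(iv.prob_correct * (1 - iv.prob_correct) / n_sim)
            assert abs(hit - iv.prob_correct) < 3 * se

    def test_to_frame_marks_never_most_likely(self):
        frame = classification_table(HetModel(n=50)).to_frame()
        f8 = frame[frame.category == "F8"].iloc[0]
        assert f8.note == "never most likely"


class TestClassify:
    @pytest.mark.parametrize("k,expected", [(50, "F1"), (0, "Native"),
                                            (12, "F3"), (19, "F2")])
    def test_diagnostic_examples(self, k, expected):
        counts = HetCounts("x", n_obs=50, k_het=k, k_hom_local=50 - k,
                           k_hom_foreign=0)
        cat, lls = classify(counts, HetModel(n=50))
        assert cat == expected
        assert set(lls) == {"Native"} | {f"F{g}" for g in range(1, 9)}

    def test_model_rescaled_to_observed_markers(self):
        # 40 called markers: the table is rebuilt at n=40
        counts = HetCounts("x", n_obs=40, k_het=40, k_hom_local=0,
                           k_hom_foreign=0)
        cat, _ = classify(counts, HetModel(n=50))
        assert cat == "F1"

    def test_loglik_finiteness(self):
        lls = log_likelihoods(10, HetModel(n=50))
        assert lls["Native"] == -math.inf  # p=0 cannot produce k>0
        assert math.isfinite(lls["F3"])

    def test_no_markers_error(self):
        counts = HetCounts("x", n_obs=0, k_het=0, k_hom_local=0,
                           k_hom_foreign=0)
        with pytest.raises(ValueError):
            classify(counts, HetModel(n=50))


class TestDualAncestry:
    def test_expected_fractions(self):
        assert dual_ancestry_expected_fractions(1) == (0.25, 0.5, 0.25)
        assert dual_ancestry_expected_fractions(2) == (0.5625, 0.375, 0.0625)

    def test_flagging_logic(self):
        model = HetModel(n=50)
        mixed = HetCounts("x", 50, k_het=20, k_hom_local=25, k_hom_foreign=5)
        res = dual_ancestry_test(mixed, model)
        assert res.flagged and res.tail_probability == 0.0
        backcross = HetCounts("y", 50, k_het=25, k_hom_local=25, k_hom_foreign=0)
        res = dual_ancestry_test(backcross, model)
        assert not res.flagged and res.tail_probability == 1.0

    def test_requires_diagnostic_panel(self):
        model = HetModel(n=50, scenario="symmetric_maf", m=0.05)
        c = HetCounts("x", 50, 20, 25, 5)
        with pytest.raises(ValueError):
            dual_ancestry_test(c, model)

    def test_detection_probability_bounds(self):
        assert dual_detection_probability(50, 51) == 0.0
        assert dual_detection_probability(50, 0) == 1.0

    @pytest.mark.parametrize("cross,t", [("F1xF1", 3), ("F2xF2", 1),
                                         ("F1xF1", 1), ("F2xF2", 3)])
    def test_detection_probability_against_multinomial_oracle(self, cross, t):
        # independent oracle: scipy multinomial pmf summed over the grid
        n = 50
        g = int(cross[1])
        p_local, p_het, p_foreign = dual_ancestry_expected_fractions(g)
        rv = multinomial(n, [p_local, p_foreign, p_het])
        total = sum(rv.pmf([kl, kf, n - kl - kf])
                    for kl in range(t, n + 1)
                    for kf in range(t, n - kl + 1))
        assert abs(dual_detection_probability(n, t, cross) - total) < 1e-10

    def test_f1xf1_three_marker_detection_value(self):
        # exact trinomial value; the rounded folklore figure is 99.8%
        v = dual_detection_probability(50, 3, "F1xF1")
        assert 0.9997 < v < 0.9999
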