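"""Diagnosticity statistics: Agresti-Coull intervals, panel diagnosis,
individual marker scoring."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridpanel.genotypes import MISSING, GenotypeMatrix
from hybridpanel.panel import (HetCounts, agresti_coull_ci, diagnose_panel,
                               score_individual, score_matrix)
from hybridpanel.synthetic import (FrequencyScenario, PopulationFrequencies,
                                   default_loci, make_frequency_profile,
                                   sample_population)


class TestAgrestiCoull:
    def test_zero_count_upper_bound(self):
        point, lower, upper = agresti_coull_ci(0, 100, 0.95)
        assert lower == 0.0
        assert abs(upper - 0.0444) < 5e-4

    def test_full_count_clamps_to_one(self):
        _, _, upper = agresti_coull_ci(100, 100, 0.95)
        assert upper == 1.0

    def test_midpoint_symmetry(self):
        point, lower, upper = agresti_coull_ci(50, 100, 0.95)
        assert abs(point - 0.5) < 1e-12
        assert abs((upper - point) - (point - lower)) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            agresti_coull_ci(0, 100, 1.0)
        with pytest.raises(ValueError):
            agresti_coull_ci(5, 4)
        with pytest.raises(ValueError):
            agresti_coull_ci(0, 0)

    @pytest.mark.parametrize("x,n", [(0, 50), (2, 188), (10, 100), (76, 234)])
    def test_against_statsmodels(self, x, n):
        # independent implementation of the same adjusted-Wald formula
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(x, n, alpha=0.05, method="agresti_coull")
        _, lower, upper = agresti_coull_ci(x, n, 0.95)
        assert abs(lower - max(lo, 0.0)) < 1e-9
        assert abs(upper - min(hi, 1.0)) < 1e-9

    def test_upper_bound_decreases_with_n_at_zero_count(self):
        uppers = [agresti_coull_ci(0, n, 0.95)[2] for n in (10, 50, 100, 500)]
        assert uppers == sorted(uppers, reverse=True)


def _two_pop_matrix(freqs, n=95, seed=0, missing_rate=0.0):
    a = sample_population(freqs, "A", n, missing_rate, seed=seed)
    b = sample_population(freqs, "B", n, missing_rate, seed=seed + 1)
    return GenotypeMatrix.concat([a, b])


class TestDiagnosePanel:
    def test_strictly_fixed_panel(self):
        freqs = make_frequency_profile(
            FrequencyScenario(n_loci=50, scenario="diagnostic"), seed=1)
        m = _two_pop_matrix(freqs)
        diag = diagnose_panel(m, "A", "B")
        assert all(d.fully_diagnostic for d in diag)
        assert all(d.observed_maf_per_pop["A"] == 0.0 for d in diag)
        assert all(d.observed_maf_per_pop["B"] == 0.0 for d in diag)

    def test_two_minor_copies_in_188(self):
        # one B individual heterozygous for the A-type allele, 94 called:
        # MAF = 2/188? here: 2 copies among 2*94 -> construct directly
        loci = default_loci(1)
        calls = np.vstack([np.zeros((94, 1)), np.full((94, 1), 2)]).astype(np.int8)
        calls[94, 0] = 1
        calls[95, 0] = 1
        m = GenotypeMatrix(loci, [f"i{k}" for k in range(188)],
                           ["A"] * 94 + ["B"] * 94, calls)
        d = diagnose_panel(m, "A", "B")[0]
        assert not d.fully_diagnostic
        assert abs(d.observed_maf_per_pop["B"] - 2 / 188) < 1e-12
        assert d.observed_maf_per_pop["A"] == 0.0

    def test_minor_allele_detection_probability(self):
        # inject MAF 0.03 into 20 of 50 loci; with 95 B individuals the
        # chance of observing >=1 minor copy is 1-(1-0.03)**190 per locus
        fa = np.zeros(50)
        fb = np.ones(50)
        fb[:20] = 0.97
        freqs = PopulationFrequencies(default_loci(50), ("A", "B"),
                                      np.vstack([fa, fb]))
        m = _two_pop_matrix(freqs, n=95, seed=42)
        diag = diagnose_panel(m, "A", "B")
        lost = sum(not d.fully_diagnostic for d in diag[:20])
        expect = 20 * (1 - 0.97 ** 190)
        sd = np.sqrt(20 * (1 - 0.97 ** 190) * 0.97 ** 190)
        assert abs(lost - expect) <= max(3 * sd, 1)
        assert all(d.fully_diagnostic for d in diag[20:])

    def test_all_missing_population_flagged(self):
        loci = default_loci(1)
        calls = np.array([[MISSING], [2]], dtype=np.int8)
        m = GenotypeMatrix(loci, ["a1", "b1"], ["A", "B"], calls)
        diag = diagnose_panel(m, "A", "B")
        assert len(diag) == 1
        assert "all_missing" in diag[0].flags
        assert not diag[0].fully_diagnostic

    def test_absent_population_raises(self):
        freqs = make_frequency_profile(
            FrequencyScenario(n_loci=5, scenario="diagnostic"), seed=1)
        m = sample_population(freqs, "A", 5, seed=0)
        with pytest.raises(ValueError):
            diagnose_panel(m, "A", "B")

    def test_tie_breaks_toward_allele_a(self):
        loci = default_loci(1)
        calls = np.array([[0], [2], [0], [2]], dtype=np.int8)
        m = GenotypeMatrix(loci, list("wxyz"), ["A", "A", "B", "B"], calls)
        d = diagnose_panel(m, "A", "B")[0]
        assert d.diagnostic_allele_per_pop["A"] == loci[0].allele_a
        assert d.diagnostic_allele_per_pop["B"] == loci[0].allele_a
        assert not d.orientable


class TestScoreIndividual:
    @pytest.fixture(scope="class")
    def oriented(self):
        freqs = make_frequency_profile(
            FrequencyScenario(n_loci=50, scenario="diagnostic"), seed=1)
        m = _two_pop_matrix(freqs)
        return freqs.loci, diagnose_panel(m, "A", "B")

    def test_f1_signature(self, oriented):
        loci, diag = oriented
        row = np.ones(50, dtype=np.int8)
        c = score_individual(row, loci, diag, "A")
        assert (c.n_obs, c.k_het, c.k_hom_local, c.k_hom_foreign) == (50, 50, 0, 0)

    def test_pure_local(self, oriented):
        loci, diag = oriented
        row = np.zeros(50, dtype=np.int8)
        c = score_individual(row, loci, diag, "A")
        assert c.k_hom_local == c.n_obs == 50

    def test_missing_excluded(self, oriented):
        loci, diag = oriented
        row = np.zeros(50, dtype=np.int8)
        row[:10] = MISSING
        c = score_individual(row, loci, diag, "A")
        assert c.n_obs == 40

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=50, max_size=50))
    def test_counting_identity(self, oriented, codes):
        loci, diag = oriented
        c = score_individual(np.array(codes, dtype=np.int8), loci, diag, "B")
        assert c.k_het + c.k_hom_local + c.k_hom_foreign == c.n_obs
        assert c.n_obs == sum(1 for x in codes if x != -1)

    def test_f2a_counts_follow_binomial(self, oriented):
        from scipy.stats import binom, chisquare
        from hybridpanel.crossing import simulate_category
        loci, diag = oriented
        freqs = make_frequency_profile(
            FrequencyScenario(n_loci=50, scenario="diagnostic"), seed=1)
        a = sample_population(freqs, "A", 50, seed=2)
        b = sample_population(freqs, "B", 50, seed=3)
        sim = simulate_category(a, b, "F2A", 10_000, seed=4)
        ks = np.array([c.k_het for c in score_matrix(sim, diag, "A")])
        observed = np.bincount(ks, minlength=51).astype(float)
        expected = 10_000 * binom.pmf(np.arange(51), 50, 0.5)
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        assert chisquare(obs, exp * obs.sum() / exp.sum()).pvalue > 0.01

    def test_hetcounts_invariant_enforced(self):
        with pytest.raises(ValueError):
            HetCounts("x", n_obs=5, k_het=1, k_hom_local=1, k_hom_foreign=1)
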