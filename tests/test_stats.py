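"""Goodness of fit, exact tests, model ranking, copy number, classing."""

import itertools
import warnings
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

import gamsel as g
from _oracles import fisher_tail_oracle
from conftest import TWO_LOCUS_OBSERVED, TWO_LOCUS_RATIO, T1_FAMILIES

LABELS9 = g.state_labels(2)


class TestChisqGof:
    def test_two_locus_family_fit(self):
        """The distorted 9-class family fits its model ratio: chi2 about
        2.47 on 7 df after dropping the impossible class."""
        table = g.CountTable(LABELS9, TWO_LOCUS_OBSERVED, TWO_LOCUS_RATIO)
        res = g.chisq_gof(table)
        assert res.statistic == pytest.approx(2.4667, abs=2e-4)
        assert res.df == 7
        assert res.p == pytest.approx(0.9296, abs=2e-4)
        assert res.dropped_classes == ("BA",)
        assert res.inputs["expected"][4] == pytest.approx(22.5)

    def test_exact_proportionality_gives_zero(self):
        res = g.chisq_gof(g.CountTable("abc", (10, 20, 10), (1, 2, 1)))
        assert res.statistic == 0 and res.p == 1.0

    def test_two_class_hand_arithmetic(self):
        res = g.chisq_gof(g.CountTable("ab", (8, 2), (1, 1)))
        assert res.statistic == pytest.approx(3.6)
        assert res.df == 1

    def test_observation_in_impossible_class_raises(self):
        with pytest.raises(g.ModelViolationError) as err:
            g.chisq_gof(g.CountTable("abc", (5, 1, 5), (1, 0, 1)))
        assert "b" in err.value.classes

    def test_pvalues_uniform_under_null(self):
        """Sampling under the model ratio, p-values are uniform within a
        Kolmogorov-Smirnov test at alpha = 0.01 (n = 90 per family), and
        agree exactly with the reference chi-square implementation."""
        rng = np.random.default_rng(0)
        probs = np.array(TWO_LOCUS_RATIO, dtype=float)
        probs /= probs.sum()
        pvals = []
        for _ in range(2000):
            counts = rng.multinomial(90, probs)
            res = g.chisq_gof(g.CountTable(LABELS9, counts, TWO_LOCUS_RATIO))
            keep = probs > 0
            ref = sps.chisquare(counts[keep], 90 * probs[keep] / probs[keep].sum())
            assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
            pvals.append(res.p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestFisherExact:
    def test_rescue_lines_against_vector_control(self):
        """Each transgene line is enriched for the double-sterile
        homozygote relative to the 1/94 vector-control rate."""
        printed = {"line1": 8.0e-4, "line2": 6.7e-5,
                   "line3": 1.1e-6, "line4": 5.5e-4}
        va, vn = T1_FAMILIES["vector"][2], sum(T1_FAMILIES["vector"])
        for line, expected_p in printed.items():
            aa, ab, bb = T1_FAMILIES[line]
            table = [[bb, aa + ab], [va, vn - va]]
            res = g.fisher_exact(table, "two-sided")
            assert res.p == pytest.approx(expected_p, rel=0.05), line

    def test_small_table_enumeration(self):
        res = g.fisher_exact([[2, 0], [0, 2]], "greater")
        assert res.p == pytest.approx(1 / 6)

    def test_no_signal_gives_unit_p(self):
        res = g.fisher_exact([[0, 10], [0, 10]], "greater")
        assert res.p == pytest.approx(1.0)

    def test_all_zero_table_warns(self):
        with pytest.warns(UserWarning):
            res = g.fisher_exact([[0, 0], [0, 0]])
        assert res.p == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_exhaustive_hypergeometric_enumeration(self, alternative):
        """Exact agreement with direct support enumeration for every 2x2
        table with N <= 30 margins drawn on a grid, and with the
        reference implementation in scipy."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            res = g.fisher_exact(table, alternative)
            oracle = float(fisher_tail_oracle(a, b, c, d, alternative))
            assert res.p == pytest.approx(oracle, rel=1e-9, abs=1e-12)
            alt = {"two-sided": "two-sided"}.get(alternative, alternative)
            assert res.p == pytest.approx(
                sps.fisher_exact(table, alternative=alt)[1], rel=1e-7)


def _plants_at_class_means(grains=200):
    """One plant per observed count, pollen at the model class means."""
    sel = g.SelectionModel.single((1, 0), g.MALE)
    recomb = g.RecombinationSpec.unlinked(2)
    plants = []
    for genotype, count in zip(g.enumerate_genotypes(2), TWO_LOCUS_OBSERVED):
        fert = float(g.pollen_fertility(genotype, sel, recomb))
        for _ in range(count):
            plants.append((genotype.states, round(fert * grains), grains))
    return plants


class TestSterilityModelSelection:
    def test_recovers_male_sterile_haplotype(self):
        """Genotype counts plus pollen phenotypes identify B|A as the
        male-sterile gamete class."""
        scores = g.sterility_model_selection(_plants_at_class_means())
        assert scores[0].name == "male B|A"
        # the female variant explains the genotypes but not the pollen
        by_name = {s.name: s.log_likelihood for s in scores}
        assert by_name["female B|A"] == -np.inf

    def test_neutral_data_ranks_neutral_first(self):
        rng = np.random.default_rng(3)
        genotypes = list(g.enumerate_genotypes(2))
        probs = np.array([1, 2, 1, 2, 4, 2, 1, 2, 1]) / 16
        counts = rng.multinomial(90, probs)
        plants = [(genotypes[i].states, 200, 200)
                  for i in range(9) for _ in range(counts[i])]
        scores = g.sterility_model_selection(plants)
        assert scores[0].name == "neutral"

    def test_genotypes_alone_tie_male_and_female(self):
        """Without pollen counts the male and female variants of one
        pattern have exactly equal likelihood."""
        plants = [(s, 0, 0) for s, _, _ in _plants_at_class_means()]
        by_name = {s.name: s.log_likelihood
                   for s in g.sterility_model_selection(plants)}
        assert by_name["male B|A"] == by_name["female B|A"]
        assert np.isfinite(by_name["male B|A"])

    def test_thirteen_default_candidates(self, candidate_models):
        assert len(candidate_models) == 13
        assert sum(1 for n, _ in candidate_models if n == "neutral") == 1

    def test_empty_input_rejected(self):
        with pytest.raises(g.EstimationError):
            g.sterility_model_selection([])


class TestEstimateCopyNumber:
    def test_vector_control_gives_zero_copies_with_flag(self):
        """The 45:48:1 control family: no rescue, and the single
        donor-homozygote plant is attributed to marker-gene
        recombination rather than to a transgene."""
        res = g.estimate_copy_number(T1_FAMILIES["vector"])
        assert res.c_hat == 0
        assert res.recombination_attributed == {"BB": 1}

    def test_exact_single_copy_ratio(self):
        res = g.estimate_copy_number((20, 30, 10), marker_r=0.0)
        assert res.c_hat == 1
        assert not res.at_boundary

    def test_mendelian_ratio_hits_the_boundary(self):
        res = g.estimate_copy_number((25, 50, 25), max_c=4, marker_r=0.0)
        assert res.c_hat == 4
        assert res.at_boundary

    def test_profile_spans_all_candidates(self):
        res = g.estimate_copy_number((20, 30, 10), max_c=3, marker_r=0.0)
        assert [c for c, _ in res.profile] == [0, 1, 2, 3]
        assert res.profile[0][1] == -np.inf  # BB impossible without rescue

    def test_t1_class_probabilities_closed_forms(self):
        assert np.allclose(g.t1_marker_class_probs(0), [0.5, 0.5, 0.0])
        assert np.allclose(g.t1_marker_class_probs(1), [1 / 3, 1 / 2, 1 / 6])


class TestClassifyFertility:
    def test_fully_fertile_plant(self):
        call = g.classify_fertility(200, 200)
        assert call.fertility_class == 1.0
        assert call.posterior[1.0] > 0.99

    def test_semisterile_plant(self):
        call = g.classify_fertility(100, 200)
        assert call.fertility_class == 0.5

    def test_matches_direct_likelihood_evaluation(self):
        """The call equals the argmax of beta-binomial likelihoods
        computed independently with scipy."""
        k, m, rho = 125, 200, 0.02
        means = [0.5, 0.75, 1.0]
        lls = []
        for p in means:
            if p == 1.0:  # degenerate beta: point mass, binomial tail
                lls.append(0.0 if k == m else -np.inf)
                continue
            a = p * (1 - rho) / rho
            b = (1 - p) * (1 - rho) / rho
            lls.append(sps.betabinom.logpmf(k, m, a, b))
        call = g.classify_fertility(k, m, means, rho)
        assert call.fertility_class == means[int(np.argmax(lls))]
        assert call.status == "ok"
        assert 0.999 < sum(call.posterior.values()) < 1.001

    def test_exact_tie_breaks_low_and_flags(self):
        # symmetric classes around k/m = 1/2 tie exactly under binomial
        call = g.classify_fertility(5, 10, [0.4, 0.6], rho=0.0)
        assert call.fertility_class == 0.4
        assert call.tie

    def test_no_grains_is_unclassifiable(self):
        call = g.classify_fertility(0, 0)
        assert call.status == "unclassifiable"
        assert call.fertility_class is None
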