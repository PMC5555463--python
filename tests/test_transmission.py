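"""Offspring distributions, fertility classes and transgene rescue."""

import itertools
from fractions import Fraction

import pytest

import gamsel as g
from _oracles import offspring_oracle, pollen_fertility_oracle
from conftest import TWO_LOCUS_RATIO

F = Fraction
HALF = F(1, 2)


class TestOffspringDistribution:
    def test_selfed_double_het_with_male_sterile_haplotype(
            self, double_het, unlinked2, male_ba):
        """The canonical 1:2:1:1:3:2:0:1:1 segregation over 9 classes."""
        dist = g.offspring_distribution(double_het, double_het, male_ba,
                                        unlinked2)
        assert dist.to_vector() == [F(r, 12) for r in TWO_LOCUS_RATIO]

    def test_single_segregating_locus_under_selection(self, unlinked2, male_ba):
        """Fixed sterile background: the donor homozygote class vanishes
        because no viable male gamete carries the donor allele."""
        parent = g.Genotype((1, 0))
        dist = g.offspring_distribution(parent, parent, male_ba, unlinked2)
        locus1 = dist.marginal(0)
        assert [locus1[(s,)] for s in (0, 1, 2)] == [HALF, HALF, 0]

    def test_neutral_testcross(self, double_het, unlinked2):
        tester = g.Genotype((0, 0))
        dist = g.offspring_distribution(double_het, tester, recomb=unlinked2)
        assert sorted(dist.probs.values()) == [F(1, 4)] * 4

    def test_matches_exhaustive_gamete_pair_enumeration(self, candidate_models):
        """Engine equals the brute-force (egg, sperm) enumeration for
        phased two-locus parents under every candidate model."""
        r = F(1, 10)
        loci = (g.Locus("a", "c1", 0.0), g.Locus("b", "c1", 1.0))
        recomb = g.RecombinationSpec.from_adjacent((r,), loci=loci)
        mother = g.Genotype.from_phase((0, 0), (1, 1))
        father = g.Genotype.from_phase((0, 1), (1, 0))
        for name, model in candidate_models:
            rules = [(rl.pattern, rl.sex, rl.penetrance) for rl in model.rules]
            try:
                got = g.offspring_distribution(mother, father, model, recomb)
            except g.NoViableGametesError:
                continue
            expected = offspring_oracle(mother.phase, father.phase, (r,), rules)
            assert dict(got.items()) == expected, name

    def test_three_locus_oracle_agreement(self):
        recomb = g.RecombinationSpec.unlinked(3)
        rs = (HALF, HALF)
        parent = g.Genotype((1, 1, 1))
        model = g.SelectionModel.single((1, 0, None), g.MALE)
        rules = [(rl.pattern, rl.sex, rl.penetrance) for rl in model.rules]
        got = g.offspring_distribution(parent, parent, model, recomb)
        phase = ((0, 0, 0), (1, 1, 1))
        assert dict(got.items()) == offspring_oracle(phase, phase, rs, rules)

    def test_male_and_female_selection_give_identical_genotypes(
            self, double_het, unlinked2):
        """Genotype data alone cannot attribute selection to a sex."""
        male = g.SelectionModel.single((1, 0), g.MALE)
        female = g.SelectionModel.single((1, 0), g.FEMALE)
        d_male = g.offspring_distribution(double_het, double_het, male, unlinked2)
        d_female = g.offspring_distribution(double_het, double_het, female,
                                            unlinked2)
        assert dict(d_male.items()) == dict(d_female.items())


class TestPollenFertility:
    @pytest.mark.parametrize("states,expected", [
        ((0, 0), 1),            # recurrent-parent type: fully fertile
        ((1, 0), HALF),         # semisterile heterozygote
        ((1, 1), F(3, 4)),      # double het: 1 of 4 gamete classes sterile
        ((2, 0), 0),            # every male gamete carries the sterile pair
    ])
    def test_expected_fertility_fractions(self, states, expected, unlinked2,
                                          male_ba):
        assert g.pollen_fertility(g.Genotype(states), male_ba,
                                  unlinked2) == expected

    def test_female_rule_does_not_touch_pollen(self, unlinked2):
        female = g.SelectionModel.single((1, 0), g.FEMALE)
        assert g.pollen_fertility(g.Genotype((1, 1)), female, unlinked2) == 1


class TestFertilityClassDistribution:
    def test_segregating_family_classes(self, double_het, unlinked2, male_ba):
        """Sterility levels 50/75/100% segregate 2:3:7."""
        pop = g.offspring_distribution(double_het, double_het, male_ba, unlinked2)
        classes = g.fertility_class_distribution(pop, male_ba, unlinked2)
        assert classes == {HALF: F(2, 12), F(3, 4): F(3, 12), F(1): F(7, 12)}

    def test_neutral_population_is_point_mass(self, double_het, unlinked2):
        pop = g.offspring_distribution(double_het, double_het, recomb=unlinked2)
        classes = g.fertility_class_distribution(pop, recomb=unlinked2)
        assert classes == {1: 1}

    def test_testcross_population_classes(self, double_het, unlinked2, male_ba):
        tester = g.Genotype((0, 0))
        pop = g.offspring_distribution(double_het, tester, male_ba, unlinked2)
        classes = g.fertility_class_distribution(pop, male_ba, unlinked2)
        assert classes == {F(1): HALF, F(3, 4): F(1, 4), HALF: F(1, 4)}

    def test_fertility_asymmetry_separates_sexes(self, double_het, unlinked2):
        """Same genotype distribution, different pollen phenotypes: the
        asymmetry that lets pollen data attribute selection to males."""
        male = g.SelectionModel.single((1, 0), g.MALE)
        female = g.SelectionModel.single((1, 0), g.FEMALE)
        pop = g.offspring_distribution(double_het, double_het, male, unlinked2)
        male_classes = g.fertility_class_distribution(pop, male, unlinked2)
        female_classes = g.fertility_class_distribution(pop, female, unlinked2)
        assert female_classes == {1: 1}
        assert male_classes != female_classes


class TestPropagate:
    def test_single_neutral_self_is_independent_mendelian(self, double_het):
        design = g.CrossDesign(double_het, (g.Self(),),
                               recomb=g.RecombinationSpec.unlinked(2))
        (dist,) = g.propagate(design)
        single = {0: F(1, 4), 1: HALF, 2: F(1, 4)}
        for s1 in (0, 1, 2):
            for s2 in (0, 1, 2):
                assert dist[(s1, s2)] == single[s1] * single[s2]

    def test_self_under_selection_matches_direct_cross(
            self, double_het, unlinked2, male_ba):
        design = g.CrossDesign(double_het, (g.Self(),), male_ba, unlinked2)
        (dist,) = g.propagate(design)
        assert dist.to_vector() == [F(r, 12) for r in TWO_LOCUS_RATIO]

    def test_two_neutral_selfs_halve_heterozygosity(self):
        design = g.CrossDesign(g.Genotype((1,)), (g.Self(), g.Self()),
                               recomb=g.RecombinationSpec.unlinked(1))
        f2, f3 = g.propagate(design)
        assert [f2[(s,)] for s in (0, 1, 2)] == [F(1, 4), HALF, F(1, 4)]
        assert [f3[(s,)] for s in (0, 1, 2)] == [F(3, 8), F(1, 4), F(3, 8)]

    def test_founder_pair_and_backcross(self):
        recomb = g.RecombinationSpec.unlinked(1)
        design = g.CrossDesign((g.Genotype((0,)), g.Genotype((2,))),
                               (g.Backcross(g.Genotype((0,))),),
                               recomb=recomb)
        (bc1,) = g.propagate(design)
        assert [bc1[(s,)] for s in (0, 1, 2)] == [HALF, HALF, 0]

    def test_empty_design_rejected(self, double_het):
        with pytest.raises(ValueError):
            g.CrossDesign(double_het, ())


class TestRescue:
    def _t1(self, copies):
        """Marker-free single-locus rescue: selfed semisterile plant."""
        parent = g.Genotype((1,))
        recomb = g.RecombinationSpec.unlinked(1)
        sel = g.SelectionModel.single((1,), g.MALE)
        rescue = g.RescueModel(copies) if copies else None
        dist = g.rescued_offspring_distribution(parent, rescue, sel, recomb) \
            if rescue else g.offspring_distribution(parent, parent, sel, recomb)
        return [dist[(s,)] for s in (0, 1, 2)]

    def test_no_transgene_reproduces_distorted_ratio(self):
        assert self._t1(0) == [HALF, HALF, 0]

    def test_single_copy_gives_2_3_1(self):
        assert self._t1(1) == [F(2, 6), F(3, 6), F(1, 6)]

    def test_many_copies_restore_mendelian_ratio(self):
        aa, ab, bb = self._t1(40)
        assert abs(aa - F(1, 4)) < F(1, 10) ** 10
        assert abs(bb - F(1, 4)) < F(1, 10) ** 10

    def test_rescued_homozygote_class_monotone_in_copies(self):
        bbs = [self._t1(c)[2] for c in range(0, 7)]
        assert bbs[0] == 0
        assert all(b1 - b0 > 0 for b0, b1 in zip(bbs, bbs[1:]))

    def test_heterozygote_frequency_is_half_for_any_rescue(self):
        for c in range(1, 9):
            assert self._t1(c)[1] == HALF

    def test_rescue_probability_q(self):
        assert g.RescueModel(0).q == 0
        assert g.RescueModel(1).q == HALF
        assert g.RescueModel(3).q == F(7, 8)
        with pytest.raises(ValueError):
            g.RescueModel(-1)
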