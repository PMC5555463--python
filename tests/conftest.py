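from fractions import Fraction

import pytest

import gamsel as g

# class counts and model ratio of the canonical two-locus selfed family
# (9 classes in locus-major order, double-sterile homozygote absent)
TWO_LOCUS_OBSERVED = (9, 14, 9, 10, 18, 15, 0, 7, 8)
TWO_LOCUS_RATIO = (1, 2, 1, 1, 3, 2, 0, 1, 1)

# transgene-rescue T1 families: (AA, AB, BB) at the linked marker
T1_FAMILIES = {
    "line1": (19, 39, 10),
    "line2": (18, 47, 15),
    "line3": (22, 33, 18),
    "line4": (6, 16, 6),
    "vector": (45, 48, 1),
}


@pytest.fixture
def male_ba():
    """Male gametes carrying B at locus 1 and A at locus 2 are sterile."""
    return g.SelectionModel.single((1, 0), g.MALE)


@pytest.fixture
def unlinked2():
    return g.RecombinationSpec.unlinked(2)


@pytest.fixture
def double_het():
    return g.Genotype((1, 1))


@pytest.fixture
def candidate_models():
    return g.default_candidate_models()


def expected_two_locus_distribution():
    return [Fraction(r, 12) for r in TWO_LOCUS_RATIO]
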