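"""Expected genotype and pollen-fertility distributions under crosses.

An offspring distribution is the outer product of the two sex-specific
gamete distributions, fused and aggregated to unphased genotype
classes.  Because selection can act on one sex only (here: pollen), a
cross can show strong transmission-ratio distortion while every plant
sets seed normally; the same machinery also predicts each genotype's
expected pollen fertility, which is what lets fertility phenotypes
stand in for genotypes at an unscored locus.

The transgene rescue model covers the complementation-test design: a
hemizygous transgene with ``c`` independent unlinked insertions rescues
a sterile male gamete with probability q = 1 - (1/2)**c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

from .core import (
    FEMALE,
    HALF,
    MALE,
    NEUTRAL,
    GameteDistribution,
    Genotype,
    RecombinationSpec,
    SelectionModel,
    enumerate_genotypes,
    gamete_distribution,
    gamete_weights,
)
from .errors import GamselError


@dataclass(frozen=True)
class RescueModel:
    """Transgene rescue of gametes hit by a sterility rule.

    copies: number of independent, hemizygous, unlinked insertions in
    the selfed transformant.  A gamete inherits at least one insertion
    with probability q = 1 - (1/2)**copies and is then viable even if it
    matches a sterile pattern.  Rescue applies to male gametes by
    default because the sterile patterns here are male-specific.
    """

    copies: int
    sexes: tuple = (MALE,)

    def __post_init__(self):
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        object.__setattr__(self, "sexes", tuple(self.sexes))

    @property
    def q(self) -> Fraction:
        return 1 - HALF ** self.copies

    def covers(self, sex: str) -> bool:
        return sex in self.sexes


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probability mapping over unphased multi-locus genotype classes."""

    probs: dict  # states tuple -> probability

    def __post_init__(self):
        object.__setattr__(self, "probs", dict(self.probs))

    @property
    def n_loci(self) -> int:
        return len(next(iter(self.probs)))

    def __getitem__(self, genotype) -> Union[float, Fraction]:
        key = genotype.states if isinstance(genotype, Genotype) else tuple(genotype)
        return self.probs.get(key, 0)

    def items(self):
        return self.probs.items()

    def total(self):
        return sum(self.probs.values())

    def to_vector(self) -> list:
        """Probabilities in canonical :func:`enumerate_genotypes` order."""
        return [self[g] for g in enumerate_genotypes(self.n_loci)]

    def expected_counts(self, n: int) -> list:
        return [n * p for p in self.to_vector()]

    def marginal(self, locus_index: int) -> "GenotypeDistribution":
        out: dict = {}
        for states, p in self.probs.items():
            key = (states[locus_index],)
            out[key] = out.get(key, 0) + p
        return GenotypeDistribution(out)


def offspring_distribution(mother: Genotype, father: Genotype,
                           selection: SelectionModel = NEUTRAL,
                           recomb: Optional[RecombinationSpec] = None,
                           rescue: Optional[RescueModel] = None,
                           ) -> GenotypeDistribution:
    """Genotype-class distribution of one cross under gametic selection."""
    if mother.n_loci != father.n_loci:
        raise GamselError("parents cover different locus sets")
    eggs = gamete_distribution(mother, recomb, FEMALE, selection, rescue)
    sperm = gamete_distribution(father, recomb, MALE, selection, rescue)
    out: dict = {}
    for e_hap, e_p in eggs.items():
        for s_hap, s_p in sperm.items():
            states = tuple(a + b for a, b in zip(e_hap, s_hap))
            out[states] = out.get(states, 0) + e_p * s_p
    return GenotypeDistribution(out)


def pollen_fertility(plant: Genotype, selection: SelectionModel = NEUTRAL,
                     recomb: Optional[RecombinationSpec] = None,
                     rescue: Optional[RescueModel] = None):
    """Fraction of a plant's male gametes that escape every sterile rule.

    This is the transmitted fraction before renormalisation, i.e. the
    expected proportion of stainable/functional pollen.  Returns 0 for a
    plant whose male gametes are all inviable.
    """
    _, total = gamete_weights(plant, recomb, MALE, selection, rescue)
    return total


def fertility_class_distribution(population: GenotypeDistribution,
                                 selection: SelectionModel = NEUTRAL,
                                 recomb: Optional[RecombinationSpec] = None,
                                 rescue: Optional[RescueModel] = None,
                                 tol: float = 1e-9) -> dict:
    """Push pollen fertility through a genotype distribution.

    Genotype classes with (numerically) equal fertility are merged;
    ``tol`` bounds the merge distance so float jitter cannot split a
    class.  Exact (Fraction) fertilities merge exactly.
    """
    classes: dict = {}
    for states, p in population.items():
        fert = pollen_fertility(Genotype(states), selection, recomb, rescue)
        key = None
        for existing in classes:
            if existing == fert or abs(float(existing) - float(fert)) <= tol:
                key = existing
                break
        if key is None:
            key = fert
            classes[key] = 0
        classes[key] = classes[key] + p
    return classes


# ----------------------------------------------------------------- crosses

@dataclass(frozen=True)
class Self:
    """Self-pollination of the current population."""


@dataclass(frozen=True)
class Backcross:
    """Cross of the current population to a declared recurrent parent."""

    recurrent: Genotype
    recurrent_is_female: bool = False


@dataclass(frozen=True)
class CrossDesign:
    """A founder cross (or starting genotype) plus an ordered step list.

    founders may be a pair of genotypes (the initial cross producing the
    starting population) or a single genotype (a point-mass start, e.g.
    an already-identified heterozygote).
    """

    founders: Union[Genotype, tuple]
    steps: tuple
    selection: SelectionModel = NEUTRAL
    recomb: Optional[RecombinationSpec] = None

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise ValueError("a cross design needs at least one step")


def propagate(design: CrossDesign) -> list[GenotypeDistribution]:
    """Expected genotype distribution after each step of a design.

    Selfing a population means selfing each genotype and mixing the
    offspring by the parental probabilities; intermediate genotypes are
    unphased, so multi-generation designs are restricted to loci where
    phase is irrelevant (unlinked, or at most one heterozygous locus per
    linked block).
    """
    if isinstance(design.founders, Genotype):
        current = GenotypeDistribution({design.founders.states: 1})
    else:
        mother, father = design.founders
        current = offspring_distribution(mother, father, design.selection,
                                         design.recomb)
    results = []
    for step in design.steps:
        nxt: dict = {}
        for states, p in current.items():
            parent = Genotype(states)
            if isinstance(step, Self):
                child = offspring_distribution(parent, parent, design.selection,
                                               design.recomb)
            elif isinstance(step, Backcross):
                mother, father = ((step.recurrent, parent)
                                  if step.recurrent_is_female
                                  else (parent, step.recurrent))
                child = offspring_distribution(mother, father, design.selection,
                                               design.recomb)
            else:
                raise TypeError(f"unknown cross step {step!r}")
            for s, q in child.items():
                nxt[s] = nxt.get(s, 0) + p * q
        current = GenotypeDistribution(nxt)
        results.append(current)
    return results


def rescued_offspring_distribution(t0: Genotype, rescue: RescueModel,
                                   selection: SelectionModel,
                                   recomb: Optional[RecombinationSpec] = None,
                                   ) -> GenotypeDistribution:
    """T1 genotype distribution from selfing a hemizygous transformant.

    Male gametes matching a sterile pattern survive with probability
    q = 1 - (1/2)**copies; female gametes are untouched.  The transgene
    itself is marginalised out (its insertions are unlinked to the
    scored loci).
    """
    return offspring_distribution(t0, t0, selection, recomb, rescue=rescue)
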