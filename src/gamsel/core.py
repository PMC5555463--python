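"""Allele, haplotype and genotype algebra, and gamete generation.

The package models two parental genomes segregating in a biallelic
cross: allele ``A`` (coded 0) is the recurrent / cultivated parent and
allele ``B`` (coded 1) the donor / wild parent.  A diploid genotype is
an ordered vector of per-locus states in {AA, AB, BB} (coded 0, 1, 2 =
number of B alleles), optionally carrying an explicit phase (the pair
of parental haplotypes).

Gametes are generated by enumerating meiotic inheritance vectors with
recombination between adjacent loci, then applying a gametic
:class:`SelectionModel` that declares which haplotypes are inviable in
which sex.  All probability arithmetic is polymorphic: with exact
inputs (``fractions.Fraction`` recombination fractions, integer
penetrance) the distributions come out as exact rationals, which is how
the canonical expected segregation ratios are derived.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

from .errors import (
    LocusMismatchError,
    NoViableGametesError,
    PhaseAmbiguityError,
)

HALF = Fraction(1, 2)

#: mapping between text codes and internal integers
ALLELE_CODES = {"A": 0, "B": 1}
ALLELE_NAMES = {0: "A", 1: "B"}
STATE_CODES = {"A": 0, "H": 1, "B": 2}
STATE_NAMES = {0: "A", 1: "H", 2: "B"}

MALE = "male"
FEMALE = "female"
BOTH = "both"
SEXES = (MALE, FEMALE)

Haplotype = tuple  # tuple of 0/1 alleles, one per locus


@dataclass(frozen=True)
class Locus:
    """A mapped marker or gene.

    position is a map position in centimorgans; loci on the same
    chromosome must have positions so recombination fractions can be
    derived from the map.
    """

    name: str
    chromosome: str = "1"
    position: Optional[float] = None

    def __post_init__(self):
        if self.position is not None and self.position < 0:
            raise ValueError(f"negative map position for locus {self.name}")


def unlinked_loci(n: int, prefix: str = "L") -> tuple[Locus, ...]:
    """n loci on n distinct chromosomes (pairwise r = 1/2)."""
    return tuple(Locus(f"{prefix}{i + 1}", chromosome=f"chr{i + 1}", position=0.0)
                 for i in range(n))


@dataclass(frozen=True)
class Genotype:
    """Unphased diploid states with an optional explicit phase.

    states: per-locus counts of the B allele (0=AA, 1=AB, 2=BB).
    phase:  optional pair of haplotypes; must reconstruct ``states``.
    """

    states: tuple
    phase: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))
        if any(s not in (0, 1, 2) for s in self.states):
            raise ValueError(f"genotype states must be 0/1/2, got {self.states}")
        if self.phase is not None:
            h1, h2 = self.phase
            h1, h2 = tuple(h1), tuple(h2)
            object.__setattr__(self, "phase", (h1, h2))
            if len(h1) != len(self.states) or len(h2) != len(self.states):
                raise LocusMismatchError("phase length differs from states length")
            if tuple(a + b for a, b in zip(h1, h2)) != self.states:
                raise ValueError("phase does not reconstruct genotype states")

    @classmethod
    def from_string(cls, code: str) -> "Genotype":
        """Build from per-locus letters, e.g. ``"HH"`` or ``"A,H,B"``."""
        cells = code.split(",") if "," in code else list(code)
        try:
            states = tuple(STATE_CODES[c.strip().upper()] for c in cells)
        except KeyError as exc:
            raise ValueError(f"unknown genotype code {exc.args[0]!r} in {code!r}") from None
        return cls(states)

    @classmethod
    def from_phase(cls, h1: Sequence[int], h2: Sequence[int]) -> "Genotype":
        h1, h2 = tuple(h1), tuple(h2)
        return cls(tuple(a + b for a, b in zip(h1, h2)), phase=(h1, h2))

    @property
    def n_loci(self) -> int:
        return len(self.states)

    def het_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.states) if s == 1)

    def to_string(self) -> str:
        return "".join(STATE_NAMES[s] for s in self.states)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


@dataclass(frozen=True)
class SelectionRule:
    """One gamete-inviability rule.

    pattern entries are 0 (allele A), 1 (allele B) or None (wildcard);
    a gamete matching the pattern in the given sex is inviable with
    probability ``penetrance``.  Integer penetrance 1 keeps the
    arithmetic exact.
    """

    pattern: tuple
    sex: str = MALE
    penetrance: Union[int, float, Fraction] = 1

    def __post_init__(self):
        object.__setattr__(
            self, "pattern",
            tuple(None if p is None else int(p) for p in self.pattern))
        if any(p not in (0, 1, None) for p in self.pattern):
            raise ValueError("pattern entries must be 0, 1 or None")
        if self.sex not in (MALE, FEMALE, BOTH):
            raise ValueError(f"sex must be male/female/both, got {self.sex!r}")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must lie in [0, 1]")

    def applies_to(self, sex: str) -> bool:
        return self.sex == BOTH or self.sex == sex

    def matches(self, haplotype: Haplotype) -> bool:
        if len(haplotype) != len(self.pattern):
            raise LocusMismatchError("haplotype/pattern length mismatch")
        return all(p is None or p == a for p, a in zip(self.pattern, haplotype))


@dataclass(frozen=True)
class SelectionModel:
    """A set of gametic selection rules; the empty set is neutral."""

    rules: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))

    @classmethod
    def single(cls, pattern, sex: str = MALE, penetrance=1) -> "SelectionModel":
        return cls((SelectionRule(tuple(pattern), sex, penetrance),))

    @property
    def is_neutral(self) -> bool:
        return not self.rules

    def viability(self, haplotype: Haplotype, sex: str, rescue=None):
        """Survival probability of a gamete of this haplotype in this sex.

        ``rescue`` is an optional transgene rescue model: a gamete hit
        by a rule survives anyway with probability ``rescue.q`` when the
        rescue covers the sex in question.
        """
        v = 1
        for rule in self.rules:
            if rule.applies_to(sex) and rule.matches(haplotype):
                pen = rule.penetrance
                if rescue is not None and rescue.covers(sex):
                    pen = pen * (1 - rescue.q)
                v = v * (1 - pen)
        return v


NEUTRAL = SelectionModel()


def _same_chromosome_blocks(loci: Sequence[Locus]) -> list[list[int]]:
    blocks: list[list[int]] = []
    for i, locus in enumerate(loci):
        if blocks and loci[blocks[-1][-1]].chromosome == locus.chromosome:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    return blocks


@dataclass(frozen=True)
class RecombinationSpec:
    """Recombination fractions between adjacent loci in an ordered set.

    Adjacent loci on different chromosomes recombine freely (r = 1/2,
    held as an exact Fraction).  Within a chromosome, r comes either
    from explicit values or from cM positions through a map function.
    """

    loci: tuple
    adjacent_r: tuple

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "adjacent_r", tuple(self.adjacent_r))
        if len(self.adjacent_r) != max(len(self.loci) - 1, 0):
            raise ValueError("need exactly one r per adjacent locus pair")
        for r in self.adjacent_r:
            if not 0 <= r <= HALF:
                raise ValueError(f"recombination fraction {r} outside [0, 1/2]")

    @classmethod
    def unlinked(cls, n_loci: int) -> "RecombinationSpec":
        return cls(unlinked_loci(n_loci), (HALF,) * (n_loci - 1))

    @classmethod
    def from_adjacent(cls, rs: Sequence, loci: Optional[Sequence[Locus]] = None):
        rs = tuple(rs)
        if loci is None:
            # r = 1/2 exactly is read as "different chromosomes"
            loci_list, chrom = [], 0
            for i in range(len(rs) + 1):
                if i == 0 or rs[i - 1] == HALF:
                    chrom += 1
                loci_list.append(Locus(f"L{i + 1}", chromosome=f"chr{chrom}"))
            loci = loci_list
        return cls(tuple(loci), rs)

    @classmethod
    def from_loci(cls, loci: Sequence[Locus], map_function: str = "kosambi"):
        from .linkage import cm_to_r  # local import: linkage depends on core

        loci = tuple(loci)
        rs = []
        for left, right in zip(loci, loci[1:]):
            if left.chromosome != right.chromosome:
                rs.append(HALF)
                continue
            if left.position is None or right.position is None:
                raise ValueError(
                    f"loci {left.name}/{right.name} share chromosome "
                    f"{left.chromosome} but lack map positions")
            rs.append(cm_to_r(abs(right.position - left.position), map_function))
        return cls(loci, tuple(rs))

    def linked_blocks(self) -> list[list[int]]:
        """Indices of loci grouped into linked (same chromosome) runs."""
        return _same_chromosome_blocks(self.loci)


@dataclass(frozen=True)
class GameteDistribution:
    """Post-selection haplotype probabilities plus the survival rate.

    ``transmitted_fraction`` is the pre-renormalisation probability mass
    of viable gametes; for male gametes it equals the plant's expected
    pollen fertility.
    """

    probs: dict
    transmitted_fraction: Union[float, Fraction]

    def items(self):
        return self.probs.items()

    def __getitem__(self, haplotype):
        return self.probs.get(tuple(haplotype), 0)


def resolve_phase(parent: Genotype, recomb: RecombinationSpec) -> tuple:
    """Return a usable phase for ``parent``.

    An explicit phase wins.  Otherwise a canonical phase is built, which
    is legitimate only when no linked block carries more than one
    heterozygous locus (with at most one het per block, every consistent
    phase yields the same gamete distribution).
    """
    if parent.phase is not None:
        return parent.phase
    het = set(parent.het_indices())
    for block in recomb.linked_blocks():
        block_het = [i for i in block if i in het]
        if len(block_het) > 1:
            names = ", ".join(recomb.loci[i].name for i in block_het)
            raise PhaseAmbiguityError(
                f"unphased genotype heterozygous at linked loci ({names}); "
                "supply a phase or declare the loci unlinked")
    h1 = tuple(0 if s < 2 else 1 for s in parent.states)
    h2 = tuple(s - a for s, a in zip(parent.states, h1))
    return h1, h2


def _meiotic_products(parent: Genotype, recomb: RecombinationSpec) -> dict:
    """Pre-selection haplotype distribution from one meiosis."""
    phase = resolve_phase(parent, recomb)
    n = parent.n_loci
    out: dict = {}
    for choices in itertools.product((0, 1), repeat=n):
        p = HALF
        for i in range(1, n):
            r = recomb.adjacent_r[i - 1]
            p = p * (r if choices[i] != choices[i - 1] else 1 - r)
        hap = tuple(phase[c][i] for i, c in enumerate(choices))
        out[hap] = out.get(hap, 0) + p
    return out


def gamete_weights(parent: Genotype, recomb: Optional[RecombinationSpec] = None,
                   sex: str = MALE, selection: SelectionModel = NEUTRAL,
                   rescue=None) -> tuple[dict, Union[float, Fraction]]:
    """Viability-weighted (unnormalised) gamete distribution and its mass.

    The returned mass is the transmitted fraction: 1 under neutrality,
    less when selection removes gametes.  No renormalisation and no
    error on total loss -- callers wanting a proper distribution use
    :func:`gamete_distribution`.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if recomb is None:
        recomb = RecombinationSpec.unlinked(parent.n_loci)
    if len(recomb.loci) != parent.n_loci:
        raise LocusMismatchError("recombination spec does not match genotype")
    raw = _meiotic_products(parent, recomb)
    weighted = {}
    total = 0
    for hap, p in raw.items():
        v = selection.viability(hap, sex, rescue=rescue)
        w = p * v
        if w != 0:
            weighted[hap] = w
        total = total + w
    return weighted, total


def gamete_distribution(parent: Genotype,
                        recomb: Optional[RecombinationSpec] = None,
                        sex: str = MALE,
                        selection: SelectionModel = NEUTRAL,
                        rescue=None) -> GameteDistribution:
    """Haplotype distribution produced by one parent, after selection.

    Gametes matching a selection rule for this sex are down-weighted by
    the rule's penetrance; the distribution is renormalised and the
    renormalisation constant (transmitted fraction) reported alongside.
    """
    weighted, total = gamete_weights(parent, recomb, sex, selection, rescue)
    if total == 0:
        raise NoViableGametesError(
            f"no viable {sex} gametes for genotype {parent.to_string()}")
    probs = {hap: w / total for hap, w in weighted.items()}
    return GameteDistribution(probs, total)


def fuse(egg: Haplotype, sperm: Haplotype) -> Genotype:
    """Syngamy: combine two haplotypes into a phased genotype."""
    egg, sperm = tuple(egg), tuple(sperm)
    if len(egg) != len(sperm):
        raise LocusMismatchError("egg and sperm cover different locus sets")
    return Genotype.from_phase(egg, sperm)


def enumerate_genotypes(n_loci: int) -> list[Genotype]:
    """All 3**n unphased genotype classes in canonical (table) order.

    Locus-major: the first locus varies slowest, states ordered
    AA < AB < BB.  For two loci this is the classical 9-row table order.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return [Genotype(states)
            for states in itertools.product((0, 1, 2), repeat=n_loci)]


def state_labels(n_loci: int) -> list[str]:
    """Text labels (e.g. 'AH') aligned with :func:`enumerate_genotypes`."""
    return [g.to_string() for g in enumerate_genotypes(n_loci)]
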