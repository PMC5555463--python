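"""Exception hierarchy."""


class GamselError(Exception):
    """Base class for all package errors."""


class LocusMismatchError(GamselError):
    """Gametes or genotypes defined over incompatible locus sets."""


class PhaseAmbiguityError(GamselError):
    """Unphased genotype heterozygous at more than one linked locus.

    Gamete frequencies over linked loci depend on whether the
    heterozygous sites are in coupling or repulsion, so the caller must
    supply a phase (or declare the loci unlinked).
    """


class NoViableGametesError(GamselError):
    """Selection removes every gamete a parent can produce."""


class ModelViolationError(GamselError):
    """Observed counts in a class the model says cannot occur."""

    def __init__(self, message, classes=()):
        super().__init__(message)
        self.classes = tuple(classes)


class PhenotypeImpossibleError(GamselError):
    """A fertility phenotype unattainable under the declared model."""


class EstimationError(GamselError):
    """No informative data for a requested estimate."""
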