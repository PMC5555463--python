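"""Map functions, two-point linkage under selection, fine-mapping.

Two-point estimation here is selection-aware: expected joint
marker x gene class frequencies are computed by the transmission engine
with the marker-gene recombination fraction r as the free parameter, so
segregation distortion caused by pollen selection does not bias r-hat
the way a naive recombinant-fraction count would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .core import (
    MALE,
    NEUTRAL,
    Genotype,
    Locus,
    RecombinationSpec,
    SelectionModel,
    enumerate_genotypes,
)
from .errors import EstimationError, PhenotypeImpossibleError
from .transmission import offspring_distribution, pollen_fertility

MAP_FUNCTIONS = ("kosambi", "haldane", "morgan")

#: log-likelihood drop bounding a 95% profile interval (chi2_1 / 2)
_LR_DROP_95 = 1.9207


def r_to_cm(r, kind: str = "kosambi") -> float:
    """Map distance (cM) for a recombination fraction.

    kosambi: d = 25 ln((1+2r)/(1-2r));  haldane: d = -50 ln(1-2r);
    morgan: d = 100 r.  r must lie in [0, 0.5); 0.5 maps to infinite
    distance for the first two and raises.
    """
    r = float(r)
    if r < 0:
        raise ValueError(f"recombination fraction {r} < 0")
    if kind == "morgan":
        if r > 0.5:
            raise ValueError(f"recombination fraction {r} > 1/2")
        return 100.0 * r
    if r >= 0.5:
        raise ValueError(f"map distance infinite at r >= 1/2 (got {r})")
    if kind == "kosambi":
        return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))
    if kind == "haldane":
        return -50.0 * math.log(1 - 2 * r)
    raise ValueError(f"unknown map function {kind!r}")


def cm_to_r(d, kind: str = "kosambi") -> float:
    """Recombination fraction for a map distance (exact inverse of r_to_cm).

    d -> infinity asymptotes to r = 0.5 (morgan caps at 0.5 beyond 50 cM).
    """
    d = float(d)
    if d < 0:
        raise ValueError(f"negative map distance {d}")
    if kind == "kosambi":
        return 0.5 * math.tanh(d / 50.0)
    if kind == "haldane":
        return 0.5 * (1.0 - math.exp(-d / 50.0))
    if kind == "morgan":
        return min(d / 100.0, 0.5)
    raise ValueError(f"unknown map function {kind!r}")


# ------------------------------------------------- genotype from phenotype

@dataclass(frozen=True)
class GeneInference:
    """Gene-locus state implied by a fertility phenotype."""

    state: Optional[int]
    ambiguous: bool
    candidates: dict  # state -> model fertility


def infer_gene_genotype(fertility_class: float, gene_locus: int,
                        background: Genotype,
                        selection: SelectionModel,
                        recomb: Optional[RecombinationSpec] = None,
                        atol: float = 0.02) -> GeneInference:
    """Read the genotype at an unscored gene locus off pollen fertility.

    Tries each state (AA/AB/BB) at ``gene_locus`` inside the declared
    ``background`` genotype and keeps those whose model fertility matches
    the observed class within ``atol``.  Exactly one match gives the
    state; several give an ambiguity flag (e.g. under a neutral model,
    where every genotype is fully fertile); none raises.
    """
    candidates: dict = {}
    matches = []
    for state in (0, 1, 2):
        states = list(background.states)
        states[gene_locus] = state
        fert = pollen_fertility(Genotype(tuple(states)), selection, recomb)
        candidates[state] = fert
        if abs(float(fert) - float(fertility_class)) <= atol:
            matches.append(state)
    if not matches:
        raise PhenotypeImpossibleError(
            f"fertility {fertility_class} impossible at locus {gene_locus} "
            f"under the declared model (attainable: "
            f"{sorted(set(float(f) for f in candidates.values()))})")
    if len(matches) > 1:
        return GeneInference(None, True, candidates)
    return GeneInference(matches[0], False, candidates)


# ------------------------------------------------------ two-point mapping

@dataclass(frozen=True)
class TwoPointModel:
    """Expected marker x gene class frequencies as a function of r.

    kind 'self': selfing of a plant heterozygous at marker and gene
    (the segregating-family design); 'backcross': het plant crossed to
    the recurrent AA|AA parent.  phase is the het parent's linkage
    phase; selection acts through the transmission engine.
    """

    kind: str = "self"
    selection: SelectionModel = NEUTRAL
    phase: str = "coupling"
    het_parent_is_female: bool = True

    def __post_init__(self):
        if self.kind not in ("self", "backcross"):
            raise ValueError("kind must be 'self' or 'backcross'")
        if self.phase not in ("coupling", "repulsion"):
            raise ValueError("phase must be 'coupling' or 'repulsion'")

    def _parent(self) -> Genotype:
        if self.phase == "coupling":
            return Genotype.from_phase((0, 0), (1, 1))
        return Genotype.from_phase((0, 1), (1, 0))

    def class_probs(self, r) -> np.ndarray:
        """9-vector of class probabilities in canonical order."""
        loci = (Locus("marker", "chr", 0.0), Locus("gene", "chr", 0.0))
        recomb = RecombinationSpec(loci, (r,))
        parent = self._parent()
        if self.kind == "self":
            dist = offspring_distribution(parent, parent, self.selection, recomb)
        else:
            recurrent = Genotype((0, 0))
            mother, father = ((parent, recurrent)
                              if self.het_parent_is_female
                              else (recurrent, parent))
            dist = offspring_distribution(mother, father, self.selection, recomb)
        return np.array([float(p) for p in dist.to_vector()])


@dataclass(frozen=True)
class TwoPointResult:
    r_hat: float
    ci: tuple  # (low, high) 95% profile-likelihood interval
    log_likelihood: float
    n: int
    cm: Optional[float]  # Kosambi distance of r_hat, None when unlinked

    def __str__(self):  # pragma: no cover - cosmetic
        cm = "inf" if self.cm is None else f"{self.cm:.1f}"
        return (f"r_hat={self.r_hat:.4f} ({cm} cM Kosambi), "
                f"95% CI [{self.ci[0]:.4f}, {self.ci[1]:.4f}], n={self.n}")


def _counts_to_array(counts) -> np.ndarray:
    if isinstance(counts, dict):
        arr = np.zeros((3, 3))
        for (m, g), n in counts.items():
            arr[int(m), int(g)] += n
        return arr
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (3, 3):
        raise ValueError("counts must be a 3x3 marker-by-gene table or a dict")
    return arr


def two_point_estimate(counts, model: Optional[TwoPointModel] = None,
                       grid_step: float = 1e-3) -> TwoPointResult:
    """Maximum-likelihood r between a marker and a gene, with 95% CI.

    ``counts`` is a 3x3 table (marker state rows AA/AB/BB, gene state
    columns) or a {(marker_state, gene_state): n} dict.  The multinomial
    likelihood uses the model's selection-aware expected class
    frequencies; maximisation is a deterministic grid scan refined by
    bounded minimisation, and the interval is the profile-likelihood
    region within a 1.92 log-likelihood drop.
    """
    if model is None:
        model = TwoPointModel()
    arr = _counts_to_array(counts)
    n_total = int(arr.sum())
    if n_total < 1:
        raise EstimationError("no informative individuals in the count table")
    flat = arr.reshape(-1)
    order = [g.states for g in enumerate_genotypes(2)]
    assert len(order) == 9

    def loglik(r: float) -> float:
        p = model.class_probs(r)
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        mask = flat > 0
        if np.any(np.isneginf(logp[mask])):
            return -np.inf
        return float(np.sum(flat[mask] * logp[mask]))

    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    grid[-1] = 0.5
    lls = np.array([loglik(r) for r in grid])
    if np.all(np.isneginf(lls)):
        raise EstimationError("likelihood is degenerate for every r")
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda r: -loglik(r), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-8})
        r_hat, ll_hat = float(res.x), -float(res.fun)
        if lls[i] > ll_hat:  # boundary beat the interior refinement
            r_hat, ll_hat = float(grid[i]), float(lls[i])
    else:
        r_hat, ll_hat = float(grid[i]), float(lls[i])

    def _ci_bound(a: float, b: float, increasing: bool) -> float:
        """Bisect for loglik(r) = ll_hat - drop on a monotone stretch."""
        target = ll_hat - _LR_DROP_95
        fa = loglik(a)
        if fa >= target:
            return a
        for _ in range(60):
            mid = 0.5 * (a + b)
            if loglik(mid) >= target:
                b = mid
            else:
                a = mid
        return b if increasing else a

    low = _ci_bound(0.0, r_hat, increasing=True) if r_hat > 0 else 0.0
    if r_hat < 0.5:
        # mirror: scan from the upper boundary toward r_hat
        target = ll_hat - _LR_DROP_95
        a, b = 0.5, r_hat
        if loglik(a) >= target:
            high = 0.5
        else:
            for _ in range(60):
                mid = 0.5 * (a + b)
                if loglik(mid) >= target:
                    b = mid
                else:
                    a = mid
            high = b
    else:
        high = 0.5
    cm = r_to_cm(r_hat, "kosambi") if r_hat < 0.5 else None
    return TwoPointResult(r_hat, (float(low), float(high)), ll_hat, n_total, cm)


# ------------------------------------------------------------ fine mapping

@dataclass(frozen=True)
class RecombinantCount:
    """Recombinants observed between one marker and the target gene."""

    marker: str
    n_recombinant: int
    n_scored: int

    def __post_init__(self):
        if not 0 <= self.n_recombinant <= self.n_scored:
            raise ValueError("need 0 <= n_recombinant <= n_scored")


@dataclass(frozen=True)
class MappingInterval:
    """Result of fine-mapping interval delimitation."""

    status: str  # 'delimited', 'one_sided', 'cosegregating'
    left: Optional[str]
    right: Optional[str]
    counts: tuple

    def __str__(self):  # pragma: no cover - cosmetic
        if self.status == "cosegregating":
            return "unresolved: all markers cosegregate with the gene"
        return f"gene delimited between {self.left} and {self.right} ({self.status})"


def delimit_interval(counts: Sequence[RecombinantCount]) -> MappingInterval:
    """Narrowest marker pair flanking the gene, from recombinant counts.

    ``counts`` must be ordered by map position.  Markers with zero
    recombinants cosegregate with the gene; the gene is localised at the
    count minimum and the flanking markers are the nearest ones with
    recombinants on each side.  With no cosegregating marker the gene
    sits between the adjacent pair with the smallest combined counts.
    All-zero counts give a 'cosegregating' status rather than an error.
    """
    counts = tuple(counts)
    if not counts:
        raise ValueError("no recombinant counts supplied")
    ns = [c.n_recombinant for c in counts]
    if all(n == 0 for n in ns):
        return MappingInterval("cosegregating", None, None, counts)
    if len(counts) == 1:
        return MappingInterval("one_sided", counts[0].marker, None, counts)
    if 0 in ns:
        first0 = ns.index(0)
        last0 = len(ns) - 1 - ns[::-1].index(0)
        left = next((counts[i].marker for i in range(first0 - 1, -1, -1)
                     if ns[i] > 0), None)
        right = next((counts[i].marker for i in range(last0 + 1, len(ns))
                      if ns[i] > 0), None)
        if left is None or right is None:
            return MappingInterval("one_sided", left, right, counts)
        return MappingInterval("delimited", left, right, counts)
    # no cosegregating marker: gene between the lightest adjacent pair
    sums = [ns[i] + ns[i + 1] for i in range(len(ns) - 1)]
    i = int(np.argmin(sums))
    return MappingInterval("delimited", counts[i].marker, counts[i + 1].marker,
                           counts)


def count_recombinants(marker_states, gene_states, markers: Sequence[str],
                       ) -> list[RecombinantCount]:
    """Per-marker recombinant chromosomes against known gene states.

    ``marker_states`` is an (n_plants x n_markers) array of 0/1/2 codes
    (negative or NaN = missing); ``gene_states`` the per-plant gene
    genotype.  Each plant contributes |marker_state - gene_state|
    recombinant chromosomes, the resolvable lower bound from unphased
    states (a double recombinant in repulsion is invisible).
    """
    m = np.asarray(marker_states, dtype=float)
    g = np.asarray(gene_states, dtype=float).reshape(-1, 1)
    valid = ~(np.isnan(m) | (m < 0) | np.isnan(g) | (g < 0))
    diff = np.abs(m - g)
    out = []
    for j, name in enumerate(markers):
        ok = valid[:, j]
        out.append(RecombinantCount(name, int(diff[ok, j].sum()), int(ok.sum())))
    return out
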