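"""Tests and likelihood fits for segregation and pollen-count data.

Covers the statistical workflow of a gametophytic-incompatibility
study: chi-square goodness of fit of genotype counts to model ratios,
exact tests for transgene-rescue enrichment, likelihood ranking of
candidate sterile-haplotype models (which needs pollen phenotypes to
break the male/female symmetry of genotype data), transgene copy-number
estimation from T1 segregation, and fertility-class calling from
fertile/total grain counts under a beta-binomial observation model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom

from .core import (
    BOTH,
    FEMALE,
    MALE,
    NEUTRAL,
    Genotype,
    Locus,
    RecombinationSpec,
    SelectionModel,
    enumerate_genotypes,
    state_labels,
)
from .errors import EstimationError, ModelViolationError
from .transmission import (
    GenotypeDistribution,
    RescueModel,
    offspring_distribution,
    pollen_fertility,
)


@dataclass(frozen=True)
class CountTable:
    """Observed class counts paired with expected model ratios."""

    labels: tuple
    observed: tuple
    expected_ratio: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "observed", tuple(int(o) for o in self.observed))
        object.__setattr__(self, "expected_ratio", tuple(self.expected_ratio))
        if not (len(self.labels) == len(self.observed) == len(self.expected_ratio)):
            raise ValueError("labels/observed/expected_ratio lengths differ")
        if any(o < 0 for o in self.observed):
            raise ValueError("observed counts must be non-negative")
        if any(r < 0 for r in self.expected_ratio):
            raise ValueError("expected ratios must be non-negative")
        if not any(r > 0 for r in self.expected_ratio):
            raise ValueError("at least one expected ratio must be positive")

    @property
    def n(self) -> int:
        return sum(self.observed)

    def expected_counts(self) -> list[float]:
        total = sum(self.expected_ratio)
        return [self.n * float(r) / float(total) for r in self.expected_ratio]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    method: str
    dropped_classes: tuple = ()
    inputs: Optional[dict] = None

    def __str__(self):  # pragma: no cover - cosmetic
        return (f"{self.method}: statistic={self.statistic:.4g}, "
                f"df={self.df}, p={self.p:.4g}")


def chisq_gof(table: CountTable) -> TestResult:
    """Chi-square goodness of fit of observed counts to expected ratios.

    Classes with an expected ratio of zero are dropped (the statistic is
    undefined there) and the degrees of freedom are the retained class
    count minus one.  An observed count in a zero-expectation class is a
    model violation and raises, carrying the offending class labels.
    """
    if table.n <= 0:
        raise EstimationError("total observed count must be positive")
    expected = table.expected_counts()
    violated = [lab for lab, o, e in zip(table.labels, table.observed, expected)
                if e == 0 and o > 0]
    if violated:
        raise ModelViolationError(
            f"observed counts in zero-expectation classes: {violated}",
            classes=violated)
    dropped = tuple(lab for lab, e in zip(table.labels, expected) if e == 0)
    kept = [(o, e) for o, e in zip(table.observed, expected) if e > 0]
    stat = sum((o - e) ** 2 / e for o, e in kept)
    df = len(kept) - 1
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return TestResult(float(stat), df, p, "chi2_gof", dropped,
                      inputs={"observed": table.observed,
                              "expected": tuple(expected)})


def fisher_exact(table, alternative: str = "greater") -> TestResult:
    """Fisher's exact test on a 2x2 table, computed in log space.

    alternative 'greater'/'less' sums the hypergeometric tail at least
    as extreme in that direction for the top-left cell; 'two-sided' sums
    every table whose point probability does not exceed the observed
    one (the minimum-likelihood convention).  An all-zero table carries
    no signal and returns p = 1 with a warning.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative integers")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n_total = a + b + c + d
    if n_total == 0:
        warnings.warn("all-zero 2x2 table: p set to 1", stacklevel=2)
        return TestResult(float("nan"), 0, 1.0, f"fisher_exact_{alternative}")
    k_col = a + c      # successes in the population
    n_row = a + b      # draws
    support = np.arange(max(0, n_row - (b + d)), min(k_col, n_row) + 1)
    logpmf = hypergeom.logpmf(support, n_total, k_col, n_row)
    obs_logpmf = float(hypergeom.logpmf(a, n_total, k_col, n_row))
    if alternative == "greater":
        sel = support >= a
    elif alternative == "less":
        sel = support <= a
    elif alternative == "two-sided":
        # tables at most as probable as the observed one, with a small
        # relative slack against round-off (same convention as R/scipy)
        sel = logpmf <= obs_logpmf + 1e-7
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    logp = float(logsumexp(logpmf[sel]))
    p = min(math.exp(logp), 1.0)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(odds, 0, p, f"fisher_exact_{alternative}",
                      inputs={"table": ((a, b), (c, d))})


# ----------------------------------------------------- model selection

@dataclass(frozen=True)
class ModelScore:
    name: str
    model: SelectionModel
    log_likelihood: float
    n_params: int = 0

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.name}: logL={self.log_likelihood:.2f}"


def default_candidate_models() -> list[tuple[str, SelectionModel]]:
    """The 13 canonical two-locus candidates.

    Each of the four gamete haplotypes sterile in males, in females, or
    in both sexes, plus the neutral model.  Names use allele letters,
    e.g. 'male B|A' = gametes carrying B at locus 1 and A at locus 2 are
    sterile when male.
    """
    out: list[tuple[str, SelectionModel]] = []
    for h1 in (0, 1):
        for h2 in (0, 1):
            pattern = (h1, h2)
            label = f"{'AB'[h1]}|{'AB'[h2]}"
            for sex in (MALE, FEMALE, BOTH):
                out.append((f"{sex} {label}", SelectionModel.single(pattern, sex)))
    out.append(("neutral", NEUTRAL))
    return out


def _multinomial_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if np.any((probs == 0) & (counts > 0)):
        return -np.inf
    mask = counts > 0
    const = gammaln(counts.sum() + 1) - gammaln(counts + 1).sum()
    return float(const + np.sum(counts[mask] * np.log(probs[mask])))


def _binom_loglik(k: np.ndarray, m: np.ndarray, p: np.ndarray) -> float:
    """Vectorised binomial log-likelihood, exact at p in {0, 1}."""
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    const = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    edge_hi = p == 1.0
    edge_lo = p == 0.0
    mid = ~(edge_hi | edge_lo)
    out[edge_hi] = np.where(k[edge_hi] == m[edge_hi], 0.0, -np.inf)
    out[edge_lo] = np.where(k[edge_lo] == 0.0, 0.0, -np.inf)
    pm = p[mid]
    out[mid] = (const[mid] + k[mid] * np.log(pm)
                + (m[mid] - k[mid]) * np.log1p(-pm))
    return float(out.sum())


def _plants_to_arrays(plants):
    """Accept a DataFrame (genotype letter columns + fertile/total) or
    a sequence of (states, fertile, total) records."""
    try:
        import pandas as pd
    except ImportError:  # pragma: no cover
        pd = None
    if pd is not None and isinstance(plants, pd.DataFrame):
        geno_cols = [c for c in plants.columns if c not in ("fertile", "total")]
        code = {"A": 0, "H": 1, "B": 2}
        states = [tuple(code[str(v).upper()] for v in row)
                  for row in plants[geno_cols].itertuples(index=False)]
        k = plants["fertile"].to_numpy()
        m = plants["total"].to_numpy()
        return states, np.asarray(k, float), np.asarray(m, float)
    states, ks, ms = [], [], []
    for rec in plants:
        s, k, m = rec
        states.append(tuple(int(x) for x in s))
        ks.append(k)
        ms.append(m)
    return states, np.array(ks, float), np.array(ms, float)


def sterility_model_selection(plants, candidates=None,
                              parent: Optional[Genotype] = None,
                              recomb: Optional[RecombinationSpec] = None,
                              ) -> list[ModelScore]:
    """Rank candidate sterile-haplotype models on genotype + pollen data.

    ``plants``: per-plant genotypes with fertile/total pollen counts
    (DataFrame with letter-coded genotype columns plus 'fertile' and
    'total', or (states, fertile, total) records).  ``parent`` is the
    common parent of the selfed family (default: the double
    heterozygote at two unlinked loci).

    Per candidate, the log-likelihood is the multinomial probability of
    the genotype class counts under the candidate's expected offspring
    distribution plus each plant's binomial probability of its fertile
    grain count given its model-implied pollen fertility.  The pollen
    term is what separates male from female variants of the same
    pattern: their genotype distributions are identical.  A candidate
    giving probability zero to anything observed scores -inf and ranks
    last.
    """
    states, k, m = _plants_to_arrays(plants)
    if len(states) == 0:
        raise EstimationError("no plants supplied")
    n_loci = len(states[0])
    if parent is None:
        parent = Genotype((1,) * n_loci)
    if candidates is None:
        candidates = default_candidate_models()
    classes = [g.states for g in enumerate_genotypes(n_loci)]
    index = {s: i for i, s in enumerate(classes)}
    counts = np.zeros(len(classes))
    for s in states:
        counts[index[s]] += 1
    plant_class = np.array([index[s] for s in states])

    scores = []
    for name, model in candidates:
        dist = offspring_distribution(parent, parent, model, recomb)
        probs = np.array([float(p) for p in dist.to_vector()])
        ll = _multinomial_loglik(counts, probs)
        if np.isfinite(ll):
            fert = np.array([float(pollen_fertility(Genotype(s), model, recomb))
                             for s in classes])
            ll += _binom_loglik(k, m, fert[plant_class])
        scores.append(ModelScore(name, model, ll))
    scores.sort(key=lambda s: s.log_likelihood, reverse=True)
    return scores


# --------------------------------------------------- transgene copy number

@dataclass(frozen=True)
class CopyNumberResult:
    c_hat: int
    at_boundary: bool  # c_hat == max_c with the profile still rising
    profile: tuple     # ((c, log_likelihood), ...)
    recombination_attributed: dict  # class label -> count explained by
                                    # marker-gene recombination only

    def __str__(self):  # pragma: no cover - cosmetic
        tag = ">=" if self.at_boundary else "="
        return f"transgene copy number c {tag} {self.c_hat}"


def t1_marker_class_probs(c: int, marker_r: float = 0.0,
                          rescue_sexes=(MALE,)) -> np.ndarray:
    """Expected T1 marker genotype frequencies (AA, AB, BB).

    Selfed transformant heterozygous at the assay marker and the gene,
    in coupling; male gametes carrying the sterile gene allele (B)
    survive with probability q = 1 - (1/2)**c.  ``marker_r`` is the
    marker-gene recombination fraction; with marker_r = 0 and c = 0 the
    BB marker class is impossible.
    """
    loci = (Locus("marker", "chr", 0.0), Locus("gene", "chr", 0.0))
    recomb = RecombinationSpec(loci, (marker_r,))
    t0 = Genotype.from_phase((0, 0), (1, 1))
    selection = SelectionModel.single((None, 1), MALE)
    rescue = RescueModel(c, rescue_sexes) if c > 0 else None
    dist = offspring_distribution(t0, t0, selection, recomb, rescue=rescue)
    marg = dist.marginal(0)
    return np.array([float(marg[(s,)]) for s in (0, 1, 2)])


def estimate_copy_number(t1_counts, max_c: int = 4,
                         marker_r: float = 0.01) -> CopyNumberResult:
    """Integer transgene copy number from T1 marker segregation.

    ``t1_counts``: (AA, AB, BB) counts at the marker linked to the
    rescued gene, or a 3-class CountTable.  The estimate maximises the
    multinomial likelihood over c in {0..max_c}; ties break toward the
    smaller c, and a maximum at max_c with the profile still rising is
    flagged as a boundary ('>=') estimate — the full-rescue limit is
    indistinguishable from large c.

    marker_r models recombination between the assay marker and the gene
    itself (default 0.01): without it a single recombinant plant in the
    class that is impossible at c = 0 would force a spurious c >= 1.
    Counts in classes impossible at the estimated c when marker_r = 0
    are reported as recombination-attributed.
    """
    if isinstance(t1_counts, CountTable):
        counts = np.asarray(t1_counts.observed, dtype=float)
        labels = t1_counts.labels
    else:
        counts = np.asarray(t1_counts, dtype=float)
        labels = ("AA", "AB", "BB")
    if counts.shape != (3,):
        raise ValueError("t1_counts must hold the three marker classes")
    if max_c < 1:
        raise ValueError("max_c must be >= 1")
    profile = []
    for c in range(max_c + 1):
        probs = t1_marker_class_probs(c, marker_r)
        profile.append((c, _multinomial_loglik(counts, probs)))
    lls = np.array([ll for _, ll in profile])
    c_hat = int(np.argmax(lls))  # argmax takes the first (smallest) maximiser
    at_boundary = c_hat == max_c and max_c >= 2 and lls[max_c] > lls[max_c - 1]
    pure = t1_marker_class_probs(c_hat, 0.0)
    attributed = {lab: int(n) for lab, n, p in zip(labels, counts, pure)
                  if p == 0 and n > 0}
    return CopyNumberResult(c_hat, at_boundary, tuple(profile), attributed)


# ----------------------------------------------- fertility classification

@dataclass(frozen=True)
class FertilityCall:
    fertility_class: Optional[float]
    posterior: dict  # class mean -> posterior weight (uniform prior)
    tie: bool
    status: str  # 'ok' or 'unclassifiable'


def _betabinom_logpmf(k: float, m: float, p: float, rho: float) -> float:
    """Beta-binomial with mean p and intra-class correlation rho.

    rho = 0 (or a degenerate mean of 0/1) collapses to the binomial.
    """
    if p in (0.0, 1.0) or rho == 0.0:
        return _binom_loglik(np.array([k]), np.array([m]), np.array([p]))
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    const = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    return float(const + betaln(k + a, m - k + b) - betaln(a, b))


def classify_fertility(fertile: int, total: int,
                       class_means: Sequence[float] = (0.5, 0.75, 1.0),
                       rho: float = 0.01) -> FertilityCall:
    """Assign a pollen count to its most likely fertility class.

    Likelihoods are beta-binomial around each class mean with
    overdispersion rho (binomial at rho = 0); posterior weights assume a
    uniform prior over classes.  Exact likelihood ties break toward the
    lower class and are flagged.  total = 0 is unclassifiable.
    """
    means = sorted(float(c) for c in class_means)
    if len(set(means)) != len(means):
        raise ValueError("class means must be distinct")
    if not 0 <= fertile <= total:
        raise ValueError("need 0 <= fertile <= total")
    if total == 0:
        return FertilityCall(None, {}, False, "unclassifiable")
    lls = np.array([_betabinom_logpmf(fertile, total, p, rho) for p in means])
    if np.all(np.isneginf(lls)):
        return FertilityCall(None, {c: 0.0 for c in means}, False,
                             "unclassifiable")
    weights = np.exp(lls - logsumexp(lls))
    best = int(np.argmax(lls))  # first maximiser = lowest tied class
    tie = bool(np.sum(np.abs(lls - lls[best]) < 1e-9) > 1)
    posterior = {c: float(w) for c, w in zip(means, weights)}
    return FertilityCall(means[best], posterior, tie, "ok")
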