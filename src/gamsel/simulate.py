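"""Seeded population simulator for segregating families.

Generates plant tables with the statistical structure the analysis
assumes: individuals are built gamete by gamete (crossovers as
independent Bernoulli(r) events between adjacent loci; sterile male
gametes rejected with probability penetrance * (1 - rescue q)), and
per-plant pollen counts are drawn beta-binomially around each plant's
model fertility.  A single seed expands into independent substreams
for genotypes, pollen counts and missingness, so adding one stream
never perturbs another and every output is bit-reproducible from
(config, seed).

Defaults mirror the segregating-family design the analysis targets:
selfed progeny of a plant heterozygous at two unlinked incompatibility
loci, ~90 plants scored, ~200 pollen grains evaluated per plant, male
gametes carrying the B|A haplotype sterile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    MALE,
    NEUTRAL,
    STATE_NAMES,
    Genotype,
    Locus,
    RecombinationSpec,
    SelectionModel,
    resolve_phase,
)
from .errors import NoViableGametesError
from .transmission import RescueModel, pollen_fertility, rescued_offspring_distribution


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated selfed (or backcrossed) family."""

    parent: Genotype
    selection: SelectionModel = NEUTRAL
    recomb: Optional[RecombinationSpec] = None
    n_plants: int = 90
    grains_per_plant: int = 200
    rho: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0
    rescue: Optional[RescueModel] = None
    cross: str = "self"  # 'self' or 'backcross'
    recurrent: Optional[Genotype] = None
    recurrent_is_female: bool = False

    def __post_init__(self):
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.cross not in ("self", "backcross"):
            raise ValueError("cross must be 'self' or 'backcross'")
        if self.cross == "backcross" and self.recurrent is None:
            raise ValueError("backcross needs a recurrent parent")

    @classmethod
    def two_locus_incompatibility(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The canonical study design: selfed double heterozygote at two
        unlinked loci, male B|A gametes sterile, 90 plants, 200 grains."""
        cfg = cls(parent=Genotype((1, 1)),
                  selection=SelectionModel.single((1, 0), MALE),
                  recomb=RecombinationSpec.unlinked(2),
                  n_plants=90, grains_per_plant=200, seed=seed)
        return replace(cfg, **overrides) if overrides else cfg


def _sample_gametes(parent: Genotype, recomb: RecombinationSpec, sex: str,
                    selection: SelectionModel, rescue, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """(size x n_loci) array of gamete alleles, after viability rejection."""
    phase = np.array(resolve_phase(parent, recomb), dtype=np.int8)  # (2, L)
    n_loci = phase.shape[1]
    rs = np.array([float(r) for r in recomb.adjacent_r])
    # fail fast when selection leaves nothing to sample
    if float(pollen_fertility(parent, selection, recomb, rescue)) == 0 and sex == MALE:
        raise NoViableGametesError(
            f"no viable male gametes for genotype {parent.to_string()}")
    out = np.empty((size, n_loci), dtype=np.int8)
    filled = 0
    while filled < size:
        batch = max(2 * (size - filled), 32)
        start = rng.integers(0, 2, size=batch)
        if n_loci > 1:
            switches = rng.random((batch, n_loci - 1)) < rs
            path = np.empty((batch, n_loci), dtype=np.int8)
            path[:, 0] = start
            cum = start.astype(np.int8)
            for j in range(1, n_loci):
                cum = cum ^ switches[:, j - 1]
                path[:, j] = cum
        else:
            path = start.reshape(-1, 1).astype(np.int8)
        gametes = phase[path, np.arange(n_loci)]
        viability = np.ones(batch)
        for rule in selection.rules:
            if not rule.applies_to(sex):
                continue
            match = np.ones(batch, dtype=bool)
            for j, p in enumerate(rule.pattern):
                if p is not None:
                    match &= gametes[:, j] == p
            pen = float(rule.penetrance)
            if rescue is not None and rescue.covers(sex):
                pen *= 1.0 - float(rescue.q)
            viability[match] *= 1.0 - pen
        accept = rng.random(batch) < viability
        kept = gametes[accept]
        take = min(len(kept), size - filled)
        out[filled:filled + take] = kept[:take]
        filled += take
    return out


def _pollen_counts(fertility: np.ndarray, grains: int, rho: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Beta-binomial fertile-grain counts around per-plant fertility."""
    fertility = np.clip(fertility, 0.0, 1.0)  # guard float round-off
    n = len(fertility)
    k = np.empty(n, dtype=np.int64)
    degenerate = (fertility <= 0) | (fertility >= 1) | (rho == 0)
    k[degenerate] = rng.binomial(grains, fertility[degenerate])
    idx = ~degenerate
    if idx.any():
        p = fertility[idx]
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        k[idx] = rng.binomial(grains, rng.beta(a, b))
    return k


def simulate_population(cfg: SimConfig) -> pd.DataFrame:
    """Simulate one family: marker genotypes plus pollen counts.

    Returns a DataFrame with one letter-coded column (A/H/B, NA when
    missing) per locus, plus 'fertile' and 'total' grain counts.
    """
    recomb = cfg.recomb or RecombinationSpec.unlinked(cfg.parent.n_loci)
    rng_geno, rng_pollen, rng_missing = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(cfg.seed).spawn(3))
    n = cfg.n_plants
    if cfg.cross == "self":
        mother = father = cfg.parent
    else:
        mother, father = ((cfg.recurrent, cfg.parent)
                          if cfg.recurrent_is_female
                          else (cfg.parent, cfg.recurrent))
    eggs = _sample_gametes(mother, recomb, FEMALE, cfg.selection, cfg.rescue,
                           n, rng_geno)
    sperm = _sample_gametes(father, recomb, MALE, cfg.selection, cfg.rescue,
                            n, rng_geno)
    states = eggs + sperm

    # per-plant model fertility, phase-aware, cached per phased genotype
    fert_cache: dict = {}
    fert = np.empty(n)
    for i in range(n):
        key = (tuple(eggs[i]), tuple(sperm[i]))
        if key not in fert_cache:
            plant = Genotype.from_phase(*key)
            fert_cache[key] = float(pollen_fertility(plant, cfg.selection,
                                                     recomb, cfg.rescue))
        fert[i] = fert_cache[key]
    fertile = _pollen_counts(fert, cfg.grains_per_plant, cfg.rho, rng_pollen)

    names = [loc.name for loc in recomb.loci]
    data = {name: [STATE_NAMES[s] for s in states[:, j]]
            for j, name in enumerate(names)}
    table = pd.DataFrame(data)
    if cfg.missing_rate > 0:
        mask = rng_missing.random(states.shape) < cfg.missing_rate
        for j, name in enumerate(names):
            table.loc[mask[:, j], name] = "NA"
    table["fertile"] = fertile
    table["total"] = cfg.grains_per_plant
    table.attrs["seed"] = cfg.seed
    return table


def simulate_mapping_population(markers: Sequence[Locus], gene: Locus,
                                n_plants: int, seed: int = 0,
                                grains_per_plant: int = 200,
                                rho: float = 0.01,
                                map_function: str = "kosambi",
                                selection: Optional[SelectionModel] = None,
                                ) -> pd.DataFrame:
    """Fine-mapping family: selfed semisterile plant het across a segment.

    ``markers`` and ``gene`` must carry cM positions on one chromosome
    with the gene strictly inside the marker span.  The default
    selection sterilises male gametes carrying the donor (B) allele at
    the gene, the single-locus semisterile situation.  The output keeps
    the true gene genotype in a column named after the gene (the
    simulator records truth; the analysis re-infers it from fertility).
    """
    loci = sorted([*markers, gene], key=lambda l: l.position)
    positions = [l.position for l in loci]
    gi = loci.index(gene)
    if gi in (0, len(loci) - 1):
        raise ValueError("gene must lie strictly between the outermost markers")
    if len(set(l.chromosome for l in loci)) != 1:
        raise ValueError("mapping population assumes one chromosome")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("marker/gene positions must be strictly increasing")
    recomb = RecombinationSpec.from_loci(loci, map_function)
    n_loci = len(loci)
    parent = Genotype.from_phase((0,) * n_loci, (1,) * n_loci)  # coupling
    if selection is None:
        pattern = [None] * n_loci
        pattern[gi] = 1
        selection = SelectionModel.single(tuple(pattern), MALE)
    cfg = SimConfig(parent=parent, selection=selection, recomb=recomb,
                    n_plants=n_plants, grains_per_plant=grains_per_plant,
                    rho=rho, seed=seed)
    return simulate_population(cfg)


def simulate_t1_family(rescue: RescueModel, n: int, seed: int = 0,
                       marker_r: float = 0.0) -> np.ndarray:
    """(AA, AB, BB) marker counts for one T1 family of size n.

    Multinomial draw from the rescued selfing distribution of a
    single-locus semisterile transformant, scored at a marker linked to
    the gene at recombination fraction ``marker_r``.
    """
    from .stats import t1_marker_class_probs

    probs = t1_marker_class_probs(rescue.copies, marker_r, rescue.sexes)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return rng.multinomial(n, probs)
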