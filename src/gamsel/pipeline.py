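"""Config-driven analysis pipeline producing delimited reports.

A run configuration (YAML or JSON) declares any of the stages below;
each produces a delimited table in the output directory and a block in
a human-readable summary.  Reports embed the package version, a hash
of the configuration and the seed, so identical inputs give identical
reports.

Stages: 'expect' (expected segregation and fertility classes), 'gof'
(chi-square goodness of fit), 'fisher' (exact tests), 'fit'
(sterile-haplotype model ranking), 'copies' (transgene copy number),
'simulate' (write a simulated plant table).
"""

from __future__ import annotations

import hashlib
import json
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .core import (
    Genotype,
    RecombinationSpec,
    SelectionModel,
    SelectionRule,
    state_labels,
)
from .errors import GamselError
from .io import load_config, read_genotype_table, write_genotype_table
from .simulate import SimConfig, simulate_population
from .stats import (
    CountTable,
    chisq_gof,
    estimate_copy_number,
    fisher_exact,
    sterility_model_selection,
)
from .transmission import (
    RescueModel,
    fertility_class_distribution,
    offspring_distribution,
)

ALLELE_FROM_CODE = {"A": 0, "B": 1, "*": None, "N": None}


def parse_pattern(text) -> tuple:
    """Haplotype pattern from text like 'B|A' or 'B|*' (A/B/* per locus)."""
    if isinstance(text, (list, tuple)):
        return tuple(None if p in (None, "*") else int(p) for p in text)
    parts = [p.strip().upper() for p in str(text).split("|")]
    try:
        return tuple(ALLELE_FROM_CODE[p] for p in parts)
    except KeyError as exc:
        raise GamselError(f"bad pattern code {exc.args[0]!r} in {text!r}") from None


def parse_selection(block) -> SelectionModel:
    """SelectionModel from a config block: list of {pattern, sex, penetrance}."""
    if not block:
        return SelectionModel()
    rules = []
    for rule in block.get("rules", block) if isinstance(block, dict) else block:
        # exact rational penetrance keeps config-driven expectations exact
        penetrance = Fraction(str(rule.get("penetrance", 1)))
        rules.append(SelectionRule(parse_pattern(rule["pattern"]),
                                   rule.get("sex", "male"),
                                   penetrance))
    return SelectionModel(tuple(rules))


def _config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _fmt(x) -> str:
    if isinstance(x, Fraction):
        return str(x)
    return f"{float(x):.6g}"


def run_pipeline(config: Union[dict, str, Path], outdir) -> Path:
    """Execute every stage declared in ``config``; return the summary path.

    Any stage error aborts with a stage-tagged GamselError.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    selection = parse_selection(config.get("selection"))
    lines = [f"gamsel {__version__}",
             f"config_hash {_config_hash(config)}",
             f"seed {seed}", ""]

    def stage(name):
        block = config.get(name)
        return block if block else None

    try:
        block = stage("expect")
        if block:
            parent = Genotype.from_string(block.get("parent", "HH"))
            recomb = RecombinationSpec.unlinked(parent.n_loci)
            rescue = None
            if block.get("rescue_copies") is not None:
                rescue = RescueModel(int(block["rescue_copies"]))
            dist = offspring_distribution(parent, parent, selection, recomb,
                                          rescue=rescue)
            labels = state_labels(parent.n_loci)
            vec = dist.to_vector()
            pd.DataFrame({"class": labels,
                          "probability": [float(p) for p in vec]}
                         ).to_csv(outdir / "expected_segregation.csv", index=False)
            fert = fertility_class_distribution(dist, selection, recomb, rescue)
            fert_rows = sorted(((float(f), float(p)) for f, p in fert.items()))
            pd.DataFrame(fert_rows, columns=["fertility", "probability"]
                         ).to_csv(outdir / "fertility_classes.csv", index=False)
            lines.append("[expect] selfing " + parent.to_string())
            lines += [f"  {lab}: {_fmt(p)}" for lab, p in zip(labels, vec)]
            lines.append("  fertility classes: " + ", ".join(
                f"{f:.0%}: {_fmt(p)}" for f, p in fert_rows))
            lines.append("")

        block = stage("gof")
        if block:
            table = CountTable(tuple(block["labels"]),
                               tuple(block["observed"]),
                               tuple(block["expected_ratio"]))
            res = chisq_gof(table)
            pd.DataFrame({"class": table.labels,
                          "observed": table.observed,
                          "expected": table.expected_counts()}
                         ).to_csv(outdir / "gof_classes.csv", index=False)
            lines.append(f"[gof] chi2={res.statistic:.4g} df={res.df} "
                         f"P={res.p:.4g}")
            if res.dropped_classes:
                lines.append(f"  dropped zero-expectation classes: "
                             f"{', '.join(res.dropped_classes)}")
            lines.append("")

        block = stage("fisher")
        if block:
            rows = []
            for entry in block.get("tables", []):
                res = fisher_exact(entry["table"],
                                   entry.get("alternative", "two-sided"))
                rows.append({"name": entry.get("name", ""),
                             "odds_ratio": res.statistic, "p": res.p})
            pd.DataFrame(rows).to_csv(outdir / "fisher.csv", index=False)
            lines.append("[fisher]")
            lines += [f"  {r['name']}: P={r['p']:.2g}" for r in rows]
            lines.append("")

        block = stage("fit")
        if block:
            plants = read_genotype_table(block["plants"])
            scores = sterility_model_selection(plants)
            pd.DataFrame([{"model": s.name, "log_likelihood": s.log_likelihood}
                          for s in scores]
                         ).to_csv(outdir / "model_selection.csv", index=False)
            lines.append(f"[fit] best model: {scores[0].name} "
                         f"(logL {scores[0].log_likelihood:.2f})")
            lines.append("")

        block = stage("copies")
        if block:
            res = estimate_copy_number(block["counts"],
                                       max_c=int(block.get("max_c", 4)),
                                       marker_r=float(block.get("marker_r", 0.01)))
            pd.DataFrame(res.profile, columns=["copies", "log_likelihood"]
                         ).to_csv(outdir / "copy_number.csv", index=False)
            tag = ">=" if res.at_boundary else "="
            lines.append(f"[copies] c {tag} {res.c_hat}")
            if res.recombination_attributed:
                lines.append(f"  recombination-attributed counts: "
                             f"{res.recombination_attributed}")
            lines.append("")

        block = stage("simulate")
        if block:
            cfg = SimConfig.two_locus_incompatibility(
                seed=seed,
                n_plants=int(block.get("n_plants", 90)),
                grains_per_plant=int(block.get("grains_per_plant", 200)),
                rho=float(block.get("rho", 0.01)),
                missing_rate=float(block.get("missing_rate", 0.0)))
            table = simulate_population(cfg)
            write_genotype_table(table, outdir / "simulated_plants.csv",
                                 seed=seed)
            lines.append(f"[simulate] wrote {len(table)} plants "
                         f"(seed {seed})")
            lines.append("")
    except GamselError:
        raise
    except Exception as exc:  # tag unexpected stage failures
        raise GamselError(f"pipeline stage failed: {exc}") from exc

    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines).rstrip() + "\n")
    return summary
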