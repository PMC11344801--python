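"""Synthetic toy models, expression profiles and dependency datasets.

The generator builds genome-scale-model miniatures with exactly solvable
flux optima so every pipeline stage can be tested against an analytic
oracle.  Topology: parallel linear chains

    exchange -> M0 -> M1 -> ... -> X  (one chain per nutrient)

all feeding a shared biomass precursor ``X``; optional shared mandatory
steps (carrying planted essential genes) sit between ``X`` and the biomass
drain.  The FBA optimum is the sum over chains of the minimum capacity
along each chain — the min-of-capacities bottleneck rule — so planted
bottlenecks, essential genes and differential effects are all recoverable
by construction.  GPR rules are assigned round-robin from the requested
categories.  All randomness flows through one seeded generator; fixtures
are byte-stable across runs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import cobra
import numpy as np
import pandas as pd
import yaml
from cobra import Metabolite, Model, Reaction

from .differential import GroupFluxTable
from .integration import ExpressionProfile
from .media import MediaDefinition
from .model_io import DEFAULT_BOUND
from .validation import DependencyDataset

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_toy_gem",
    "make_expression",
    "make_dependency",
    "make_group_fluxes",
    "chain_media",
    "write_fixture_bundle",
]

_CATEGORY_GENE_COST = {"one-gene": 1, "or": 2, "and": 2, "andor": 3, "none": 0}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one generated toy model."""

    seed: int = 0
    n_linear_chains: int = 2
    chain_length: int = 3
    uptake_capacity: float = 5.0
    internal_capacity: float = 10.0
    include_rule_categories: tuple[str, ...] = ("one-gene", "or", "and", "andor", "none")
    bottleneck: tuple[str, float] | None = None
    planted_essentials: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_linear_chains < 1 or self.chain_length < 1:
            raise ValueError("need at least one chain of length one")
        if self.uptake_capacity <= 0 or self.internal_capacity <= 0:
            raise ValueError("capacities must be positive")
        bad = set(self.include_rule_categories) - set(_CATEGORY_GENE_COST)
        if bad:
            raise ValueError(f"unknown rule categories: {sorted(bad)}")
        if self.bottleneck is not None and self.bottleneck[1] <= 0:
            raise ValueError("bottleneck capacity must be positive")


@dataclass
class GroundTruth:
    """What the generator knows the model must do."""

    optimum: float
    chain_capacities: dict[str, float]  # chain id -> min capacity along it
    essential_reactions: list[str]
    essential_genes: list[str]
    exchange_ids: list[str]
    biomass_id: str
    reactions_by_category: dict[str, list[str]] = field(default_factory=dict)
    genes_by_reaction: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _rule_text(category: str, genes: list[str]) -> str:
    if category == "none":
        return ""
    if category == "one-gene":
        return genes[0]
    if category == "or":
        return f"{genes[0]} or {genes[1]}"
    if category == "and":
        return f"{genes[0]} and {genes[1]}"
    return f"({genes[0]} and {genes[1]}) or {genes[2]}"


def make_toy_gem(spec: FixtureSpec) -> tuple[Model, GroundTruth]:
    """Build the toy model and its analytic ground truth."""
    model = Model(f"toy_gem_seed{spec.seed}")
    gene_counter = 0
    categories = list(spec.include_rule_categories)
    truth = GroundTruth(
        optimum=0.0,
        chain_capacities={},
        essential_reactions=[],
        essential_genes=list(spec.planted_essentials),
        exchange_ids=[],
        biomass_id="BIOMASS",
    )
    x = Metabolite("X", compartment="c")
    reactions: list[Reaction] = []
    cat_idx = 0
    for chain in range(1, spec.n_linear_chains + 1):
        mets = [
            Metabolite(f"M{chain}_{step}", compartment="c")
            for step in range(spec.chain_length)
        ] + [x]
        ex = Reaction(f"EX_M{chain}_0")
        ex.add_metabolites({mets[0]: -1})
        ex.bounds = (-spec.uptake_capacity, DEFAULT_BOUND)
        reactions.append(ex)
        truth.exchange_ids.append(ex.id)
        capacities = [spec.uptake_capacity]
        for step in range(spec.chain_length):
            rxn = Reaction(f"R{chain}_{step + 1}")
            rxn.add_metabolites({mets[step]: -1, mets[step + 1]: 1})
            cap = spec.internal_capacity
            rxn.bounds = (0.0, cap)
            category = categories[cat_idx % len(categories)]
            cat_idx += 1
            n_genes = _CATEGORY_GENE_COST[category]
            genes = [f"G{gene_counter + i + 1}" for i in range(n_genes)]
            gene_counter += n_genes
            rxn.gene_reaction_rule = _rule_text(category, genes)
            truth.reactions_by_category.setdefault(category, []).append(rxn.id)
            truth.genes_by_reaction[rxn.id] = genes
            reactions.append(rxn)
            capacities.append(cap)
        truth.chain_capacities[f"chain{chain}"] = min(capacities)

    # shared mandatory steps carrying planted essential genes
    upstream = x
    for i, gene in enumerate(spec.planted_essentials, start=1):
        downstream = Metabolite(f"XE{i}", compartment="c")
        rxn = Reaction(f"RE{i}")
        rxn.add_metabolites({upstream: -1, downstream: 1})
        rxn.bounds = (0.0, DEFAULT_BOUND)
        rxn.gene_reaction_rule = gene
        truth.reactions_by_category.setdefault("one-gene", []).append(rxn.id)
        truth.genes_by_reaction[rxn.id] = [gene]
        truth.essential_reactions.append(rxn.id)
        reactions.append(rxn)
        upstream = downstream

    biomass = Reaction("BIOMASS")
    biomass.add_metabolites({upstream: -1})
    biomass.bounds = (0.0, DEFAULT_BOUND)
    reactions.append(biomass)
    truth.essential_reactions.append("BIOMASS")

    model.add_reactions(reactions)
    model.objective = "BIOMASS"

    if spec.bottleneck is not None:
        rid, cap = spec.bottleneck
        if rid not in model.reactions:
            raise ValueError(f"bottleneck reaction {rid!r} not in generated model")
        reaction = model.reactions.get_by_id(rid)
        if reaction.id.startswith("EX_"):
            reaction.lower_bound = -cap
        else:
            reaction.upper_bound = cap
        match = re.match(r"(?:EX_M|R)(\d+)_", rid)
        key = f"chain{match.group(1)}" if match else ""
        if key in truth.chain_capacities:
            truth.chain_capacities[key] = min(truth.chain_capacities[key], cap)

    missing = set(spec.planted_essentials) - {g.id for g in model.genes}
    if missing:
        raise ValueError(f"planted essential genes missing from model: {missing}")
    truth.optimum = sum(truth.chain_capacities.values())
    return model, truth


def chain_media(model: Model, truth: GroundTruth, name: str = "toy-medium") -> MediaDefinition:
    """A medium opening every chain uptake at the model's current bounds."""
    entries = {
        rid: tuple(model.reactions.get_by_id(rid).bounds) for rid in truth.exchange_ids
    }
    return MediaDefinition(name=name, entries=entries)


def make_expression(
    model: Model,
    seed: int,
    high_genes: tuple[str, ...] = (),
    low_genes: tuple[str, ...] = (),
    base_level: float = 8.0,
    low_value: float = 0.5,
    high_value: float | None = None,
    jitter_sd: float = 0.05,
    sample_id: str = "sample",
) -> ExpressionProfile:
    """Deterministic expression profile: low genes bind their reactions,
    high genes exceed demand, the rest sit at base_level with small jitter."""
    overlap = set(high_genes) & set(low_genes)
    if overlap:
        raise ValueError(f"genes in both high and low sets: {sorted(overlap)}")
    unknown = (set(high_genes) | set(low_genes)) - {g.id for g in model.genes}
    if unknown:
        raise ValueError(f"genes not in model: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    if high_value is None:
        high_value = 2.0 * base_level
    values: dict[str, float] = {}
    for gene in model.genes:
        jitter = float(rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else 0.0
        values[gene.id] = max(base_level + jitter, 0.0)
    for gene in high_genes:
        values[gene] = high_value
    for gene in low_genes:
        values[gene] = low_value
    return ExpressionProfile(sample_id=sample_id, values=values)


def make_dependency(
    model: Model,
    seed: int,
    essential_genes: tuple[str, ...] = (),
    noise_sd: float = 0.05,
    group_lines: dict[str, list[str]] | None = None,
    group_essentials: dict[str, tuple[str, ...]] | None = None,
) -> DependencyDataset:
    """Dependency scores: essentials ~ clipped N(0.9, sd), others
    ~ clipped N(0.1, sd), truncated to [0, 1]; two groups of lines by
    default, with optional group-specific essential sets."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    unknown = set(essential_genes) - {g.id for g in model.genes}
    if unknown:
        raise ValueError(f"essential genes not in model: {sorted(unknown)}")
    if group_lines is None:
        group_lines = {
            "low": ["low1", "low2", "low3"],
            "high": ["high1", "high2", "high3"],
        }
    group_essentials = group_essentials or {}
    rng = np.random.default_rng(seed)
    genes = [g.id for g in model.genes]
    rows = {}
    for label, lines in group_lines.items():
        essentials = set(essential_genes) | set(group_essentials.get(label, ()))
        for line in lines:
            scores = []
            for gene in genes:
                centre = 0.9 if gene in essentials else 0.1
                scores.append(float(np.clip(rng.normal(centre, noise_sd), 0.0, 1.0)))
            rows[line] = scores
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
    return DependencyDataset(scores=frame, groups={k: list(v) for k, v in group_lines.items()})


def make_group_fluxes(
    model: Model,
    seed: int,
    planted: dict[str, float],
    n_per_group: int = 3,
    base_flux: float = 2.0,
    noise_sd: float = 0.0,
) -> tuple[GroupFluxTable, GroupFluxTable]:
    """Two group flux tables with planted per-reaction effects.

    ``planted`` maps reaction id -> multiplicative effect on the low group
    (e.g. 2.0 doubles the low-group flux; negative values flip direction).
    All other reactions carry identical base flux in both groups, so with
    zero noise exactly the planted reactions satisfy the difference
    criteria.
    """
    unknown = set(planted) - {r.id for r in model.reactions}
    if unknown:
        raise ValueError(f"planted reactions not in model: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rids = [r.id for r in model.reactions]

    def sample_column() -> np.ndarray:
        col = np.full(len(rids), base_flux)
        if noise_sd > 0:
            col = col + rng.normal(0.0, noise_sd, size=len(rids))
        return col

    low_cols, high_cols = {}, {}
    for i in range(n_per_group):
        low = sample_column()
        high = sample_column()
        for rid, effect in planted.items():
            low[rids.index(rid)] = base_flux * effect
        low_cols[f"low{i + 1}"] = pd.Series(low, index=rids)
        high_cols[f"high{i + 1}"] = pd.Series(high, index=rids)
    return (
        GroupFluxTable.from_solutions("low", low_cols),
        GroupFluxTable.from_solutions("high", high_cols),
    )


def write_fixture_bundle(directory: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    """Write a complete fixture bundle (SBML model, expression TSV, media
    YAML, thresholds YAML, dependency CSV, ground-truth JSON) into a
    directory and return the paths."""
    from .model_io import write_model  # local import avoids cycle at module load

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model, truth = make_toy_gem(spec)
    paths = {
        "model": directory / "model.xml",
        "expression": directory / "expression.tsv",
        "media": directory / "media.yaml",
        "thresholds": directory / "thresholds.yaml",
        "dependency": directory / "dependency.csv",
        "ground_truth": directory / "ground_truth.json",
    }
    write_model(model, paths["model"])

    profile = make_expression(model, seed=spec.seed, sample_id="S1")
    pd.DataFrame({"S1": pd.Series(profile.values)}).rename_axis("gene").to_csv(
        paths["expression"], sep="\t"
    )

    media = chain_media(model, truth)
    paths["media"].write_text(
        yaml.safe_dump(
            {"name": media.name, "entries": {k: list(v) for k, v in media.entries.items()}}
        )
    )
    # threshold at half the analytic optimum: comfortably reachable
    paths["thresholds"].write_text(
        yaml.safe_dump({"S1": float(2.0 / max(truth.optimum, 1e-9))})
    )
    dependency = make_dependency(model, seed=spec.seed, essential_genes=spec.planted_essentials)
    dependency.scores.rename_axis("cell_line").to_csv(paths["dependency"])
    paths["ground_truth"].write_text(json.dumps(truth.to_dict(), indent=2))
    return paths
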