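"""Flux balance analysis and in-silico single-gene knockout screening.

FBA maximises the objective (biomass) flux subject to steady-state mass
balance S·v = 0 and the reaction bounds.  Plain FBA admits alternate
optimal flux vectors; where the flux *vector* (rather than just the
optimum) feeds a downstream comparison, parsimonious FBA — a secondary
minimisation of total absolute flux at the fixed optimum — is the default.

A gene knockout disables every reaction whose GPR boolean expression
evaluates false with that gene set false and all others true, and reports
the ratio of the knocked-out optimum to the unperturbed optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import pandas as pd
from cobra.flux_analysis import pfba

from .model_io import objective_reaction_id, reaction_rule

__all__ = [
    "FluxSolution",
    "KnockoutResult",
    "optimize",
    "disabled_reactions",
    "gene_knockout",
    "knockout_screen",
]

_OBJ_TOL = 1e-9


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: pd.Series  # reaction id -> flux
    status: str  # optimal | infeasible | unbounded | ...
    parsimonious: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class KnockoutResult:
    gene: str
    growth_ratio: float
    disabled_reactions: list[str] = field(default_factory=list)


def optimize(model: cobra.Model, parsimonious: bool = False) -> FluxSolution:
    """Solve the FBA LP; infeasible/unbounded outcomes are returned as a
    status, not raised."""
    try:
        if parsimonious:
            solution = pfba(model)
            # pfba's objective is the flux-sum; report the biomass flux.
            objective = float(solution.fluxes[objective_reaction_id(model)])
        else:
            solution = model.optimize()
            objective = solution.objective_value
    except Exception:
        return FluxSolution(
            objective_value=float("nan"),
            fluxes=pd.Series(dtype=float),
            status="infeasible",
            parsimonious=parsimonious,
        )
    status = solution.status
    if status != "optimal":
        return FluxSolution(
            objective_value=float("nan"),
            fluxes=pd.Series(dtype=float),
            status=status,
            parsimonious=parsimonious,
        )
    return FluxSolution(
        objective_value=float(objective),
        fluxes=solution.fluxes.copy(),
        status=status,
        parsimonious=parsimonious,
    )


def slim_optimum(model: cobra.Model) -> float:
    """Objective value only; 0.0 when the LP is infeasible."""
    value = model.slim_optimize(error_value=float("nan"))
    return 0.0 if value != value else float(value)


def disabled_reactions(model: cobra.Model, gene: str) -> list[str]:
    """Reactions whose GPR evaluates false when ``gene`` is knocked out."""
    states = {gene: False}
    out: list[str] = []
    for reaction in model.reactions:
        rule = reaction_rule(reaction)
        if gene in rule.genes and not rule.evaluate(states):
            out.append(reaction.id)
    return out


def gene_knockout(
    model: cobra.Model, gene: str, baseline: float | None = None
) -> KnockoutResult:
    """Knock out one gene and report KO optimum / baseline optimum.

    The model is restored afterwards.  A baseline of 0 with a KO optimum
    of 0 yields a ratio of 1 (no capability was lost).
    """
    if gene not in {g.id for g in model.genes}:
        raise KeyError(f"gene {gene!r} not in model")
    if baseline is None:
        baseline = slim_optimum(model)
    hit = disabled_reactions(model, gene)
    with model:
        for rid in hit:
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        ko_optimum = slim_optimum(model)
    if baseline <= _OBJ_TOL:
        ratio = 1.0 if ko_optimum <= _OBJ_TOL else ko_optimum / max(baseline, _OBJ_TOL)
    else:
        ratio = ko_optimum / baseline
    ratio = min(max(ratio, 0.0), 1.0)  # clip LP noise
    return KnockoutResult(gene=gene, growth_ratio=ratio, disabled_reactions=hit)


def knockout_screen(
    model: cobra.Model, genes: list[str] | None = None
) -> list[KnockoutResult]:
    """Single-gene knockouts for every gene (or a subset), each computed
    independently against the same baseline, in model gene order."""
    order = [g.id for g in model.genes]
    if genes is not None:
        wanted = set(genes)
        unknown = wanted - set(order)
        if unknown:
            raise KeyError(f"genes not in model: {sorted(unknown)}")
        order = [g for g in order if g in wanted]
    baseline = slim_optimum(model)
    return [gene_knockout(model, g, baseline=baseline) for g in order]
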