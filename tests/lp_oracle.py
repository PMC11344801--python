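"""Independent LP oracle for the test suite.

Builds the flux balance LP directly from a cobra model's stoichiometry and
solves it with scipy's HiGHS-backed linprog — a solver stack disjoint from
the optlang/GLPK path the package uses — so FBA optima and the sequential
integration replay can be checked against an independent implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from fluxcap.model_io import objective_reaction_id


def fba_optimum(model) -> float:
    """Maximise the objective reaction flux subject to S v = 0 and bounds."""
    reactions = list(model.reactions)
    metabolites = list(model.metabolites)
    met_index = {m.id: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(reactions)))
    bounds = []
    for j, reaction in enumerate(reactions):
        for met, coeff in reaction.metabolites.items():
            S[met_index[met.id], j] = coeff
        bounds.append(reaction.bounds)
    c = np.zeros(len(reactions))
    obj = objective_reaction_id(model)
    c[[r.id for r in reactions].index(obj)] = -1.0  # linprog minimises
    result = linprog(c, A_eq=S, b_eq=np.zeros(len(metabolites)), bounds=bounds,
                     method="highs")
    if not result.success:
        return 0.0
    return -result.fun


def _classify(rule_text: str) -> str:
    text = f" {rule_text.lower()} "
    has_and = " and " in text
    has_or = " or " in text
    if not rule_text.strip():
        return "none"
    if has_and and has_or:
        return "andor"
    if has_or:
        return "or"
    if has_and:
        return "and"
    return "one-gene"


def _flat_genes(rule_text: str) -> list[str]:
    out = []
    for token in rule_text.replace("(", " ").replace(")", " ").split():
        if token.lower() not in ("and", "or") and token not in out:
            out.append(token)
    return out


def replay_integration(model, expression: dict, growth_min: float,
                       media_locked: frozenset, essential_fraction: float = 0.01):
    """Step-by-step brute-force replay of the sequential integration loop.

    Works on a copy of the model, solving every decision with the scipy LP.
    Returns (reopened ids, final optimum, dispositions).
    """
    work = model.copy()
    baseline = fba_optimum(work)
    floor = min(growth_min, baseline)
    reopened, dispositions = [], {}
    current = baseline
    for reaction in work.reactions:
        rid = reaction.id
        if rid in media_locked:
            dispositions[rid] = "media_locked"
            continue
        saved = reaction.bounds
        reaction.bounds = (0.0, 0.0)
        ko = fba_optimum(work)
        reaction.bounds = saved
        if ko < essential_fraction * current - 1e-9:
            dispositions[rid] = "essential_locked"
            continue
        category = _classify(reaction.gene_reaction_rule)
        if category == "andor":
            dispositions[rid] = "andor_skipped"
            continue
        genes = _flat_genes(reaction.gene_reaction_rule)
        if category == "none" or any(g not in expression for g in genes):
            dispositions[rid] = "genes_missing"
            continue
        values = [expression[g] for g in genes]
        if category == "or":
            magnitude = sum(values)
        elif category == "and":
            magnitude = min(values)
        else:
            magnitude = values[0]
        lower = -magnitude if reaction.lower_bound < 0 else 0.0
        reaction.bounds = (lower, magnitude)
        candidate = fba_optimum(work)
        if candidate < floor - 1e-9:
            reaction.bounds = saved
            dispositions[rid] = "reopened"
            reopened.append(rid)
        else:
            dispositions[rid] = "constrained"
            current = candidate
    return reopened, fba_optimum(work), dispositions
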