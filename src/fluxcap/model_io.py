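"""Reading, writing and summarising genome-scale metabolic models.

Models are held as :class:`cobra.Model` objects read from SBML Level 3 with
the FBC extension; reaction iteration order is document order everywhere
downstream (the integration loop is order-sensitive).  This module adds the
GPR classification layer: every reaction's gene-protein-reaction rule is
parsed into a :class:`~fluxcap.gpr.GPRRule` and the per-category census a
genome-scale reconstruction is typically described by (one-gene / 'or' /
'and' / 'andor' counts, fraction annotated) is computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import cobra
import cobra.io
from cobra.util.solver import linear_reaction_coefficients

from .gpr import GPRRule, parse_gpr

__all__ = [
    "DEFAULT_BOUND",
    "ModelIOError",
    "RuleCensus",
    "read_model",
    "write_model",
    "objective_reaction_id",
    "is_exchange",
    "exchange_ids",
    "reaction_rule",
    "summarize_rules",
]

#: Default excess reaction rate limit, mmol/gDW/h.
DEFAULT_BOUND = 1000.0


class ModelIOError(ValueError):
    """Raised for unreadable models or models without a usable objective."""


@dataclass(frozen=True)
class RuleCensus:
    """Counts of reactions by GPR category plus the annotated fraction."""

    n_reactions: int
    n_genes: int
    n_annotated: int
    n_one_gene: int
    n_or: int
    n_and: int
    n_andor: int
    fraction_annotated: float

    def to_dict(self) -> dict:
        return asdict(self)

    def table(self) -> str:
        rows = [
            ("reactions", self.n_reactions),
            ("unique genes", self.n_genes),
            ("annotated reactions", self.n_annotated),
            ("  one-gene rules", self.n_one_gene),
            ("  'or' rules (isoenzymes)", self.n_or),
            ("  'and' rules (subunits)", self.n_and),
            ("  'andor' rules (mixed)", self.n_andor),
        ]
        width = max(len(label) for label, _ in rows)
        lines = [f"{label:<{width}}  {count:>7d}" for label, count in rows]
        lines.append(
            f"{'fraction annotated':<{width}}  {self.fraction_annotated:>7.3f}"
        )
        return "\n".join(lines)


def read_model(path: str | Path) -> cobra.Model:
    """Read an SBML Level 3 + FBC model.

    Reaction order follows document order.  Raises :class:`ModelIOError`
    if the file cannot be parsed or the model declares no objective
    reaction (a biomass objective is required for every downstream step).
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file not found: {path}")
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of exception types
        raise ModelIOError(f"could not parse SBML model {path}: {exc}") from exc
    objective_reaction_id(model)  # validates an objective is present
    return model


def write_model(model: cobra.Model, path: str | Path) -> None:
    """Write the model back to SBML Level 3 + FBC."""
    cobra.io.write_sbml_model(model, str(path))


def objective_reaction_id(model: cobra.Model) -> str:
    """Id of the (single) objective reaction, typically biomass."""
    coeffs = linear_reaction_coefficients(model)
    if not coeffs:
        raise ModelIOError(f"model {model.id!r} declares no objective reaction")
    return next(iter(coeffs)).id


def is_exchange(reaction: cobra.Reaction, objective_id: str | None = None) -> bool:
    """A boundary reaction touching exactly one metabolite.

    The objective (biomass) reaction is never classified as an exchange,
    even when it drains a single pooled metabolite.
    """
    if objective_id is not None and reaction.id == objective_id:
        return False
    return len(reaction.metabolites) == 1


def exchange_ids(model: cobra.Model) -> list[str]:
    obj = objective_reaction_id(model)
    return [r.id for r in model.reactions if is_exchange(r, obj)]


def reaction_rule(reaction: cobra.Reaction) -> GPRRule:
    """Parsed, classified GPR rule of a reaction."""
    return parse_gpr(reaction.gene_reaction_rule)


def summarize_rules(model: cobra.Model) -> RuleCensus:
    """Classify every reaction's GPR and tally the category census."""
    counts = {"one-gene": 0, "or": 0, "and": 0, "andor": 0, "none": 0}
    genes: set[str] = set()
    for reaction in model.reactions:
        rule = reaction_rule(reaction)
        counts[rule.category] += 1
        genes.update(rule.genes)
    n_reactions = len(model.reactions)
    n_annotated = n_reactions - counts["none"]
    return RuleCensus(
        n_reactions=n_reactions,
        n_genes=len(genes),
        n_annotated=n_annotated,
        n_one_gene=counts["one-gene"],
        n_or=counts["or"],
        n_and=counts["and"],
        n_andor=counts["andor"],
        fraction_annotated=(n_annotated / n_reactions) if n_reactions else 0.0,
    )
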