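"""Growth-thresholded integration of transcriptomics data into reaction bounds.

The integration algorithm tailors a media-constrained genome-scale model to
one sample's expression profile while guaranteeing that the predicted growth
never falls below an experimentally measured floor.  Expression values
(log2(TPM+1) by default) are mapped onto reaction bounds according to the
GPR rule category:

====================  =======================================================
one-gene              lower = -E (reversible) or 0, upper = +E
'or' (isoenzymes)     lower = -sum(E_i) or 0,        upper = sum(E_i)
'and' (subunits)      lower = -min(E_i) or 0,        upper = min(E_i)
====================  =======================================================

Mixed 'andor' rules are excluded from integration.  Reactions are processed
one at a time in model document order; each is skipped if locked by the
medium, skipped if essential (knocking it out drops the optimum below a
fraction of baseline), skipped if its genes are missing from the profile,
and otherwise *provisionally* constrained.  An FBA solve then arbitrates:
if the optimum stays at or above the growth floor the constraint is kept,
otherwise the reaction's prior bounds are restored and the reaction is
recorded as reopened.  The growth floor is the inverse of the experimental
doubling time, since biomass flux (g/gDW/h) is the growth rate and its
inverse the doubling time (h).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import pandas as pd
import yaml

from .gpr import GPRRule
from .media import media_locked_ids, _MEDIA_ATTR
from .model_io import reaction_rule
from .simulation import slim_optimum

__all__ = [
    "ExpressionProfile",
    "GrowthThreshold",
    "IntegrationReport",
    "UnsupportedRuleCategory",
    "rule_bounds",
    "reaction_is_essential",
    "integrate",
    "doubling_time",
    "growth_rate",
    "load_expression",
    "load_thresholds",
]

#: Absolute tolerance on FBA objective comparisons.
OBJ_TOL = 1e-9

#: Knockout optimum below this fraction of baseline marks a reaction essential.
ESSENTIAL_FRACTION = 0.01


class UnsupportedRuleCategory(ValueError):
    """rule_bounds asked to map an 'andor' or unannotated rule."""


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene normalised expression for one sample (log2(TPM+1) scale)."""

    sample_id: str
    values: dict[str, float]

    def __post_init__(self):
        bad = {
            g: v
            for g, v in self.values.items()
            if not (v == v and abs(v) != float("inf")) or v < 0
        }
        if bad:
            raise ValueError(f"non-finite or negative expression values: {bad}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.values

    def __getitem__(self, gene: str) -> float:
        return self.values[gene]


@dataclass(frozen=True)
class GrowthThreshold:
    """Experimental doubling time converted to a minimum growth rate."""

    sample_id: str
    doubling_time_h: float

    def __post_init__(self):
        if self.doubling_time_h <= 0:
            raise ValueError("doubling time must be positive")

    @property
    def growth_min(self) -> float:
        return 1.0 / self.doubling_time_h


@dataclass
class IntegrationReport:
    """Per-reaction outcome of one integration run."""

    sample_id: str
    dispositions: dict[str, str] = field(default_factory=dict)
    final_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    reopened: list[str] = field(default_factory=list)
    final_growth: float = 0.0
    growth_min: float = 0.0
    effective_floor: float = 0.0
    threshold_unreachable: bool = False
    n_fba_solves: int = 0

    @property
    def final_doubling_time_h(self) -> float:
        return doubling_time(self.final_growth) if self.final_growth > 0 else float("inf")

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for disposition in self.dispositions.values():
            out[disposition] = out.get(disposition, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "growth_min": self.growth_min,
            "effective_floor": self.effective_floor,
            "threshold_unreachable": self.threshold_unreachable,
            "final_growth": self.final_growth,
            "final_doubling_time_h": self.final_doubling_time_h,
            "n_fba_solves": self.n_fba_solves,
            "reopened": list(self.reopened),
            "disposition_counts": self.counts(),
            "dispositions": dict(self.dispositions),
            "final_bounds": {r: list(b) for r, b in self.final_bounds.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def doubling_time(growth: float) -> float:
    """Doubling time (h) as the inverse of the growth rate (g/gDW/h)."""
    if growth <= 0:
        raise ValueError("doubling time undefined for non-positive growth")
    return 1.0 / growth


def growth_rate(doubling_time_h: float) -> float:
    """Growth rate (g/gDW/h) as the inverse of the doubling time (h)."""
    if doubling_time_h <= 0:
        raise ValueError("growth rate undefined for non-positive doubling time")
    return 1.0 / doubling_time_h


def rule_bounds(
    rule: GPRRule, expression: ExpressionProfile, reversible: bool
) -> tuple[float, float]:
    """Map a GPR rule and expression profile onto (lower, upper) bounds.

    one-gene uses the value directly, 'or' sums the isoenzyme values,
    'and' takes the minimum subunit value.  The lower bound is the negated
    magnitude for reversible reactions and 0 otherwise.
    """
    if rule.category not in ("one-gene", "or", "and"):
        raise UnsupportedRuleCategory(
            f"cannot derive bounds for rule category {rule.category!r}"
        )
    values = [expression[g] for g in rule.genes]
    if rule.category == "or":
        magnitude = sum(values)
    elif rule.category == "and":
        magnitude = min(values)
    else:
        magnitude = values[0]
    return (-magnitude if reversible else 0.0, magnitude)


def reaction_is_essential(
    model: cobra.Model,
    reaction_id: str,
    essential_fraction: float = ESSENTIAL_FRACTION,
    baseline: float | None = None,
) -> bool:
    """True iff closing the reaction drops the optimum below
    ``essential_fraction`` × the unperturbed optimum.  The model is
    restored afterwards."""
    reaction = model.reactions.get_by_id(reaction_id)
    if baseline is None:
        value = model.slim_optimize(error_value=float("nan"))
        if value != value:
            raise RuntimeError(
                "baseline FBA is infeasible; check the applied media constraints"
            )
        baseline = float(value)
    saved = reaction.bounds
    reaction.bounds = (0.0, 0.0)
    ko = slim_optimum(model)
    reaction.bounds = saved
    return ko < essential_fraction * baseline - OBJ_TOL


def integrate(
    model: cobra.Model,
    expression: ExpressionProfile,
    threshold: GrowthThreshold,
    *,
    essential_fraction: float = ESSENTIAL_FRACTION,
    order: str = "document",
    allow_partial_or: bool = False,
) -> tuple[cobra.Model, IntegrationReport]:
    """Run the sequential constrain/check/relax loop on a media-constrained model.

    Parameters
    ----------
    model:
        Media-constrained model (see :func:`fluxcap.media.apply_media`).
        Not modified; a constrained copy is returned.
    expression:
        The sample's expression profile.
    threshold:
        Experimental doubling time; its inverse is the growth floor.
    essential_fraction:
        Fraction of the current optimum below which a reaction knockout
        marks the reaction essential (locked at its prior bounds).
    order:
        ``document`` (canonical) or ``sorted`` (lexicographic by id).
    allow_partial_or:
        Permit 'or' rules whose genes are only partially covered by the
        profile (summing over the covered genes).  Off by default: any
        missing gene leaves the reaction at its prior bounds.

    Returns
    -------
    (constrained model copy, IntegrationReport)
    """
    locked = media_locked_ids(model)
    constrained = model.copy()
    setattr(constrained, _MEDIA_ATTR, locked)

    report = IntegrationReport(sample_id=expression.sample_id)
    report.growth_min = threshold.growth_min

    baseline = slim_optimum(constrained)
    report.n_fba_solves += 1
    floor = threshold.growth_min
    if baseline < floor - OBJ_TOL:
        warnings.warn(
            f"growth floor {floor:.6g} exceeds the media-constrained optimum "
            f"{baseline:.6g}; proceeding with the achievable optimum as floor",
            stacklevel=2,
        )
        report.threshold_unreachable = True
        floor = baseline
    report.effective_floor = floor

    reaction_ids = [r.id for r in constrained.reactions]
    if order == "sorted":
        reaction_ids = sorted(reaction_ids)
    elif order != "document":
        raise ValueError(f"unknown processing order {order!r}")

    current = baseline
    for rid in reaction_ids:
        reaction = constrained.reactions.get_by_id(rid)
        if rid in locked:
            report.dispositions[rid] = "media_locked"
            continue
        report.n_fba_solves += 1
        if reaction_is_essential(
            constrained, rid, essential_fraction, baseline=current
        ):
            report.dispositions[rid] = "essential_locked"
            continue
        rule = reaction_rule(reaction)
        if rule.category == "andor":
            report.dispositions[rid] = "andor_skipped"
            continue
        if rule.category == "none":
            report.dispositions[rid] = "genes_missing"
            continue
        present = [g for g in rule.genes if g in expression]
        if len(present) < len(rule.genes):
            partial_ok = (
                allow_partial_or and rule.category == "or" and len(present) > 0
            )
            if not partial_ok:
                report.dispositions[rid] = "genes_missing"
                continue
            effective = GPRRule(category="or", genes=tuple(present))
        else:
            effective = rule
        prior = reaction.bounds
        reaction.bounds = rule_bounds(effective, expression, reaction.lower_bound < 0)
        candidate = slim_optimum(constrained)
        report.n_fba_solves += 1
        if candidate < floor - OBJ_TOL:
            reaction.bounds = prior
            report.dispositions[rid] = "reopened"
            report.reopened.append(rid)
        else:
            report.dispositions[rid] = "constrained"
            current = candidate

    report.final_growth = slim_optimum(constrained)
    report.n_fba_solves += 1
    report.final_bounds = {r.id: r.bounds for r in constrained.reactions}
    return constrained, report


# ---------------------------------------------------------------------------
# file input


def load_expression(
    path: str | Path, genes: set[str] | None = None
) -> dict[str, ExpressionProfile]:
    """Read an expression table (TSV/CSV) into per-sample profiles.

    Orientation is auto-detected: genes may be rows (one column per
    sample) or columns (one row per sample).  When a model gene set is
    supplied, the axis with the larger overlap is taken as the gene axis;
    otherwise genes are assumed to be rows.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if genes is not None:
        row_hits = len(set(map(str, frame.index)) & genes)
        col_hits = len(set(map(str, frame.columns)) & genes)
        if col_hits > row_hits:
            frame = frame.T
    return {
        str(sample): ExpressionProfile(
            sample_id=str(sample),
            values={str(g): float(v) for g, v in frame[sample].dropna().items()},
        )
        for sample in frame.columns
    }


def load_thresholds(path: str | Path) -> dict[str, GrowthThreshold]:
    """Read doubling times: YAML/JSON ``{sample_id: doubling_time_h}``."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return {
        str(sid): GrowthThreshold(sample_id=str(sid), doubling_time_h=float(dt))
        for sid, dt in data.items()
    }
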