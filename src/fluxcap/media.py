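"""Growth-medium constraints on exchange reactions.

A medium (e.g. DMEM) is encoded as bounds on exchange reactions, with the
COBRA sign convention: negative flux is uptake.  Applying a medium sets the
listed exchanges to exactly the given bounds and closes uptake (lower bound
0) on every other exchange, leaving secretion open — an undefined medium
component cannot be consumed but anything may still be excreted.

Culture media usually include foetal bovine serum (FBS), whose composition
is not chemically defined.  ``estimate_serum_components`` reconstructs the
serum contribution by greedy essentiality-directed reopening: while the
predicted growth stays below a floor, the closed exchange whose reopening
(restoring default bounds) raises the FBA optimum the most is permanently
reopened, with ties broken by model document order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import yaml

from .model_io import DEFAULT_BOUND, exchange_ids, is_exchange, objective_reaction_id
from .simulation import slim_optimum

__all__ = [
    "MediaDefinition",
    "MediaError",
    "SerumEstimate",
    "load_media",
    "apply_media",
    "media_locked_ids",
    "estimate_serum_components",
]

_MEDIA_ATTR = "_fluxcap_media_locked"


class MediaError(ValueError):
    """Unknown or non-exchange reaction ids in a media definition."""


@dataclass(frozen=True)
class MediaDefinition:
    """Exchange-reaction bounds defining a growth medium (mmol/gDW/h)."""

    name: str
    entries: dict[str, tuple[float, float]]

    def __post_init__(self):
        for rid, (lb, ub) in self.entries.items():
            if lb > ub:
                raise MediaError(f"media entry {rid}: lower bound {lb} > upper {ub}")


@dataclass
class SerumEstimate:
    reopened: list[str] = field(default_factory=list)
    rationale: dict[str, str] = field(default_factory=dict)
    satisfied: bool = True
    final_growth: float = 0.0


def load_media(path: str | Path) -> MediaDefinition:
    """Read a media file: YAML/JSON ``{name, entries: {rxn_id: [lb, ub]}}``."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    entries = {
        rid: (float(lb), float(ub)) for rid, (lb, ub) in data["entries"].items()
    }
    return MediaDefinition(name=data.get("name", path.stem), entries=entries)


def apply_media(model: cobra.Model, media: MediaDefinition) -> cobra.Model:
    """Return a copy of the model constrained to the medium.

    Listed exchanges get exactly the specified bounds; all other exchanges
    have uptake closed (lower bound 0); non-exchange reactions are
    untouched.  The set of media-locked reaction ids is recorded on the
    returned model (see :func:`media_locked_ids`).
    """
    obj = objective_reaction_id(model)
    unknown = [rid for rid in media.entries if rid not in model.reactions]
    if unknown:
        raise MediaError(f"media ids not in model: {unknown}")
    non_exchange = [
        rid
        for rid in media.entries
        if not is_exchange(model.reactions.get_by_id(rid), obj)
    ]
    if non_exchange:
        raise MediaError(f"media ids are not exchange reactions: {non_exchange}")

    constrained = model.copy()
    for rid in exchange_ids(constrained):
        reaction = constrained.reactions.get_by_id(rid)
        if rid in media.entries:
            reaction.bounds = media.entries[rid]
        elif reaction.lower_bound < 0:
            reaction.lower_bound = 0.0
    setattr(constrained, _MEDIA_ATTR, frozenset(media.entries))
    return constrained


def media_locked_ids(model: cobra.Model) -> frozenset[str]:
    """Reaction ids fixed by the applied medium (empty if none applied)."""
    return getattr(model, _MEDIA_ATTR, frozenset())


def estimate_serum_components(
    model: cobra.Model,
    candidates: list[str] | None = None,
    growth_floor: float = 0.0,
    default_bound: float = DEFAULT_BOUND,
) -> SerumEstimate:
    """Greedy reopening of closed exchanges until growth reaches a floor.

    The model is modified in place (reopened exchanges keep their restored
    default bounds ±``default_bound``).  If no candidate can lift the
    optimum to the floor the estimate is returned flagged unsatisfied.
    """
    locked = media_locked_ids(model)
    if candidates is None:
        candidates = [rid for rid in exchange_ids(model) if rid not in locked]
    else:
        overlap = set(candidates) & set(locked)
        if overlap:
            raise MediaError(f"serum candidates overlap media entries: {sorted(overlap)}")
    remaining = [
        rid
        for rid in candidates
        if model.reactions.get_by_id(rid).lower_bound >= 0  # uptake closed
    ]

    estimate = SerumEstimate()
    current = slim_optimum(model)
    while current < growth_floor and remaining:
        best_rid, best_growth = None, current
        for rid in remaining:  # document order => deterministic tie-break
            reaction = model.reactions.get_by_id(rid)
            saved = reaction.bounds
            reaction.bounds = (-default_bound, default_bound)
            growth = slim_optimum(model)
            reaction.bounds = saved
            if growth > best_growth + 1e-12:
                best_rid, best_growth = rid, growth
        if best_rid is None:
            estimate.satisfied = False
            break
        reaction = model.reactions.get_by_id(best_rid)
        estimate.rationale[best_rid] = (
            f"growth {current:.6g} -> {best_growth:.6g} on reopening"
        )
        reaction.bounds = (-default_bound, default_bound)
        estimate.reopened.append(best_rid)
        remaining.remove(best_rid)
        current = best_growth
    estimate.final_growth = current
    if current < growth_floor:
        estimate.satisfied = False
    return estimate
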