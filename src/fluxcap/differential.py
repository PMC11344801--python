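"""Differential-flux comparison between two groups of constrained models.

Flux solutions from the sample-specific models of two groups (e.g. low-
versus high-grade tumour cell lines) are compared reaction by reaction
with a three-part difference criterion:

* a relative change of at least 10% between the group mean fluxes
  (denominator: the larger absolute mean), **and** at least one
  sample-level flux of magnitude >= 0.5 mmol/gDW/h in either group; **or**
* the flux changed direction between the groups (opposite-signed means).

Flagged reactions are then tallied per metabolic subsystem together with
the number of unique genes appearing in their GPR rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .model_io import is_exchange, objective_reaction_id, reaction_rule

__all__ = [
    "ZERO_TOL",
    "GroupFluxTable",
    "DifferentialFluxRecord",
    "active_fraction",
    "flag_differential",
    "subsystem_census",
]

#: Fluxes below this magnitude (mmol/gDW/h) count as zero.
ZERO_TOL = 1e-6


@dataclass
class GroupFluxTable:
    """Per-reaction fluxes across the member samples of one group."""

    label: str
    fluxes: pd.DataFrame  # reactions x samples

    @classmethod
    def from_solutions(cls, label: str, solutions: dict[str, pd.Series]) -> "GroupFluxTable":
        frame = pd.DataFrame(solutions)
        if frame.isna().any().any():
            raise ValueError("member solutions do not cover the same reaction set")
        return cls(label=label, fluxes=frame)

    @property
    def mean(self) -> pd.Series:
        return self.fluxes.mean(axis=1)

    @property
    def sem(self) -> pd.Series:
        n = self.fluxes.shape[1]
        return self.fluxes.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else self.mean * 0.0


@dataclass
class DifferentialFluxRecord:
    reaction_id: str
    mean_low: float
    mean_high: float
    rel_change: float
    magnitude_ok: bool
    sign_change: bool
    flagged: bool
    subsystem: str = ""
    sem_low: float = 0.0
    sem_high: float = 0.0


def active_fraction(
    tables: list[GroupFluxTable], model: cobra.Model, zero_tol: float = ZERO_TOL
) -> float:
    """Fraction of non-exchange reactions carrying flux (|v| > tolerance)
    in at least one sample of any group."""
    obj = objective_reaction_id(model)
    internal = [r.id for r in model.reactions if not is_exchange(r, obj)]
    if not internal:
        return 0.0
    active: set[str] = set()
    for table in tables:
        sub = table.fluxes.reindex(internal).fillna(0.0)
        hits = sub.abs().gt(zero_tol).any(axis=1)
        active.update(hits[hits].index)
    return len(active) / len(internal)


def flag_differential(
    low: GroupFluxTable,
    high: GroupFluxTable,
    rel_threshold: float = 0.10,
    magnitude: float = 0.5,
    zero_tol: float = ZERO_TOL,
    model: cobra.Model | None = None,
) -> list[DifferentialFluxRecord]:
    """Apply the three-part difference criterion to every reaction.

    Raises on mismatched reaction universes.  If a model is supplied,
    subsystem tags are attached to the records.
    """
    if set(low.fluxes.index) != set(high.fluxes.index):
        raise ValueError("groups do not share the same reaction set")
    subsystems: dict[str, str] = {}
    if model is not None:
        subsystems = {r.id: (r.subsystem or "") for r in model.reactions}

    mean_low, mean_high = low.mean, high.mean
    sem_low, sem_high = low.sem, high.sem
    records: list[DifferentialFluxRecord] = []
    for rid in low.fluxes.index:
        ml, mh = float(mean_low[rid]), float(mean_high[rid])
        denom = max(abs(ml), abs(mh))
        rel = abs(ml - mh) / denom if denom > zero_tol else 0.0
        mag_ok = bool(
            (low.fluxes.loc[rid].abs() >= magnitude).any()
            or (high.fluxes.loc[rid].abs() >= magnitude).any()
        )
        sign = (ml > zero_tol and mh < -zero_tol) or (ml < -zero_tol and mh > zero_tol)
        flagged = (rel >= rel_threshold and mag_ok) or sign
        records.append(
            DifferentialFluxRecord(
                reaction_id=rid,
                mean_low=ml,
                mean_high=mh,
                rel_change=rel,
                magnitude_ok=mag_ok,
                sign_change=sign,
                flagged=flagged,
                subsystem=subsystems.get(rid, ""),
                sem_low=float(sem_low[rid]),
                sem_high=float(sem_high[rid]),
            )
        )
    return records


def subsystem_census(
    records: list[DifferentialFluxRecord], model: cobra.Model
) -> dict[str, tuple[int, int]]:
    """Per-subsystem (reaction count, unique gene count) over flagged records.

    Reactions without GPR annotation contribute to the reaction count only.
    """
    reactions_by_subsystem: dict[str, int] = {}
    genes_by_subsystem: dict[str, set[str]] = {}
    for record in records:
        if not record.flagged:
            continue
        reaction = model.reactions.get_by_id(record.reaction_id)
        subsystem = record.subsystem or (reaction.subsystem or "")
        reactions_by_subsystem[subsystem] = reactions_by_subsystem.get(subsystem, 0) + 1
        genes_by_subsystem.setdefault(subsystem, set()).update(
            reaction_rule(reaction).genes
        )
    return {
        subsystem: (count, len(genes_by_subsystem[subsystem]))
        for subsystem, count in reactions_by_subsystem.items()
    }


def records_frame(records: list[DifferentialFluxRecord]) -> pd.DataFrame:
    """Records as a DataFrame with all intermediate quantities (for TSV output)."""
    return pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "subsystem": r.subsystem,
                "mean_low": r.mean_low,
                "mean_high": r.mean_high,
                "sem_low": r.sem_low,
                "sem_high": r.sem_high,
                "rel_change": r.rel_change,
                "magnitude_ok": r.magnitude_ok,
                "sign_change": r.sign_change,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )
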