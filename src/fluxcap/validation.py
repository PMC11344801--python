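"""Validation of model predictions against CRISPR gene-dependency screens.

Two procedures:

* **Dependency-delta over-representation analysis (ORA).**  Per-gene mean
  dependency scores are contrasted between two groups of cell lines; the
  top-N genes by delta are tested for enrichment in user-supplied gene
  sets (GMT) with a hypergeometric upper-tail test and Benjamini-Hochberg
  FDR control across sets.

* **Essentiality correlation.**  In-silico single-gene knockout growth
  ratios are Pearson-correlated with experimental dependency scores on the
  shared gene set, restricted to genes with a predicted growth effect
  (ratio below a cutoff).  A dependency score near 1 means the gene's loss
  strongly impairs growth, so agreement appears as negative correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulation import KnockoutResult

__all__ = [
    "DependencyDataset",
    "EnrichmentResult",
    "load_dependency",
    "load_gmt",
    "dependency_delta",
    "top_n",
    "ora",
    "essentiality_correlation",
]


@dataclass
class DependencyDataset:
    """CRISPR dependency scores (lines x genes, values in [0, 1]) with
    named cell-line groups."""

    scores: pd.DataFrame
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        values = self.scores.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("dependency scores must lie in [0, 1]")
        for label, lines in self.groups.items():
            missing = [l for l in lines if l not in self.scores.index]
            if missing:
                raise ValueError(f"group {label!r} references unknown lines {missing}")


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    overlap: int
    p_value: float
    fdr: float
    enrichment_ratio: float
    overlap_genes: tuple[str, ...] = ()


def load_dependency(
    path: str | Path, groups: dict[str, list[str]] | None = None
) -> DependencyDataset:
    """Read a dependency CSV (cell lines x genes).  DepMap-dialect column
    headers ``"SYMBOL (entrez)"`` are trimmed to the symbol."""
    frame = pd.read_csv(path, index_col=0)
    frame.columns = [c.split(" (")[0] if " (" in c else c for c in frame.columns]
    return DependencyDataset(scores=frame, groups=groups or {})


def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def dependency_delta(
    data: DependencyDataset, group_a: str, group_b: str
) -> tuple[pd.Series, list[str]]:
    """Per-gene mean(group_a) - mean(group_b).

    Genes with a missing score in any member line of either group are
    dropped; the dropped gene ids are returned alongside.
    """
    lines_a = data.groups.get(group_a)
    lines_b = data.groups.get(group_b)
    if not lines_a or not lines_b:
        raise ValueError(f"empty or unknown group: {group_a!r} / {group_b!r}")
    sub_a = data.scores.loc[lines_a]
    sub_b = data.scores.loc[lines_b]
    complete = sub_a.notna().all(axis=0) & sub_b.notna().all(axis=0)
    dropped = sorted(complete[~complete].index.astype(str))
    delta = sub_a.loc[:, complete].mean(axis=0) - sub_b.loc[:, complete].mean(axis=0)
    return delta, dropped


def top_n(delta: pd.Series, n: int = 250) -> list[str]:
    """The n genes with the largest delta, descending; ties at equal delta
    broken lexicographically by gene id."""
    if n > len(delta):
        raise ValueError(f"n={n} exceeds the {len(delta)} available genes")
    ordered = sorted(delta.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [str(g) for g, _ in ordered[:n]]


def ora(
    gene_list: list[str],
    gene_sets: dict[str, set[str]],
    reference: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a gene list in each gene set.

    Gene sets are intersected with the reference universe first; sets with
    no reference genes are skipped.  p is the upper-tail probability of an
    overlap at least as large as observed; FDR is Benjamini-Hochberg across
    the tested sets; enrichment ratio is observed / expected overlap.
    Results are sorted by p ascending.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    listed = set(gene_list) & reference
    M = len(reference)
    N = len(listed)
    if M < len(set(gene_list)):
        # tolerate genes outside the reference but require a sane universe
        if N == 0:
            raise ValueError("no gene-list members inside the reference set")
    results: list[EnrichmentResult] = []
    for name, members in gene_sets.items():
        in_ref = members & reference
        if not in_ref:
            continue
        K = len(in_ref)
        overlap_genes = tuple(sorted(in_ref & listed))
        k = len(overlap_genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        expected = N * K / M
        ratio = k / expected if expected > 0 else 0.0
        results.append(
            EnrichmentResult(
                set_name=name,
                set_size=K,
                overlap=k,
                p_value=min(p, 1.0),
                fdr=float("nan"),
                enrichment_ratio=ratio,
                overlap_genes=overlap_genes,
            )
        )
    if results:
        _, fdrs, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for result, fdr in zip(results, fdrs):
            result.fdr = float(fdr)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def essentiality_correlation(
    ko: list[KnockoutResult],
    dependency: dict[str, float] | pd.Series,
    max_ratio: float = 1.0,
) -> tuple[float, float, int]:
    """Pearson correlation of KO growth ratio vs dependency score over the
    shared genes with growth_ratio < max_ratio.  Returns (r, p, n)."""
    if isinstance(dependency, pd.Series):
        dependency = dependency.dropna().to_dict()
    pairs = [
        (result.growth_ratio, float(dependency[result.gene]))
        for result in ko
        if result.growth_ratio < max_ratio and result.gene in dependency
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} gene(s) shared after filtering; need >= 3"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in ratios or dependency scores")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(pairs)
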