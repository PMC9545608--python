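"""Normalized DE proportions (chord-plot matrices) and category counts.

For each pairwise comparison the number of significant genes is normalized by
the number of genes *expressed* within the pair — genes with any count in the
union of the two groups' cells — and reported as a percentage. The matrix
over the 14 (region, class) nodes feeds standard chord-diagram renderers; the
per-category counts per class pair feed stacked-bar summaries. Rendering
itself is out of scope: the package emits the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .collapse import CATEGORIES
from .datasets import CLASSES, REGIONS, ExpressionDataset
from .de import ComparisonSpec


@dataclass(frozen=True)
class PairSummary:
    """DE counts for one comparison: n_de / n_expressed -> pct_de."""

    spec: ComparisonSpec
    n_de: int
    n_expressed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_de <= self.n_expressed:
            raise ValueError("need 0 <= n_de <= n_expressed")

    @property
    def pct_de(self) -> float:
        return de_percentage(self.n_de, self.n_expressed)


def expressed_gene_count(
    dataset: ExpressionDataset,
    spec: ComparisonSpec,
    universe: set[str] | None = None,
) -> int:
    """Genes with a nonzero total count across the union of the pair's cells.

    Average expression within the pair greater than zero is equivalent to a
    nonzero raw total, so the count is taken on raw counts. ``universe``
    optionally restricts to a gene set (e.g. one GO category).
    """
    if spec.kind == "within_region":
        mask = dataset.cell_mask(region=spec.region, cls=spec.class_a) | \
            dataset.cell_mask(region=spec.region, cls=spec.class_b)
    else:
        mask = dataset.cell_mask(cls=spec.class_a)
    expressed = dataset.counts[:, mask].sum(axis=1) > 0
    if universe is not None:
        members = np.array([str(g).upper() in universe for g in dataset.genes])
        expressed &= members
    return int(expressed.sum())


def de_percentage(n_de: int, n_expressed: int) -> float:
    """100 * n_de / n_expressed, reported to one decimal (half-up)."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    pct = Decimal(100 * n_de) / Decimal(n_expressed)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pair_summaries(
    dataset: ExpressionDataset,
    de_table: pd.DataFrame,
    specs: Sequence[ComparisonSpec],
    universe: set[str] | None = None,
) -> list[PairSummary]:
    """One :class:`PairSummary` per comparison of the plan.

    ``universe`` (uppercase symbols) restricts both the significant genes and
    the expressed-gene denominator to a gene set.
    """
    universe_norm = {g.upper() for g in universe} if universe is not None else None
    out = []
    for spec in specs:
        rows = de_table[de_table["comparison_id"] == spec.comparison_id]
        genes = {str(g).upper() for g in rows["gene"]}
        if universe_norm is not None:
            genes &= universe_norm
        n_exp = expressed_gene_count(dataset, spec, universe=universe_norm)
        out.append(PairSummary(spec, len(genes), n_exp))
    return out


def _node(region: str, cls: str) -> str:
    return f"{region} {cls}"


def build_chord_matrix(summaries: Iterable[PairSummary]) -> pd.DataFrame:
    """Symmetric matrix of pct_de over the 14 (region, class) nodes.

    Tested pairs get their percentage (mirrored across the diagonal);
    untested pairs stay NaN (absent, distinct from an observed 0.0).
    """
    nodes = [_node(r, c) for r in REGIONS for c in CLASSES]
    mat = pd.DataFrame(np.nan, index=nodes, columns=nodes)
    seen: set[tuple[str, str]] = set()
    for s in summaries:
        spec = s.spec
        if spec.kind == "within_region":
            a = _node(spec.region, spec.class_a)
            b = _node(spec.region, spec.class_b)
        else:
            a = _node("ALM", spec.class_a)
            b = _node("VISp", spec.class_a)
        if (a, b) in seen:
            raise ValueError(f"duplicate pair in summaries: {a} / {b}")
        seen.add((a, b))
        seen.add((b, a))
        mat.loc[a, b] = s.pct_de
        mat.loc[b, a] = s.pct_de
    return mat


def category_counts_by_pair(
    collapsed: pd.DataFrame, circuit_filter: bool = True
) -> pd.DataFrame:
    """Counts of genes per class pair per regionality category.

    Conserved and divergent records are counted once per (gene, pair). With
    ``circuit_filter`` only rows carrying at least one gene-set label count.
    """
    rows = collapsed
    if circuit_filter:
        if "go_terms" not in rows.columns:
            rows = rows.iloc[0:0]
        else:
            rows = rows[rows["go_terms"].fillna("").astype(str) != ""]
    out = pd.DataFrame(0, index=pd.Index([], name="pair"), columns=list(CATEGORIES))
    if len(rows) == 0:
        return out
    pair = rows["class_a"] + " vs " + rows["class_b"]
    counts = (
        pd.crosstab(pair, rows["category"])
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    counts.index.name = "pair"
    counts.columns.name = None
    return counts
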