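"""Pairwise differential-expression engine.

The workflow normalizes raw counts per cell (library-size scaling to a fixed
factor, natural-log transform with a pseudocount of 1), then runs ordered
pairwise tests:

* within each region, every class pair inside a neurotransmitter group,
  always in the canonical order (e.g. "VIP vs PV", never "PV vs VIP"),
* across regions, each class against itself, ALM always first.

Per gene a comparison reports the average log fold change of back-transformed
group means, detection fractions, and a two-sided Wilcoxon rank-sum p-value
(normal approximation, midranks, tie-corrected variance, no continuity
correction), Bonferroni-adjusted over the full gene universe. Only rows that
clear the effect-size pre-filter and the adjusted significance level are
emitted, so a result table contains significant rows only.

Because analogous ALM and VISp comparisons share their class order, the sign
of ``avg_logFC`` is directly comparable between regions: positive always means
"higher in the first-listed group".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CLASS_ORDER, GROUPS, REGIONS, ExpressionDataset, group_of

DE_COLUMNS = (
    "comparison_id",
    "region_scope",
    "class_a",
    "class_b",
    "gene",
    "avg_logFC",
    "p_raw",
    "p_adj",
    "pct_a",
    "pct_b",
)

CROSS_SCOPE = "cross"


@dataclass(frozen=True)
class NormalizationConfig:
    """Library-size normalization: ln(count / total * scale_factor + 1)."""

    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass(frozen=True)
class DETestConfig:
    """Thresholds of the significance rule.

    ``logfc_threshold`` is applied two-sided (|avg_logFC|, natural-log units)
    before testing; ``min_detect_fraction`` requires the gene detected in at
    least that fraction of cells in one of the two groups; ``adjust_n`` is the
    Bonferroni multiplier (``None`` = total genes in the dataset).
    """

    logfc_threshold: float = 0.25
    alpha: float = 0.05
    min_detect_fraction: float = 0.10
    adjust_n: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_detect_fraction <= 1:
            raise ValueError("min_detect_fraction must be in [0, 1]")
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold must be nonnegative")


@dataclass(frozen=True)
class ComparisonSpec:
    """One ordered pairwise test.

    ``kind == "within_region"``: ``class_a`` vs ``class_b`` inside ``region``.
    ``kind == "cross_region"``: the class ``class_a`` (== ``class_b``) compared
    between ALM (first) and VISp.
    """

    kind: str
    class_a: str
    class_b: str
    region: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("within_region", "cross_region"):
            raise ValueError(f"unknown comparison kind {self.kind!r}")
        if self.kind == "within_region":
            if self.region not in REGIONS:
                raise ValueError(f"within-region spec needs a region, got {self.region!r}")
            if self.class_a == self.class_b:
                raise ValueError("within-region comparison needs two distinct classes")
            if group_of(self.class_a) != group_of(self.class_b):
                raise ValueError("classes of a comparison must share a group")
        else:
            if self.class_a != self.class_b:
                raise ValueError("cross-region spec compares a class with itself")

    @property
    def group(self) -> str:
        return group_of(self.class_a)

    @property
    def pair_name(self) -> str:
        """Class-pair label, e.g. ``"VIP vs PV"`` (within-region only)."""
        return f"{self.class_a} vs {self.class_b}"

    @property
    def comparison_id(self) -> str:
        if self.kind == "within_region":
            return f"{self.region} {self.pair_name}"
        return f"ALM vs VISp {self.class_a}"

    @property
    def region_scope(self) -> str:
        return self.region if self.kind == "within_region" else CROSS_SCOPE

    def swapped(self) -> "ComparisonSpec":
        if self.kind != "within_region":
            raise ValueError("only within-region comparisons can be swapped")
        return replace(self, class_a=self.class_b, class_b=self.class_a)


def log_normalize(
    counts: np.ndarray,
    config: NormalizationConfig = NormalizationConfig(),
    cell_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """ln(count / cell_total * scale_factor + 1), per cell (column)."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = np.flatnonzero(totals == 0)
        name = cell_ids[bad[0]] if cell_ids is not None else f"column {bad[0]}"
        raise ValueError(f"cell with zero total count: {name}")
    return np.log1p(counts / totals * config.scale_factor)


def build_comparison_plan(
    dataset: ExpressionDataset | None = None,
    groups: Iterable[str] = GROUPS,
) -> list[ComparisonSpec]:
    """All ordered pairwise comparisons for the classes present.

    For the full taxonomy this is 6 glutamatergic + 3 GABAergic pairs per
    region, plus one cross-region comparison per class: (6+3)*2 + 7 = 25.
    """
    groups = tuple(groups)
    if dataset is not None:
        present = {
            (r, c)
            for r, c in zip(dataset.cells["region"], dataset.cells["class"])
        }
        for g in groups:
            for region in REGIONS:
                for cls in CLASS_ORDER[g]:
                    if (region, cls) not in present:
                        raise ValueError(f"dataset is missing class {cls!r} in {region}")
    specs: list[ComparisonSpec] = []
    for region in REGIONS:
        for g in groups:
            order = CLASS_ORDER[g]
            for i, a in enumerate(order):
                for b in order[i + 1 :]:
                    specs.append(
                        ComparisonSpec("within_region", a, b, region=region)
                    )
    for g in groups:
        for cls in CLASS_ORDER[g]:
            specs.append(ComparisonSpec("cross_region", cls, cls))
    return specs


def _back_mean(norm: np.ndarray) -> np.ndarray:
    """Per-gene mean of back-transformed normalized values, plus pseudocount."""
    return np.expm1(norm).mean(axis=-1) + 1.0


def average_log_fold_change(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Natural-log fold change of back-transformed group means (A minus B).

    Accepts 1-D (one gene) or 2-D (genes x cells) arrays of log-normalized
    values; positive means higher in group A.
    """
    norm_a = np.asarray(norm_a, dtype=float)
    norm_b = np.asarray(norm_b, dtype=float)
    if norm_a.shape[-1] == 0 or norm_b.shape[-1] == 0:
        raise ValueError("both groups must be non-empty")
    return np.log(_back_mean(norm_a)) - np.log(_back_mean(norm_b))


def wilcoxon_rank_sum(values_a: np.ndarray, values_b: np.ndarray) -> float | np.ndarray:
    """Two-sided rank-sum p-value, normal approximation with tie correction.

    Midranks handle ties; no continuity correction. When the pooled sample is
    a single constant (no separation possible) the p-value is 1. Vectorized
    over leading axes: inputs of shape ``(g, n_a)`` and ``(g, n_b)`` yield
    ``g`` p-values.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[-1] == 0 or b.shape[-1] == 0:
        raise ValueError("both groups must be non-empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            a, b, axis=-1, alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
    p = np.asarray(res.pvalue, dtype=float)
    # zero tie-corrected variance <=> every pooled value identical
    degenerate = (a.min(axis=-1) == a.max(axis=-1)) & (
        b.min(axis=-1) == b.max(axis=-1)
    ) & (a[:, 0] == b[:, 0])
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    if np.asarray(values_a).ndim == 1:
        return float(p[0])
    return p


def _group_masks(dataset: ExpressionDataset, spec: ComparisonSpec):
    if spec.kind == "within_region":
        mask_a = dataset.cell_mask(region=spec.region, cls=spec.class_a)
        mask_b = dataset.cell_mask(region=spec.region, cls=spec.class_b)
    else:
        mask_a = dataset.cell_mask(region="ALM", cls=spec.class_a)
        mask_b = dataset.cell_mask(region="VISp", cls=spec.class_a)
    return mask_a, mask_b


def run_de_test(
    dataset: ExpressionDataset,
    spec: ComparisonSpec,
    de_config: DETestConfig = DETestConfig(),
    norm_config: NormalizationConfig = NormalizationConfig(),
    norm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run one ordered comparison; return the table of significant genes only.

    ``norm`` may carry the pre-computed log-normalized matrix for the whole
    dataset (as produced by :func:`log_normalize`) to avoid recomputation when
    looping over a plan.
    """
    mask_a, mask_b = _group_masks(dataset, spec)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"empty group in comparison {spec.comparison_id!r}")
    if norm is None:
        norm = log_normalize(
            dataset.counts, norm_config, cell_ids=dataset.cells["cell_id"].tolist()
        )

    raw_a = dataset.counts[:, mask_a]
    raw_b = dataset.counts[:, mask_b]
    pct_a = (raw_a > 0).mean(axis=1)
    pct_b = (raw_b > 0).mean(axis=1)
    keep = np.maximum(pct_a, pct_b) >= de_config.min_detect_fraction

    norm_a = norm[:, mask_a]
    norm_b = norm[:, mask_b]
    logfc = average_log_fold_change(norm_a, norm_b)
    keep &= np.abs(logfc) >= de_config.logfc_threshold

    idx = np.flatnonzero(keep)
    adjust_n = de_config.adjust_n if de_config.adjust_n is not None else dataset.n_genes
    if idx.size:
        p_raw = np.asarray(wilcoxon_rank_sum(norm_a[idx], norm_b[idx]))
        p_adj = np.minimum(1.0, p_raw * adjust_n)
        sig = p_adj < de_config.alpha
        idx, p_raw, p_adj = idx[sig], p_raw[sig], p_adj[sig]
    else:
        p_raw = p_adj = np.empty(0)

    return pd.DataFrame(
        {
            "comparison_id": spec.comparison_id,
            "region_scope": spec.region_scope,
            "class_a": spec.class_a,
            "class_b": spec.class_b,
            "gene": dataset.genes[idx],
            "avg_logFC": logfc[idx],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
        },
        columns=list(DE_COLUMNS),
    )


def run_de_plan(
    dataset: ExpressionDataset,
    specs: Sequence[ComparisonSpec] | None = None,
    de_config: DETestConfig = DETestConfig(),
    norm_config: NormalizationConfig = NormalizationConfig(),
) -> pd.DataFrame:
    """Run every comparison of a plan and concatenate the significant rows."""
    if specs is None:
        specs = build_comparison_plan(dataset)
    norm = log_normalize(
        dataset.counts, norm_config, cell_ids=dataset.cells["cell_id"].tolist()
    )
    tables = [
        run_de_test(dataset, spec, de_config, norm_config, norm=norm)
        for spec in specs
    ]
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=list(DE_COLUMNS)
    )
    return out
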