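"""Synthetic class-labeled count data and ready-made DE tables.

The generator emulates the statistical structure the analysis assumes: for
each of the 14 (region, class) groups it draws negative-binomial counts with
per-cell log-normal size factors, and plants multiplicative expression
effects encoding every downstream outcome category — conserved or
region-specific class relevance, divergent pairs, region-biased and
origin-specific genes, inconsistent decoys, and nulls. A truth table records
each planted gene's intended category so recovery can be scored after the
full pipeline.

Two fixture builders encode the study's in-text worked examples (a seven-gene
interneuron panel and a single gene whose conserved and ALM-specific results
point to different classes), so the collapse and class-relevance stages are
testable without any count data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import CLASS_ORDER, CLASSES, GABAERGIC, GLUTAMATERGIC, REGIONS, ExpressionDataset
from .de import DE_COLUMNS, ComparisonSpec

CAT_CONSERVED = "conserved-class-relevant"
CAT_ALM = "ALM-specific-class-relevant"
CAT_VISP = "VISp-specific-class-relevant"
CAT_DIVERGENT = "divergent"
CAT_REGION_BIASED = "region-biased"
CAT_ORIGIN = "origin-specific"
CAT_DECOY = "inconsistent-decoy"
CAT_NULL = "null"

TRUTH_COLUMNS = ("gene", "category", "class", "direction", "region", "class_b")


@dataclass(frozen=True)
class PlantSpec:
    """One planted gene.

    Interpretation of the fields depends on ``category``:

    * conserved / ALM- / VISp-specific class-relevant: ``cls`` + ``direction``
      (the effect is applied to that class in both regions or one region);
    * divergent: elevated in ``cls`` cells in ALM and ``cls_b`` cells in VISp
      (both classes from one comparison, producing opposite signs);
    * region-biased: ``cls`` names a group; all its classes are elevated in
      ``region``;
    * origin-specific: ``cls`` in {"VIP-only", "PV&SST-only"}, elevated in
      ``region``;
    * inconsistent-decoy: elevated in ``cls`` in ALM and ``cls_b`` in VISp,
      where the two classes share exactly one comparison — that comparison
      collapses to divergent and each regional subset retains a strict subset
      of every class set, so the gene is significant yet never class-relevant.
    """

    category: str
    cls: str | None = None
    direction: str = "up"
    region: str | None = None
    cls_b: str | None = None


def default_planting() -> tuple[PlantSpec, ...]:
    """One-or-more planted genes for every truth category."""
    return (
        PlantSpec(CAT_CONSERVED, "VIP", "up"),
        PlantSpec(CAT_CONSERVED, "VIP", "up"),
        PlantSpec(CAT_CONSERVED, "VIP", "up"),
        PlantSpec(CAT_CONSERVED, "SST", "down"),
        PlantSpec(CAT_CONSERVED, "SST", "down"),
        PlantSpec(CAT_CONSERVED, "L5 PT", "up"),
        PlantSpec(CAT_CONSERVED, "L5 PT", "up"),
        PlantSpec(CAT_ALM, "VIP", "up"),
        PlantSpec(CAT_ALM, "VIP", "up"),
        PlantSpec(CAT_ALM, "L6 CT", "down"),
        PlantSpec(CAT_ALM, "L6 CT", "down"),
        PlantSpec(CAT_VISP, "PV", "up"),
        PlantSpec(CAT_VISP, "PV", "up"),
        PlantSpec(CAT_VISP, "L2/3 IT", "up"),
        PlantSpec(CAT_VISP, "L2/3 IT", "up"),
        PlantSpec(CAT_DIVERGENT, "VIP", cls_b="PV"),
        PlantSpec(CAT_DIVERGENT, "L5 IT", cls_b="L5 PT"),
        PlantSpec(CAT_REGION_BIASED, GLUTAMATERGIC, region="ALM"),
        PlantSpec(CAT_REGION_BIASED, GABAERGIC, region="VISp"),
        PlantSpec(CAT_ORIGIN, "VIP-only", region="ALM"),
        PlantSpec(CAT_ORIGIN, "PV&SST-only", region="VISp"),
        PlantSpec(CAT_DECOY, "VIP", cls_b="SST"),
        PlantSpec(CAT_DECOY, "VIP", cls_b="SST"),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of a synthetic run.

    ``n_cells_per_group`` cells are drawn for each of the 14 (region, class)
    groups; planted effects multiply the negative-binomial mean by
    ``effect_fold`` (or its reciprocal for down effects).
    """

    n_cells_per_group: int = 200
    n_genes: int = 300
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    library_size_cv: float = 0.3
    effect_fold: float = 4.0
    seed: int = 0
    planting: tuple[PlantSpec, ...] = field(default_factory=default_planting)

    def __post_init__(self) -> None:
        if self.n_cells_per_group < 2:
            raise ValueError("n_cells_per_group must be at least 2")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be nonnegative")
        if self.effect_fold <= 0:
            raise ValueError("effect_fold must be positive")
        if self.n_genes < len(self.planting):
            raise ValueError(
                f"n_genes={self.n_genes} is smaller than the "
                f"{len(self.planting)} planted genes requested"
            )


_SLUG = {
    CAT_CONSERVED: "cons",
    CAT_ALM: "alm",
    CAT_VISP: "visp",
    CAT_DIVERGENT: "div",
    CAT_REGION_BIASED: "bias",
    CAT_ORIGIN: "orig",
    CAT_DECOY: "decoy",
    CAT_NULL: "null",
}


def _group_index() -> dict[tuple[str, str], int]:
    return {
        (region, cls): i
        for i, (region, cls) in enumerate(
            (r, c) for r in REGIONS for c in CLASSES
        )
    }


def _apply_plant(
    fold_row: np.ndarray, spec: PlantSpec, effect_fold: float, gidx: dict
) -> None:
    f = effect_fold if spec.direction == "up" else 1.0 / effect_fold
    if spec.category == CAT_CONSERVED:
        for region in REGIONS:
            fold_row[gidx[(region, spec.cls)]] = f
    elif spec.category in (CAT_ALM, CAT_VISP):
        region = "ALM" if spec.category == CAT_ALM else "VISp"
        fold_row[gidx[(region, spec.cls)]] = f
    elif spec.category == CAT_DIVERGENT:
        fold_row[gidx[("ALM", spec.cls)]] = f
        fold_row[gidx[("VISp", spec.cls_b)]] = f
    elif spec.category == CAT_REGION_BIASED:
        for cls in CLASS_ORDER[spec.cls]:
            fold_row[gidx[(spec.region, cls)]] = f
    elif spec.category == CAT_ORIGIN:
        targets = ("VIP",) if spec.cls == "VIP-only" else ("PV", "SST")
        for cls in targets:
            fold_row[gidx[(spec.region, cls)]] = f
    elif spec.category == CAT_DECOY:
        fold_row[gidx[("ALM", spec.cls)]] = f
        fold_row[gidx[("VISp", spec.cls_b)]] = f
    elif spec.category == CAT_NULL:
        pass
    else:
        raise ValueError(f"unknown planted category {spec.category!r}")


def generate_counts(config: SynthConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw a synthetic dataset and its truth table. Deterministic per seed.

    A planted gene carries a multiplicative effect only when ``effect_fold``
    differs from 1; at exactly 1 no effect exists, so every gene is recorded
    as null in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    gidx = _group_index()
    n_groups = len(gidx)
    n_cells = n_groups * config.n_cells_per_group

    planting = config.planting
    if config.effect_fold == 1.0:
        planting = tuple(PlantSpec(CAT_NULL) for _ in planting)

    folds = np.ones((config.n_genes, n_groups))
    genes, truth_rows = [], []
    counters: dict[str, int] = {}
    for spec in planting:
        slug = _SLUG[spec.category]
        counters[slug] = counters.get(slug, 0) + 1
        name = f"{slug}{counters[slug]:03d}"
        genes.append(name)
        _apply_plant(folds[len(genes) - 1], spec, config.effect_fold, gidx)
        truth_rows.append(
            (name, spec.category, spec.cls or "", spec.direction,
             spec.region or "", spec.cls_b or "")
        )
    for i in range(config.n_genes - len(genes)):
        name = f"null{i + 1:04d}"
        genes.append(name)
        truth_rows.append((name, CAT_NULL, "", "", "", ""))
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))

    # per-cell log-normal size factors with unit mean
    if config.library_size_cv > 0:
        sigma2 = np.log1p(config.library_size_cv**2)
        sf = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n_cells)
    else:
        sf = np.ones(n_cells)

    cell_ids, cell_regions, cell_classes, group_col = [], [], [], np.empty(n_cells, int)
    pos = 0
    for (region, cls), idx in gidx.items():
        tag = cls.replace("/", "").replace(" ", "")
        for i in range(config.n_cells_per_group):
            cell_ids.append(f"{region}_{tag}_{i:04d}")
            cell_regions.append(region)
            cell_classes.append(cls)
            group_col[pos] = idx
            pos += 1

    mean = config.baseline_mean * sf[None, :] * folds[:, group_col]
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean))

    cells = pd.DataFrame(
        {"cell_id": cell_ids, "region": cell_regions, "class": cell_classes}
    )
    dataset = ExpressionDataset(counts, np.array(genes, dtype=object), cells)
    return dataset, truth


# ----------------------------------------------------------- DE-table forge


def _parse_comparison(comp: str) -> ComparisonSpec:
    if comp.startswith("ALM vs VISp "):
        cls = comp[len("ALM vs VISp "):]
        return ComparisonSpec("cross_region", cls, cls)
    region, rest = comp.split(" ", 1)
    if " vs " not in rest:
        raise ValueError(f"cannot parse comparison {comp!r}")
    a, b = rest.split(" vs ")
    return ComparisonSpec("within_region", a, b, region=region)


def generate_de_table(
    pattern_spec: Sequence[tuple[str, str, int, bool, float]],
) -> pd.DataFrame:
    """Forge a significant-rows DE table from an explicit pattern.

    Each entry is ``(comparison, gene, sign, significant, magnitude)`` where
    ``comparison`` is e.g. ``"ALM VIP vs PV"`` or ``"ALM vs VISp VIP"``.
    Non-significant entries are omitted from the output (the engine emits
    significant rows only); significant ones get ``avg_logFC = sign *
    magnitude`` and an adjusted p-value below any reasonable level.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for comp, gene, sign, significant, magnitude in pattern_spec:
        spec = _parse_comparison(comp)
        key = (spec.comparison_id, gene)
        if key in seen:
            raise ValueError(f"duplicate pattern entry for {key}")
        seen.add(key)
        if not significant:
            continue
        if sign not in (-1, 1):
            raise ValueError(f"sign must be +/-1, got {sign!r}")
        rows.append(
            {
                "comparison_id": spec.comparison_id,
                "region_scope": spec.region_scope,
                "class_a": spec.class_a,
                "class_b": spec.class_b,
                "gene": gene,
                "avg_logFC": sign * magnitude,
                "p_raw": 1e-9,
                "p_adj": 1e-6,
                "pct_a": 0.9,
                "pct_b": 0.5,
            }
        )
    return pd.DataFrame(rows, columns=list(DE_COLUMNS))


def seven_gene_fixture() -> pd.DataFrame:
    """The seven-gene interneuron worked example as a forged DE table.

    Three genes are significant between VIP and PV only (in ALM, both regions,
    or VISp respectively) and therefore fail the VIP class set; four genes are
    significant in all three interneuron tests with a VIP-consistent direction
    (VIP > PV, VIP > SST, SST > PV) in both regions, ALM only, or VISp only.
    The SST-vs-PV direction is a fixture choice (significance is required;
    either direction yields the same VIP records).
    """
    m = 0.5
    pattern: list[tuple[str, str, int, bool, float]] = []

    def sig(region: str, pair: str, gene: str, sign: int = 1) -> None:
        pattern.append((f"{region} {pair}", gene, sign, True, m))

    sig("ALM", "VIP vs PV", "cyfip1")
    for region in REGIONS:
        sig(region, "VIP vs PV", "dlg2")
    sig("VISp", "VIP vs PV", "kctd13")
    for gene in ("nrxn1", "snap25"):
        for region in REGIONS:
            for pair in ("VIP vs PV", "VIP vs SST", "SST vs PV"):
                sig(region, pair, gene)
    for pair in ("VIP vs PV", "VIP vs SST", "SST vs PV"):
        sig("ALM", pair, "socs5")
    for pair in ("VIP vs PV", "VIP vs SST", "SST vs PV"):
        sig("VISp", pair, "pten")
    return generate_de_table(pattern)


def egr1_fixture() -> pd.DataFrame:
    """Forged DE table for the conserved-vs-regional reconciliation example.

    The gene is significant in all three interneuron tests in ALM but only in
    VIP-vs-PV and SST-vs-PV in VISp: its ALM-specific relevance (VIP up) and
    its conserved relevance (PV down) involve different classes, so both
    records are asterisked.
    """
    m = 0.5
    pattern = [
        ("ALM VIP vs PV", "egr1", 1, True, m),
        ("ALM VIP vs SST", "egr1", 1, True, m),
        ("ALM SST vs PV", "egr1", 1, True, m),
        ("VISp VIP vs PV", "egr1", 1, True, m),
        ("VISp SST vs PV", "egr1", 1, True, m),
    ]
    return generate_de_table(pattern)
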