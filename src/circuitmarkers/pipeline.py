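"""End-to-end orchestration: counts -> DE -> annotation -> collapse ->
class relevance -> summaries -> heatmap-ready matrices, plus a run manifest.

Every stage writes deterministic CSV/TSV; the manifest records the config,
its hash, the seed and per-stage row counts, so reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import relevance as rel
from . import summarize as summ
from .collapse import collapse as collapse_within
from .datasets import CLASS_ORDER, GLUTAMATERGIC, GROUPS, ExpressionDataset, group_of
from .de import (
    CROSS_SCOPE,
    DETestConfig,
    NormalizationConfig,
    build_comparison_plan,
    run_de_plan,
)
from .simulate import SynthConfig, generate_counts

log = logging.getLogger("circuitmarkers")


@dataclass
class PipelineConfig:
    """Paths, thresholds and scope toggles of a full run."""

    out_dir: str
    counts: str | None = None  # directory holding matrix.mtx/genes.tsv/cells.tsv
    counts_tsv: str | None = None  # dense genes-as-rows TSV alternative
    meta: str | None = None  # cell metadata TSV (with counts_tsv)
    gmt: str | None = None
    risk: str | None = None
    synthetic: bool = False
    seed: int = 0
    n_cells_per_group: int = 200
    n_genes: int = 300
    effect_fold: float = 4.0
    scale_factor: float = 10_000.0
    logfc_threshold: float = 0.25
    alpha: float = 0.05
    min_detect_fraction: float = 0.10
    groups: tuple[str, ...] = tuple(GROUPS)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)

    def de_config(self) -> DETestConfig:
        return DETestConfig(
            logfc_threshold=self.logfc_threshold,
            alpha=self.alpha,
            min_detect_fraction=self.min_detect_fraction,
        )

    def norm_config(self) -> NormalizationConfig:
        return NormalizationConfig(scale_factor=self.scale_factor)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_dataset(config: PipelineConfig):
    if config.synthetic:
        synth = SynthConfig(
            n_cells_per_group=config.n_cells_per_group,
            n_genes=config.n_genes,
            effect_fold=config.effect_fold,
            seed=config.seed,
        )
        return generate_counts(synth)
    if config.counts:
        return ExpressionDataset.read_dir(config.counts), None
    if config.counts_tsv and config.meta:
        return ExpressionDataset.read_dense_tsv(config.counts_tsv, config.meta), None
    raise ValueError("config must set synthetic=true, counts, or counts_tsv+meta")


def group_pair_order(group: str) -> list[str]:
    """Canonical ordered class-pair names of a group."""
    order = CLASS_ORDER[group]
    return [
        f"{a} vs {b}" for i, a in enumerate(order) for b in order[i + 1 :]
    ]


def export_heatmap_matrix(
    records: pd.DataFrame,
    de_subset: pd.DataFrame,
    group: str,
) -> pd.DataFrame:
    """Comparison x gene matrix of signed effect sizes for heatmap rendering.

    ``records`` holds class-relevance records of one group and regionality;
    ``de_subset`` the matching regionality subset (columns gene, pair,
    avg_logFC). Columns are genes ordered by (class, direction); rows are the
    group's comparisons; cells are the signed avg_logFC where significant and
    empty (NaN) otherwise. Four annotation rows (class, direction, asterisk,
    risk) precede the comparison rows.
    """
    pairs = group_pair_order(group)
    if len(records) == 0:
        return pd.DataFrame(
            index=["class", "direction", "asterisk", "risk"] + pairs
        )
    known = set(de_subset["gene"])
    missing = set(records["gene"]) - known
    if missing:
        raise ValueError(f"records reference gene(s) absent from DE data: {sorted(missing)}")

    order = {c: i for i, c in enumerate(rel.GROUP_CANDIDATES[group])}
    rec = records.sort_values(
        by=["class", "direction", "gene"],
        key=lambda s: s.map(order) if s.name == "class" else s,
        kind="stable",
    )
    genes = list(dict.fromkeys(rec["gene"]))
    first = rec.drop_duplicates("gene").set_index("gene")

    values = de_subset.pivot_table(
        index="pair", columns="gene", values="avg_logFC", aggfunc="first"
    )
    body = pd.DataFrame(np.nan, index=pairs, columns=genes)
    for g in genes:
        if g in values.columns:
            for p in pairs:
                if p in values.index and not pd.isna(values.loc[p, g]):
                    body.loc[p, g] = values.loc[p, g]

    annot = pd.DataFrame(
        {
            g: {
                "class": first.loc[g, "class"],
                "direction": first.loc[g, "direction"],
                "asterisk": "*" if bool(first.loc[g, "asterisk"]) else "",
                "risk": "risk" if bool(first.loc[g, "risk_flag"]) else "",
            }
            for g in genes
        }
    ).reindex(["class", "direction", "asterisk", "risk"])
    return pd.concat([annot, body])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write outputs under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str, n_rows: int) -> None:
        manifest["stages"][name] = int(n_rows)
        log.info("stage %-22s rows=%d", name, n_rows)

    dataset, truth = _load_dataset(config)
    stage("dataset_cells", dataset.n_cells)
    if truth is not None:
        truth.to_csv(os.path.join(out, "truth.csv"), index=False)

    specs = build_comparison_plan(dataset, groups=config.groups)
    de = run_de_plan(dataset, specs, config.de_config(), config.norm_config())
    os.makedirs(os.path.join(out, "de"), exist_ok=True)
    for spec in specs:
        sub = de[de["comparison_id"] == spec.comparison_id]
        fname = spec.comparison_id.replace("/", "").replace(" ", "_") + ".csv"
        sub.to_csv(os.path.join(out, "de", fname), index=False)
    de.to_csv(os.path.join(out, "de_all.csv"), index=False)
    stage("de_significant_rows", len(de))

    gene_sets = ann.load_gene_sets(config.gmt) if config.gmt else None
    risk = ann.load_risk_genes(config.risk) if config.risk else None
    annotated = de
    if gene_sets is not None:
        annotated = ann.filter_circuit_related(annotated, gene_sets)
    if risk is not None:
        annotated = ann.flag_risk_genes(annotated, risk)
    annotated.to_csv(os.path.join(out, "circuit_de.csv"), index=False)
    stage("circuit_rows", len(annotated))

    within = annotated[annotated["region_scope"] != CROSS_SCOPE]
    cross = de[de["region_scope"] == CROSS_SCOPE]  # region bias uses all genes

    collapsed = collapse_within(within)
    collapsed.to_csv(os.path.join(out, "collapsed.csv"), index=False)
    stage("collapsed_rows", len(collapsed))

    summaries = summ.pair_summaries(dataset, de, specs)
    summ.build_chord_matrix(summaries).to_csv(
        os.path.join(out, "chord_all_genes.tsv"), sep="\t"
    )
    if gene_sets is not None:
        for name, members in gene_sets.sets.items():
            per = summ.pair_summaries(dataset, de, specs, universe=members)
            summ.build_chord_matrix(per).to_csv(
                os.path.join(out, f"chord_{name}.tsv"), sep="\t"
            )
    counts_tbl = summ.category_counts_by_pair(
        collapsed, circuit_filter=gene_sets is not None
    )
    counts_tbl.to_csv(os.path.join(out, "category_counts.csv"))
    stage("category_count_pairs", len(counts_tbl))

    records = rel.classify_all(collapsed)
    records.to_csv(os.path.join(out, "class_relevance.csv"), index=False)
    for regionality in ("conserved", "ALM", "VISp"):
        records[records["regionality"] == regionality].to_csv(
            os.path.join(out, f"class_relevance_{regionality}.csv"), index=False
        )
    stage("class_relevance_records", len(records))

    bias_tables = [
        rel.region_biased_genes(cross, g) for g in config.groups
    ]
    bias_tables.append(rel.origin_specific_genes(cross))
    bias = pd.concat(bias_tables, ignore_index=True)
    if gene_sets is not None and len(bias):
        bias["circuit_related"] = bias["gene"].map(
            lambda g: bool(gene_sets.labels_for(g))
        )
    bias.to_csv(os.path.join(out, "region_bias.csv"), index=False)
    stage("region_bias_records", len(bias))

    subsets = rel.regionality_subsets(collapsed)
    subset_for = {"conserved": "conserved", "ALM": "ALM-full", "VISp": "VISp-full"}
    for regionality, sub_name in subset_for.items():
        for group in config.groups:
            sub = subsets[sub_name]
            sub = sub[sub["pair"].isin(rel.GROUP_PAIRS[group])]
            rec_group = records["class"].map(
                lambda c: GLUTAMATERGIC if c == rel.IT_COMPOSITE else group_of(c)
            )
            recs = records[
                (records["regionality"] == regionality) & (rec_group == group)
            ]
            mat = export_heatmap_matrix(recs, sub, group)
            tag = f"{group}_{regionality}".replace("/", "")
            mat.to_csv(os.path.join(out, f"heatmap_{tag}.tsv"), sep="\t")

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
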