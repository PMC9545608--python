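"""Regionality categorization of analogous cross-region comparison pairs.

Every within-region comparison (e.g. "VIP vs PV" in ALM) has exactly one
analogue in the other region with identical class order. For each gene
significant in at least one member of an analogous pair, the pair of results
collapses to one categorized record:

* significant in both regions, same sign  -> ``conserved`` (avg_logFC values
  averaged into one collapsed value),
* significant in both regions, opposite signs -> ``divergent`` (both regional
  values kept; no collapsed value — the interpretation differs per region),
* significant in ALM only  -> ``ALM-specific``,
* significant in VISp only -> ``VISp-specific``.

Because input tables contain significant rows only, "significant" here simply
means "present". Gene-set labels and risk flags are carried through by union
of the source rows' annotations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GO_TERM_SEP
from .datasets import group_of
from .de import CROSS_SCOPE, ComparisonSpec

CATEGORY_CONSERVED = "conserved"
CATEGORY_DIVERGENT = "divergent"
CATEGORY_ALM = "ALM-specific"
CATEGORY_VISP = "VISp-specific"
CATEGORIES = (CATEGORY_ALM, CATEGORY_VISP, CATEGORY_CONSERVED, CATEGORY_DIVERGENT)

COLLAPSED_COLUMNS = (
    "gene",
    "class_a",
    "class_b",
    "group",
    "category",
    "avg_logFC_alm",
    "avg_logFC_visp",
    "avg_logFC_collapsed",
    "go_terms",
    "risk_flag",
    "risk_category",
)


def match_analogous(
    specs: Sequence[ComparisonSpec],
) -> list[tuple[ComparisonSpec, ComparisonSpec]]:
    """Pair each ALM within-region spec with its VISp analogue."""
    by_region: dict[str, dict[tuple[str, str], ComparisonSpec]] = {
        "ALM": {},
        "VISp": {},
    }
    for spec in specs:
        if spec.kind != "within_region":
            raise ValueError(
                f"cross-region comparison {spec.comparison_id!r} has no analogue"
            )
        by_region[spec.region][(spec.class_a, spec.class_b)] = spec
    pairs = []
    for key, alm_spec in by_region["ALM"].items():
        if key not in by_region["VISp"]:
            raise ValueError(f"no VISp analogue for ALM {alm_spec.pair_name!r}")
        pairs.append((alm_spec, by_region["VISp"][key]))
    unmatched = set(by_region["VISp"]) - set(by_region["ALM"])
    if unmatched:
        raise ValueError(f"no ALM analogue for VISp pair(s): {sorted(unmatched)}")
    return pairs


def _merge_annotations(rows: pd.DataFrame) -> tuple[str, bool, str]:
    terms: set[str] = set()
    if "go_terms" in rows:
        for t in rows["go_terms"].dropna():
            terms |= {x for x in str(t).split(GO_TERM_SEP) if x}
    risk = bool(rows["risk_flag"].any()) if "risk_flag" in rows else False
    cat = ""
    if "risk_category" in rows:
        cats = [str(c) for c in rows["risk_category"].dropna() if str(c)]
        cat = cats[0] if cats else ""
    return GO_TERM_SEP.join(sorted(terms)), risk, cat


def collapse_pair(de_alm: pd.DataFrame, de_visp: pd.DataFrame) -> pd.DataFrame:
    """Collapse one analogous comparison pair into categorized records.

    Both inputs must hold significant rows of a single within-region
    comparison, with identical ``(class_a, class_b)`` order.
    """
    frames = [t for t in (de_alm, de_visp) if len(t)]
    if not frames:
        return pd.DataFrame(columns=list(COLLAPSED_COLUMNS))
    head = frames[0].iloc[0]
    class_a, class_b = head["class_a"], head["class_b"]
    for t in frames:
        if not ((t["class_a"] == class_a) & (t["class_b"] == class_b)).all():
            raise ValueError("analogous tables must share one ordered class pair")
        if (t["avg_logFC"] == 0).any():
            raise ValueError(
                "significant row with avg_logFC exactly 0 violates the "
                "effect-size pre-filter"
            )

    alm = de_alm.set_index("gene") if len(de_alm) else pd.DataFrame()
    visp = de_visp.set_index("gene") if len(de_visp) else pd.DataFrame()
    records = []
    genes = sorted(set(alm.index) | set(visp.index))
    for gene in genes:
        in_alm, in_visp = gene in alm.index, gene in visp.index
        fc_alm = float(alm.loc[gene, "avg_logFC"]) if in_alm else np.nan
        fc_visp = float(visp.loc[gene, "avg_logFC"]) if in_visp else np.nan
        if in_alm and in_visp:
            if np.sign(fc_alm) == np.sign(fc_visp):
                category = CATEGORY_CONSERVED
                collapsed = (fc_alm + fc_visp) / 2.0
            else:
                category = CATEGORY_DIVERGENT
                collapsed = np.nan
        elif in_alm:
            category, collapsed = CATEGORY_ALM, fc_alm
        else:
            category, collapsed = CATEGORY_VISP, fc_visp
        src = pd.concat(
            [t.loc[[gene]] for t, present in ((alm, in_alm), (visp, in_visp)) if present]
        )
        go_terms, risk, risk_cat = _merge_annotations(src)
        records.append(
            {
                "gene": gene,
                "class_a": class_a,
                "class_b": class_b,
                "group": group_of(class_a),
                "category": category,
                "avg_logFC_alm": fc_alm,
                "avg_logFC_visp": fc_visp,
                "avg_logFC_collapsed": collapsed,
                "go_terms": go_terms,
                "risk_flag": risk,
                "risk_category": risk_cat,
            }
        )
    return pd.DataFrame(records, columns=list(COLLAPSED_COLUMNS))


def collapse(de_within: pd.DataFrame) -> pd.DataFrame:
    """Collapse a combined within-region DE table over every analogous pair.

    Rows are grouped by ordered class pair; the output is sorted by
    (group, class pair, gene) for deterministic, diffable CSVs.
    """
    if len(de_within) == 0:
        return pd.DataFrame(columns=list(COLLAPSED_COLUMNS))
    if (de_within["region_scope"] == CROSS_SCOPE).any():
        raise ValueError("collapse expects within-region results only")
    out = []
    for (class_a, class_b), rows in de_within.groupby(
        ["class_a", "class_b"], sort=False
    ):
        out.append(
            collapse_pair(
                rows[rows["region_scope"] == "ALM"],
                rows[rows["region_scope"] == "VISp"],
            )
        )
    table = pd.concat(out, ignore_index=True)
    return table.sort_values(
        ["group", "class_a", "class_b", "gene"], kind="stable"
    ).reset_index(drop=True)
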