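"""Class-relevant genes from set-consistency of pairwise DE results.

A gene is *class-relevant* to a neuronal class when, within one regionality
subset (conserved, ALM, or VISp) and one neurotransmitter group, it is
significant in **every** comparison of that class's fixed *class set* and sits
on the same side (consistently higher, or consistently lower) in all of them.
The class sets are:

===========  ===========================================================
L2/3 IT      L2/3 IT vs L5 IT; L2/3 IT vs L6 CT; L2/3 IT vs L5 PT
L5 IT        L2/3 IT vs L5 IT; L5 IT vs L5 PT; L5 IT vs L6 CT
IT           L2/3 IT vs L5 PT; L2/3 IT vs L6 CT; L5 IT vs L5 PT; L5 IT vs L6 CT
L5 PT        L2/3 IT vs L5 PT; L5 IT vs L5 PT; L5 PT vs L6 CT
L6 CT        L2/3 IT vs L6 CT; L5 IT vs L6 CT; L5 PT vs L6 CT
VIP          VIP vs PV; VIP vs SST
SST          SST vs PV; VIP vs SST
PV           SST vs PV; VIP vs PV
===========  ===========================================================

The composite class "IT" is considered when both L2/3 IT and L5 IT appear
among a gene's significant comparisons; when L2/3 IT, L5 IT and IT would all
emit, the single IT record supersedes the two constituent records.

A second stage reconciles regionality: class relevance is computed on the
conserved subset alone and on each region's full significant data (conserved
plus region-specific). Region records duplicating a conserved (gene, class,
direction) are pruned; a gene kept region-specifically whose *different*
(class, direction) also appears conserved is flagged with an asterisk on both
records.

Divergent datapoints never participate in class relevance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import GO_TERM_SEP
from .collapse import (
    CATEGORY_ALM,
    CATEGORY_CONSERVED,
    CATEGORY_VISP,
)
from .datasets import GABAERGIC, GLUTAMATERGIC, group_of
from .de import CROSS_SCOPE

IT_COMPOSITE = "IT"

#: class -> frozenset of comparison (class-pair) names that must be jointly
#: significant and side-consistent.
CLASS_SETS: dict[str, frozenset[str]] = {
    "L2/3 IT": frozenset({"L2/3 IT vs L5 IT", "L2/3 IT vs L6 CT", "L2/3 IT vs L5 PT"}),
    "L5 IT": frozenset({"L2/3 IT vs L5 IT", "L5 IT vs L5 PT", "L5 IT vs L6 CT"}),
    IT_COMPOSITE: frozenset(
        {"L2/3 IT vs L5 PT", "L2/3 IT vs L6 CT", "L5 IT vs L5 PT", "L5 IT vs L6 CT"}
    ),
    "L5 PT": frozenset({"L2/3 IT vs L5 PT", "L5 IT vs L5 PT", "L5 PT vs L6 CT"}),
    "L6 CT": frozenset({"L2/3 IT vs L6 CT", "L5 IT vs L6 CT", "L5 PT vs L6 CT"}),
    "VIP": frozenset({"VIP vs PV", "VIP vs SST"}),
    "SST": frozenset({"SST vs PV", "VIP vs SST"}),
    "PV": frozenset({"SST vs PV", "VIP vs PV"}),
}

#: candidate evaluation order per group (deterministic output ordering)
GROUP_CANDIDATES: dict[str, tuple[str, ...]] = {
    GLUTAMATERGIC: ("L2/3 IT", "L5 IT", IT_COMPOSITE, "L5 PT", "L6 CT"),
    GABAERGIC: ("VIP", "SST", "PV"),
}

#: valid comparison names per group, mapped to their ordered classes
PAIR_CLASSES: dict[str, tuple[str, str]] = {
    "L2/3 IT vs L5 IT": ("L2/3 IT", "L5 IT"),
    "L2/3 IT vs L5 PT": ("L2/3 IT", "L5 PT"),
    "L2/3 IT vs L6 CT": ("L2/3 IT", "L6 CT"),
    "L5 IT vs L5 PT": ("L5 IT", "L5 PT"),
    "L5 IT vs L6 CT": ("L5 IT", "L6 CT"),
    "L5 PT vs L6 CT": ("L5 PT", "L6 CT"),
    "VIP vs SST": ("VIP", "SST"),
    "VIP vs PV": ("VIP", "PV"),
    "SST vs PV": ("SST", "PV"),
}

GROUP_PAIRS: dict[str, frozenset[str]] = {
    g: frozenset(p for p, (a, _) in PAIR_CLASSES.items() if group_of(a) == g)
    for g in (GLUTAMATERGIC, GABAERGIC)
}

UP, DOWN = "up", "down"

RECORD_COLUMNS = (
    "gene",
    "class",
    "direction",
    "regionality",
    "asterisk",
    "dual_partner",
    "go_terms",
    "risk_flag",
    "risk_category",
)

REGIONALITY_CONSERVED = "conserved"


def _side_is_up(cls: str, pair: str, sign: float) -> bool:
    """Whether ``cls`` is the higher-expressing side of ``pair``."""
    a, b = PAIR_CLASSES[pair]
    if cls == a:
        return sign > 0
    if cls == b:
        return sign < 0
    if cls == IT_COMPOSITE and a in ("L2/3 IT", "L5 IT"):
        # in every IT-set comparison the IT member is listed first
        return sign > 0
    raise ValueError(f"class {cls!r} does not participate in comparison {pair!r}")


def regionality_subsets(collapsed: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a collapsed table into the inputs of the class-relevance search.

    Returns subsets keyed ``conserved``, ``ALM``, ``VISp`` (region-specific
    only), ``ALM-full`` and ``VISp-full`` (region-specific plus the region's
    side of conserved results). Divergent rows appear in none of them. Each
    subset carries columns ``gene, pair, avg_logFC`` plus annotations.
    """

    def _extract(mask: pd.Series, value_col: str) -> pd.DataFrame:
        rows = collapsed.loc[mask].copy()
        rows["pair"] = rows["class_a"] + " vs " + rows["class_b"]
        rows["avg_logFC"] = rows[value_col]
        keep = ["gene", "pair", "avg_logFC"]
        for col in ("go_terms", "risk_flag", "risk_category"):
            if col in rows:
                keep.append(col)
        return rows[keep].reset_index(drop=True)

    cat = collapsed["category"] if len(collapsed) else pd.Series(dtype=object)
    is_cons = cat == CATEGORY_CONSERVED
    is_alm = cat == CATEGORY_ALM
    is_visp = cat == CATEGORY_VISP
    return {
        "conserved": _extract(is_cons, "avg_logFC_collapsed"),
        "ALM": _extract(is_alm, "avg_logFC_alm"),
        "VISp": _extract(is_visp, "avg_logFC_visp"),
        "ALM-full": _extract(is_cons | is_alm, "avg_logFC_alm"),
        "VISp-full": _extract(is_cons | is_visp, "avg_logFC_visp"),
    }


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=list(RECORD_COLUMNS))


def identify_class_relevant(
    subset: pd.DataFrame,
    group: str | None = None,
    regionality: str = "",
) -> pd.DataFrame:
    """Find class-relevant genes in one regionality subset.

    ``subset`` needs columns ``gene``, ``pair`` (comparison name, e.g.
    ``"VIP vs PV"``) and ``avg_logFC`` (signed; positive = first class
    higher), holding significant results only. When ``group`` is given, every
    pair must belong to that group's vocabulary; otherwise both groups are
    processed independently.

    Per gene: collect its significant comparison set and the classes involved
    (adding "IT" when both L2/3 IT and L5 IT appear); for every candidate
    class whose class set is contained in the comparison set, restrict to
    those comparisons and emit a record iff the class sits on one side in all
    of them. A gene may emit several records (e.g. one class up, another
    down); exactly-one-up/one-down pairs are cross-linked as dual records.
    """
    if len(subset) == 0:
        return _empty_records()
    unknown = set(subset["pair"]) - set(PAIR_CLASSES)
    if unknown:
        raise ValueError(f"unknown comparison name(s): {sorted(unknown)}")
    if group is None:
        parts = [
            identify_class_relevant(
                subset[subset["pair"].isin(GROUP_PAIRS[g])], g, regionality
            )
            for g in (GLUTAMATERGIC, GABAERGIC)
        ]
        return pd.concat(parts, ignore_index=True)
    bad = set(subset["pair"]) - GROUP_PAIRS[group]
    if bad:
        raise ValueError(
            f"comparison(s) {sorted(bad)} are not in the {group} vocabulary"
        )

    records: list[dict] = []
    for gene, rows in subset.groupby("gene", sort=True):
        if rows["pair"].duplicated().any():
            raise ValueError(f"duplicate comparison rows for gene {gene!r}")
        signs = dict(zip(rows["pair"], rows["avg_logFC"]))
        involved: set[str] = set()
        for pair in signs:
            involved.update(PAIR_CLASSES[pair])
        if {"L2/3 IT", "L5 IT"} <= involved:
            involved.add(IT_COMPOSITE)

        gene_records: dict[str, dict] = {}
        for cls in GROUP_CANDIDATES[group]:
            if cls not in involved:
                continue
            cset = CLASS_SETS[cls]
            if not cset <= signs.keys():
                continue
            sides = [_side_is_up(cls, pair, signs[pair]) for pair in sorted(cset)]
            if all(sides):
                direction = UP
            elif not any(sides):
                direction = DOWN
            else:
                continue
            used = rows[rows["pair"].isin(cset)]
            go_terms = ""
            if "go_terms" in used:
                terms: set[str] = set()
                for t in used["go_terms"].dropna():
                    terms |= {x for x in str(t).split(GO_TERM_SEP) if x}
                go_terms = GO_TERM_SEP.join(sorted(terms))
            gene_records[cls] = {
                "gene": gene,
                "class": cls,
                "direction": direction,
                "regionality": regionality,
                "asterisk": False,
                "dual_partner": "",
                "go_terms": go_terms,
                "risk_flag": bool(used["risk_flag"].any())
                if "risk_flag" in used
                else False,
                "risk_category": next(
                    (str(c) for c in used.get("risk_category", pd.Series(dtype=object)).dropna() if str(c)),
                    "",
                ),
            }

        if {"L2/3 IT", "L5 IT", IT_COMPOSITE} <= gene_records.keys():
            del gene_records["L2/3 IT"]
            del gene_records["L5 IT"]

        recs = list(gene_records.values())
        ups = [r for r in recs if r["direction"] == UP]
        downs = [r for r in recs if r["direction"] == DOWN]
        if len(ups) == 1 and len(downs) == 1:
            ups[0]["dual_partner"] = downs[0]["class"]
            downs[0]["dual_partner"] = ups[0]["class"]
        records.extend(recs)

    if not records:
        return _empty_records()
    out = pd.DataFrame(records, columns=list(RECORD_COLUMNS))
    order = {c: i for i, c in enumerate(GROUP_CANDIDATES[group])}
    out = out.sort_values(
        by=["class", "direction", "gene"],
        key=lambda s: s.map(order) if s.name == "class" else s,
        kind="stable",
    )
    return out.reset_index(drop=True)


def reconcile_regional(
    conserved_records: pd.DataFrame,
    alm_full_records: pd.DataFrame,
    visp_full_records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Prune region records duplicated in the conserved set; flag asterisks.

    Inputs are class-relevance record tables from the conserved subset and
    from each region's full (conserved + region-specific) data. Region records
    whose (gene, class, direction) already appears conserved are removed; a
    gene that survives region-specifically while a *different* (class,
    direction) of it is conserved gets ``asterisk=True`` on both its region
    and conserved records. Idempotent.
    """

    def _keys(df: pd.DataFrame) -> set[tuple]:
        return set(zip(df["gene"], df["class"], df["direction"]))

    cons = conserved_records.copy()
    cons["regionality"] = REGIONALITY_CONSERVED
    cons_keys = _keys(cons)
    cons_genes = set(cons["gene"])

    pruned = {}
    for name, table in (("ALM", alm_full_records), ("VISp", visp_full_records)):
        t = table.copy()
        if len(t):
            keep = [
                (g, c, d) not in cons_keys
                for g, c, d in zip(t["gene"], t["class"], t["direction"])
            ]
            t = t.loc[keep].copy()
        t["regionality"] = name
        t["asterisk"] = t["gene"].isin(cons_genes) if len(t) else t.get("asterisk", False)
        pruned[name] = t.reset_index(drop=True)

    region_genes = set(pruned["ALM"]["gene"]) | set(pruned["VISp"]["gene"])
    cons["asterisk"] = cons["gene"].isin(region_genes) if len(cons) else cons.get("asterisk", False)
    return cons.reset_index(drop=True), pruned["ALM"], pruned["VISp"]


def classify_all(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Full regionality-aware class relevance on a collapsed table.

    Runs the class-relevance search on the conserved subset and on each
    region's full data, reconciles the three, and returns one concatenated
    record table (regionality in {conserved, ALM, VISp}).
    """
    subs = regionality_subsets(collapsed)
    cons = identify_class_relevant(subs["conserved"], regionality=REGIONALITY_CONSERVED)
    alm = identify_class_relevant(subs["ALM-full"], regionality="ALM")
    visp = identify_class_relevant(subs["VISp-full"], regionality="VISp")
    cons, alm, visp = reconcile_regional(cons, alm, visp)
    out = pd.concat([cons, alm, visp], ignore_index=True)
    return out[list(RECORD_COLUMNS)]


# --------------------------------------------------------------- region bias

BIAS_COLUMNS = ("gene", "group", "biased_to", "scope")

SCOPE_ALL = "all-classes"
SCOPE_VIP_ONLY = "VIP-only"
SCOPE_PV_SST_ONLY = "PV&SST-only"


def _cross_signs(cross_de: pd.DataFrame) -> dict[str, dict[str, float]]:
    """gene -> {class: avg_logFC} from cross-region significant rows."""
    if len(cross_de) and (cross_de["region_scope"] != CROSS_SCOPE).any():
        raise ValueError("expected cross-region results only")
    out: dict[str, dict[str, float]] = {}
    for gene, cls, fc in zip(
        cross_de["gene"], cross_de["class_a"], cross_de["avg_logFC"]
    ):
        out.setdefault(gene, {})[cls] = fc
    return out


def region_biased_genes(
    cross_de: pd.DataFrame,
    group: str,
    classes_tested: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Genes significant with uniform sign in every class's cross-region test.

    ALM is listed first in every cross-region comparison, so uniformly
    positive means biased to ALM, uniformly negative biased to VISp.
    ``classes_tested`` defaults to all classes of ``group``; a missing class
    is an error, since "all classes" is then unverifiable.
    """
    from .datasets import CLASS_ORDER

    required = tuple(CLASS_ORDER[group])
    if classes_tested is None:
        classes_tested = required
    missing = set(required) - set(classes_tested)
    if missing:
        raise ValueError(f"missing cross-region table(s) for: {sorted(missing)}")
    signs = _cross_signs(cross_de)
    records = []
    for gene in sorted(signs):
        per_class = {c: s for c, s in signs[gene].items() if c in required}
        if set(per_class) != set(required):
            continue
        vals = np.sign(list(per_class.values()))
        if np.all(vals > 0):
            records.append((gene, group, "ALM", SCOPE_ALL))
        elif np.all(vals < 0):
            records.append((gene, group, "VISp", SCOPE_ALL))
    return pd.DataFrame(records, columns=list(BIAS_COLUMNS))


def origin_specific_genes(cross_de: pd.DataFrame) -> pd.DataFrame:
    """Interneuron cross-region biases split by embryonic origin.

    VIP interneurons derive from the caudal ganglionic eminence; PV and SST
    share a medial origin. ``VIP-only``: significant in the VIP test and in
    neither PV nor SST. ``PV&SST-only``: significant with uniform sign in PV
    and SST and not in VIP.
    """
    signs = _cross_signs(cross_de)
    records = []
    for gene in sorted(signs):
        per_class = signs[gene]
        has = {c for c in ("VIP", "SST", "PV") if c in per_class}
        if has == {"VIP"}:
            to = "ALM" if per_class["VIP"] > 0 else "VISp"
            records.append((gene, GABAERGIC, to, SCOPE_VIP_ONLY))
        elif has == {"SST", "PV"}:
            s_pv, s_sst = np.sign(per_class["PV"]), np.sign(per_class["SST"])
            if s_pv == s_sst:
                to = "ALM" if s_pv > 0 else "VISp"
                records.append((gene, GABAERGIC, to, SCOPE_PV_SST_ONLY))
    return pd.DataFrame(records, columns=list(BIAS_COLUMNS))
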