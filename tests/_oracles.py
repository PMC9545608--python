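"""Independent brute-force oracles used only by the tests.

Each oracle re-states its rule literally and shares no code with the package:
the rank-sum oracle enumerates every group assignment; the regionality oracle
is an explicit truth table over significance/sign patterns; the class-set
oracle checks the subset and side-consistency conditions by direct
enumeration over all classes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata

# class sets restated independently (not imported from the package)
ORACLE_CLASS_SETS = {
    "L2/3 IT": {"L2/3 IT vs L5 IT", "L2/3 IT vs L6 CT", "L2/3 IT vs L5 PT"},
    "L5 IT": {"L2/3 IT vs L5 IT", "L5 IT vs L5 PT", "L5 IT vs L6 CT"},
    "IT": {"L2/3 IT vs L5 PT", "L2/3 IT vs L6 CT", "L5 IT vs L5 PT", "L5 IT vs L6 CT"},
    "L5 PT": {"L2/3 IT vs L5 PT", "L5 IT vs L5 PT", "L5 PT vs L6 CT"},
    "L6 CT": {"L2/3 IT vs L6 CT", "L5 IT vs L6 CT", "L5 PT vs L6 CT"},
    "VIP": {"VIP vs PV", "VIP vs SST"},
    "SST": {"SST vs PV", "VIP vs SST"},
    "PV": {"SST vs PV", "VIP vs PV"},
}

GABA_PAIRS = ("VIP vs SST", "VIP vs PV", "SST vs PV")
GLUT_PAIRS = (
    "L2/3 IT vs L5 IT",
    "L2/3 IT vs L5 PT",
    "L2/3 IT vs L6 CT",
    "L5 IT vs L5 PT",
    "L5 IT vs L6 CT",
    "L5 PT vs L6 CT",
)
GABA_CLASSES = ("VIP", "SST", "PV")
GLUT_CLASSES = ("L2/3 IT", "L5 IT", "IT", "L5 PT", "L6 CT")


def exact_rank_sum_p(a, b) -> float:
    """Exact two-sided rank-sum p-value by enumerating all group assignments.

    Midranks handle ties; the two-sided p is 2*min(P(W<=w), P(W>=w)) capped
    at 1, where W is the rank sum of the first group.
    """
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    ranks = rankdata(pooled)
    n = len(a)
    w_obs = ranks[:n].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n)]
    sums = np.array(sums)
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def oracle_collapse_category(alm_sign: int, visp_sign: int) -> str | None:
    """Regionality category from two significance/sign states (0 = absent)."""
    if alm_sign == 0 and visp_sign == 0:
        return None
    if alm_sign != 0 and visp_sign == 0:
        return "ALM-specific"
    if alm_sign == 0 and visp_sign != 0:
        return "VISp-specific"
    return "conserved" if alm_sign == visp_sign else "divergent"


def _oracle_side_up(cls: str, pair: str, sign: int) -> bool:
    first, second = pair.split(" vs ")
    if cls == "IT":
        # in every IT-set comparison the first-listed class is the IT member
        return sign > 0
    if cls == first:
        return sign > 0
    assert cls == second
    return sign < 0


def oracle_class_relevance(signs: dict[str, int], group: str) -> set[tuple[str, str]]:
    """(class, direction) records for one gene's significance pattern.

    ``signs`` maps comparison name -> nonzero sign for significant results
    (absent comparisons omitted). Checks every class of the group: the class
    set must be contained in the comparison set, the class side-consistent
    in all its comparisons, and the composite IT requires both constituents
    among the involved classes; when IT and both constituents would all emit,
    only IT is reported.
    """
    classes = GLUT_CLASSES if group == "glutamatergic" else GABA_CLASSES
    involved = set()
    for pair in signs:
        involved.update(pair.split(" vs "))
    out: set[tuple[str, str]] = set()
    for cls in classes:
        if cls == "IT":
            if not ({"L2/3 IT", "L5 IT"} <= involved):
                continue
        elif cls not in involved:
            continue
        cset = ORACLE_CLASS_SETS[cls]
        if not cset <= set(signs):
            continue
        sides = {_oracle_side_up(cls, pair, signs[pair]) for pair in cset}
        if sides == {True}:
            out.add((cls, "up"))
        elif sides == {False}:
            out.add((cls, "down"))
    if {("IT", "up"), ("IT", "down")} & out:
        for cls in ("L2/3 IT", "L5 IT"):
            hit = {(cls, "up"), (cls, "down")} & out
            if not hit:
                break
        else:
            out = {(c, d) for c, d in out if c not in ("L2/3 IT", "L5 IT")}
    return out
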