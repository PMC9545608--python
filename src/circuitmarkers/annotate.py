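"""Gene-set filtering and risk-gene flagging.

The analysis restricts differential-expression results to "circuit-related"
genes: members of three gene-ontology categories supplied as a GMT file —
cell-cell adhesion (CCA), regulation of cell-cell adhesion (RCCA), and
regulation of trans-synaptic signaling (RTSS). A separate CSV of risk genes
(symbol + evidence category, all categories retained) marks clinically
relevant genes.

Symbols are matched exactly after whitespace stripping, with a
case-insensitive fallback: the input mixes capitalized mouse-style symbols
(Nrxn1) with lowercase ones (nrxn1). No ortholog mapping is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

GENE_SET_NAMES = ("CCA", "RCCA", "RTSS")

GO_TERM_SEP = ";"


def _norm_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets with case-insensitive membership lookup."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {
            name: {_norm_symbol(g) for g in members}
            for name, members in self.sets.items()
        }

    def labels_for(self, gene: str) -> tuple[str, ...]:
        """Sorted names of every set containing ``gene``."""
        g = _norm_symbol(gene)
        return tuple(sorted(name for name, members in self.sets.items() if g in members))

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


@dataclass
class RiskGeneList:
    """Risk-gene symbol -> evidence-category label."""

    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.categories = {
            _norm_symbol(g): str(c) for g, c in self.categories.items()
        }

    def __contains__(self, gene: str) -> bool:
        return _norm_symbol(gene) in self.categories

    def category(self, gene: str) -> str:
        return self.categories.get(_norm_symbol(gene), "")


def load_gene_sets(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"malformed GMT line {lineno} in {path}: expected at least "
                f"3 tab-separated fields, got {len(fields)}"
            )
        name = fields[0].strip()
        members = {f for f in (x.strip() for x in fields[2:]) if f}
        sets[name] = sets.get(name, set()) | members
    return GeneSetCollection(sets)


def load_risk_genes(path: str | os.PathLike) -> RiskGeneList:
    """Read a risk-gene CSV with columns ``gene`` and ``category``."""
    df = pd.read_csv(path)
    for col in ("gene", "category"):
        if col not in df.columns:
            raise ValueError(f"risk-gene CSV missing column {col!r}")
    return RiskGeneList(dict(zip(df["gene"], df["category"])))


def filter_circuit_related(
    de_table: pd.DataFrame, sets: GeneSetCollection
) -> pd.DataFrame:
    """Keep rows whose gene belongs to any set; annotate with all matches.

    Order-preserving and idempotent; the ``go_terms`` column carries the
    matched set names joined by ``";"``.
    """
    labels = de_table["gene"].map(lambda g: sets.labels_for(g))
    out = de_table.loc[labels.map(len) > 0].copy()
    out["go_terms"] = labels.loc[out.index].map(GO_TERM_SEP.join)
    return out.reset_index(drop=True)


def flag_risk_genes(records: pd.DataFrame, risk: RiskGeneList) -> pd.DataFrame:
    """Set ``risk_flag`` / ``risk_category`` columns from the risk list."""
    out = records.copy()
    out["risk_flag"] = out["gene"].map(lambda g: g in risk)
    out["risk_category"] = out["gene"].map(risk.category)
    return out
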