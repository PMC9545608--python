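"""Expression-data container and on-disk formats.

The analysis operates on a gene x cell raw-count matrix in which every cell
carries a cortical region (ALM or VISp), a neuronal class (four excitatory
projection-neuron classes, three interneuron classes), and the neurotransmitter
group implied by the class. The class taxonomy is fixed:

* glutamatergic: L2/3 IT, L5 IT, L5 PT, L6 CT
* GABAergic: PV, SST, VIP

Counts travel as MatrixMarket (genes x cells) plus two TSV sidecars (gene
symbols; per-cell metadata), or as a single dense TSV with genes as rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

GLUT_CLASSES: tuple[str, ...] = ("L2/3 IT", "L5 IT", "L5 PT", "L6 CT")
GABA_CLASSES: tuple[str, ...] = ("VIP", "SST", "PV")
CLASSES: tuple[str, ...] = GLUT_CLASSES + GABA_CLASSES
REGIONS: tuple[str, ...] = ("ALM", "VISp")

GLUTAMATERGIC = "glutamatergic"
GABAERGIC = "GABAergic"
GROUPS: tuple[str, ...] = (GLUTAMATERGIC, GABAERGIC)

CLASS_TO_GROUP: dict[str, str] = {
    **{c: GLUTAMATERGIC for c in GLUT_CLASSES},
    **{c: GABAERGIC for c in GABA_CLASSES},
}

#: Canonical within-group ordering used to fix the direction of every pairwise
#: comparison (first class listed first in "A vs B").
CLASS_ORDER: dict[str, tuple[str, ...]] = {
    GLUTAMATERGIC: GLUT_CLASSES,
    GABAERGIC: GABA_CLASSES,  # VIP < SST < PV, i.e. "VIP vs PV", "SST vs PV"
}

CELL_META_COLUMNS = ("cell_id", "region", "class", "group")


def group_of(cls: str) -> str:
    """Neurotransmitter group of a neuronal class."""
    try:
        return CLASS_TO_GROUP[cls]
    except KeyError:
        raise ValueError(f"unknown neuronal class: {cls!r}") from None


@dataclass
class ExpressionDataset:
    """Raw counts (genes x cells) with per-cell region/class metadata.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, shape ``(n_genes, n_cells)``. Stored dense;
        the analyses here are class-level and comfortably in-memory.
    genes
        Unique gene symbols, length ``n_genes``.
    cells
        DataFrame with columns ``cell_id, region, class, group``. ``group`` may
        be omitted and is derived from ``class``.
    """

    counts: np.ndarray
    genes: np.ndarray
    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        self.genes = np.asarray(self.genes, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x cell matrix")
        if self.counts.shape[0] != len(self.genes):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but {len(self.genes)} genes"
            )
        if self.counts.shape[1] != len(self.cells):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but {len(self.cells)} cells"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        cells = self.cells.reset_index(drop=True).copy()
        for col in ("cell_id", "region", "class"):
            if col not in cells.columns:
                raise ValueError(f"cell metadata missing column {col!r}")
        bad_region = set(cells["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown region(s): {sorted(bad_region)}")
        bad_class = set(cells["class"]) - set(CLASSES)
        if bad_class:
            raise ValueError(f"unknown class(es): {sorted(bad_class)}")
        derived = cells["class"].map(CLASS_TO_GROUP)
        if "group" in cells.columns:
            if not (cells["group"] == derived).all():
                raise ValueError("cell 'group' inconsistent with class taxonomy")
        else:
            cells["group"] = derived
        self.cells = cells[list(CELL_META_COLUMNS)]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_mask(
        self,
        region: str | None = None,
        cls: str | None = None,
        group: str | None = None,
    ) -> np.ndarray:
        """Boolean mask over cells matching all given criteria."""
        mask = np.ones(self.n_cells, dtype=bool)
        if region is not None:
            mask &= (self.cells["region"] == region).to_numpy()
        if cls is not None:
            mask &= (self.cells["class"] == cls).to_numpy()
        if group is not None:
            mask &= (self.cells["group"] == group).to_numpy()
        return mask

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.genes == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0])

    # ------------------------------------------------------------------ I/O

    def write_dir(self, out_dir: str | os.PathLike) -> None:
        """Write matrix.mtx (genes x cells), genes.tsv and cells.tsv."""
        os.makedirs(out_dir, exist_ok=True)
        spio.mmwrite(
            os.path.join(out_dir, "matrix.mtx"),
            sparse.coo_matrix(self.counts.astype(np.int64)),
        )
        pd.Series(self.genes, name="gene").to_csv(
            os.path.join(out_dir, "genes.tsv"), sep="\t", index=False
        )
        self.cells.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)

    @classmethod
    def read_dir(cls, in_dir: str | os.PathLike) -> "ExpressionDataset":
        counts = spio.mmread(os.path.join(in_dir, "matrix.mtx"))
        genes = pd.read_csv(os.path.join(in_dir, "genes.tsv"), sep="\t")["gene"]
        cells = pd.read_csv(os.path.join(in_dir, "cells.tsv"), sep="\t")
        return cls(counts, genes.to_numpy(dtype=object), cells)

    @classmethod
    def read_dense_tsv(
        cls, counts_path: str | os.PathLike, meta_path: str | os.PathLike
    ) -> "ExpressionDataset":
        """Read a dense genes-as-rows TSV (first column = gene symbol)."""
        mat = pd.read_csv(counts_path, sep="\t", index_col=0)
        cells = pd.read_csv(meta_path, sep="\t")
        order = cells["cell_id"].tolist()
        mat = mat[order]
        return cls(mat.to_numpy(), mat.index.to_numpy(dtype=object), cells)
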