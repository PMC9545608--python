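# circuitmarkers

Tools for asking a specific question of class-labeled cortical single-cell
RNA-seq data: **which genes related to synaptic connectivity distinguish the
major neuronal classes, and is each gene–class relationship conserved across
cortical regions or specific to one of them?**

The package operates on a gene × cell raw-count matrix whose cells carry a
region label (ALM, the anterior lateral motor cortex, or VISp, the primary
visual cortex) and one of seven neuronal class labels — four excitatory
projection-neuron classes (L2/3 IT, L5 IT, L5 PT, L6 CT) and three
interneuron classes (PV, SST, VIP). From there it runs:

1. **Pairwise differential expression** (`circuitmarkers.de`). Counts are
   normalized per cell as `ln(count / total × 10,000 + 1)`. Every ordered
   class pair within a region, and every class across regions (ALM always
   first), is tested with a two-sided Wilcoxon rank-sum test on genes passing
   a detection filter (≥ 10 % of cells in one group) and an effect-size
   pre-filter (|avg_logFC| ≥ 0.25, natural-log fold change of
   back-transformed group means). P-values are Bonferroni-corrected over the
   gene universe; rows with adjusted p < 0.05 are reported. Because analogous
   tests in the two regions share their class order, the sign of `avg_logFC`
   is directly comparable between regions.
2. **Circuit-gene annotation** (`circuitmarkers.annotate`). Results are
   restricted to genes in supplied GMT gene sets — cell-cell adhesion (CCA),
   regulation of cell-cell adhesion (RCCA), regulation of trans-synaptic
   signaling (RTSS) — and autism risk genes from a CSV list are flagged.
3. **Regionality collapsing** (`circuitmarkers.collapse`). Each gene's
   results in an analogous comparison pair collapse to one categorized
   record: *conserved* (significant in both regions, same sign; values
   averaged), *divergent* (both regions, opposite signs; values kept),
   *ALM-specific* or *VISp-specific* (one region only).
4. **Class relevance** (`circuitmarkers.relevance`). A gene is relevant to a
   class when it is significant in every comparison of that class's fixed
   *class set* (e.g. VIP = {VIP vs PV, VIP vs SST}) with the class on one
   consistent side; a composite "IT" class captures genes shared by L2/3 IT
   and L5 IT. Relevance is computed per regionality, region records
   duplicated in the conserved set are pruned, and genes whose conserved and
   region-specific relevance point to different classes are marked with an
   asterisk. Region-bias queries find genes uniformly enriched in one region
   across all classes of a group, or only in interneurons of one embryonic
   origin (VIP vs PV/SST).
5. **Summaries and exports** (`circuitmarkers.summarize`,
   `circuitmarkers.pipeline`). Percentages of differentially expressed genes
   per pair (normalized by the genes expressed within the pair) as
   chord-diagram matrices, per-category counts per class pair, heatmap-ready
   comparison × gene matrices, and a manifest with per-stage row counts.

A synthetic-data module (`circuitmarkers.simulate`) draws negative-binomial
counts with per-cell size factors and plants genes of every output category
(conserved / region-specific class-relevant, divergent, region-biased,
origin-specific, inconsistent decoys, nulls) with a truth table, so the whole
pipeline is testable end to end without external data.

## Worked example

The class-relevance logic in miniature, on a built-in seven-gene interneuron
panel (three genes significant only between VIP and PV; four significant in
all three interneuron tests with a VIP-consistent direction):

```python
from circuitmarkers import collapse, classify_all, seven_gene_fixture

records = classify_all(collapse(seven_gene_fixture()))
print(records[["gene", "class", "direction", "regionality"]])
```

```
     gene class direction regionality
0   nrxn1   VIP        up   conserved
1  snap25   VIP        up   conserved
2   nrxn1    PV      down   conserved
3  snap25    PV      down   conserved
4   socs5   VIP        up         ALM
5   socs5    PV      down         ALM
6    pten   VIP        up        VISp
7    pten    PV      down        VISp
```

Four genes are retained as VIP-relevant (expression higher in VIP than in
both PV and SST): `nrxn1` and `snap25` in both regions, `socs5` only in ALM,
`pten` only in VISp. The significant-everywhere pattern also makes each gene
PV-relevant downward — the dual record the set logic implies. The other three
panel genes (`cyfip1`, `dlg2`, `kctd13`) are significant between VIP and PV
but not between VIP and SST, fail the VIP class set, and are discarded.

A full synthetic run from the shell:

```bash
circuitmarkers run-all --out runs/demo --seed 1
# or stage by stage:
circuitmarkers synth counts --out runs/counts --seed 1
circuitmarkers de run --counts runs/counts --out runs/de.csv
circuitmarkers collapse --de runs/de.csv --out runs/collapsed.csv
circuitmarkers classify --collapsed runs/collapsed.csv --cross runs/de.csv --out runs/
```

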