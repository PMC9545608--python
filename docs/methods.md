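# Methods

## The analysis in brief

The pipeline takes class-labeled single-cell expression counts from two
cortical regions and produces, per gene, a structured answer to "which
neuronal class differentially expresses this gene, in which direction, and
is that relationship conserved across regions?". It is a composition of a
standard marker-detection step (library-size normalization, effect-size
pre-filter, rank-sum test, Bonferroni correction) with three set-logic
stages specific to the two-region design: regionality collapsing, class-set
consistency, and conserved-vs-regional reconciliation.

## Normalization and differential expression

Counts are normalized per cell as `ln(count / cell_total × s + 1)` with
scale factor `s = 10,000` (configurable). The effect size reported for a
comparison is the natural-log fold change of back-transformed group means
with a pseudocount of one:

    avg_logFC = ln( mean_c∈A (e^x_c − 1) + 1 ) − ln( mean_c∈B (e^x_c − 1) + 1 )

computed on the normalized values `x`, positive when the first-listed group
is higher. This is the convention of 2019-era marker-detection tooling
(natural log, not log2); the sign is antisymmetric under group swap, which
the tests verify.

The significance rule per gene and comparison is, in order: (1) detection —
the gene must be detected (count > 0) in at least `min_detect_fraction`
(default 0.10) of the cells of one group; (2) effect size — |avg_logFC| ≥
0.25, applied two-sided because both enriched and depleted genes are
reported; (3) a two-sided Wilcoxon rank-sum test on the normalized values,
asymptotic normal approximation with midranks and tie-corrected variance, no
continuity correction; (4) Bonferroni adjustment `p_adj = min(1, p × N)`
with `N` the total number of genes in the dataset (not the pre-filter
survivors), and a cut at `p_adj < 0.05`. All four constants are
configuration fields with these defaults. Result tables contain significant
rows only.

**Approximation accuracy.** Against an exact-permutation reference at group
sizes ≤ 8, the asymptotic p-value tracks the exact one closely in the tail
that decisions depend on (differences of order 10⁻³ at p ≈ 10⁻³) and can
deviate by up to ~0.1 in mid-range p for heavily tied tiny samples, where no
decision is at stake. The tie-free 3-vs-3 separation case gives p = 0.0495
versus the exact 0.1 — the discreteness floor of n = 3. Degenerate input
(all pooled values identical) is defined as p = 1.

**Comparison plan.** Within each region, all class pairs within a
neurotransmitter group are tested in a fixed canonical order (glutamatergic
L2/3 IT < L5 IT < L5 PT < L6 CT; GABAergic VIP < SST < PV), and each class
is tested across regions with ALM first: 6 + 3 pairs × 2 regions + 7
cross-region = 25 comparisons. Fixing the order per pair makes signs
directly comparable between the two regions' analogous tests.

## Regionality collapsing

For each gene and analogous comparison pair, presence/sign in the two
regions maps to exactly one category:

| ALM | VISp | category | collapsed value |
|-----|------|----------|-----------------|
| sig, sign σ | sig, sign σ | conserved | mean of the two values |
| sig, sign σ | sig, sign −σ | divergent | none (both values kept) |
| sig | absent | ALM-specific | the ALM value |
| absent | sig | VISp-specific | the VISp value |

The mapping is exhaustive and mutually exclusive over the 8 non-trivial
patterns (verified by enumeration against an independent truth table).
Divergent results keep both regional values because their interpretation
differs per region. Gene-set labels and risk flags are merged by union.

## Class relevance (class-set consistency)

Each class has a fixed *class set* of comparisons that must all be
significant with the class on one consistent side:

    L2/3 IT: {L2/3 IT vs L5 IT, L2/3 IT vs L6 CT, L2/3 IT vs L5 PT}
    L5 IT:   {L2/3 IT vs L5 IT, L5 IT vs L5 PT, L5 IT vs L6 CT}
    IT:      {L2/3 IT vs L5 PT, L2/3 IT vs L6 CT, L5 IT vs L5 PT, L5 IT vs L6 CT}
    L5 PT:   {L2/3 IT vs L5 PT, L5 IT vs L5 PT, L5 PT vs L6 CT}
    L6 CT:   {L2/3 IT vs L6 CT, L5 IT vs L6 CT, L5 PT vs L6 CT}
    VIP:     {VIP vs PV, VIP vs SST}
    SST:     {SST vs PV, VIP vs SST}
    PV:      {SST vs PV, VIP vs PV}

Per gene and regionality subset the algorithm collects the comparisons in
which the gene is significant, adds the composite IT candidate when both
L2/3 IT and L5 IT are involved, and emits a record for every class whose set
is contained in the gene's comparison set with a consistent side (up =
higher than every other class in the set, down = lower). A gene may emit
several records; an exactly-one-up/one-down pair is cross-linked as a dual
record. Divergent datapoints never participate.

Two structural facts, established by exhaustive enumeration in the test
suite, are worth knowing. First, the IT composite never needs to "supersede"
both constituents: the L2/3 IT and L5 IT class sets share the L2/3-vs-L5
comparison, on which the two classes necessarily take opposite sides, so
same-direction records for both constituents cannot coexist (the supersede
rule is implemented but is a no-op safety net). Second, a gene significant
in all three interneuron comparisons always yields two records (e.g. VIP up
and one of SST/PV down) — the set logic is closed under complementation, so
single-record expectations apply only to genes significant in exactly one
class set.

## Conserved-vs-regional reconciliation

Class relevance is computed three times: on the conserved subset alone, and
on each region's *full* significant data — conserved plus that region's
specific results, using the region's own effect sizes. The full-region runs
are necessary because a region's class relevance can rest on a mixture of
conserved and region-specific comparisons. Region records whose (gene,
class, direction) already appears conserved are pruned as redundant; a gene
that survives region-specifically while a *different* (class, direction) of
it is conserved is flagged with an asterisk on both records. The operation
is idempotent. The interneuron worked example: a gene significant in all
three ALM tests but only VIP-vs-PV and SST-vs-PV in VISp reconciles to an
asterisked ALM "VIP up" record plus an asterisked conserved "PV down"
record.

## Region-bias queries

On the cross-region tests (ALM listed first), a gene is *region-biased* for
a group when it is significant with uniform sign in every class of the group
(positive → ALM, negative → VISp). Origin-restricted variants for
interneurons: *VIP-only* (significant for VIP, not PV or SST — the
caudal-ganglionic-eminence lineage) and *PV&SST-only* (uniform sign in PV
and SST, absent in VIP — the medial lineage).

## Summaries

DE percentages are normalized per pair by the number of genes *expressed*
within the pair (nonzero total count over the union of the two groups'
cells, equivalent to average expression > 0 and computed on raw counts) and
reported to one decimal with half-up rounding; full precision is kept
internally. The chord matrix places the 25 pair percentages symmetrically on
the 14 (region, class) nodes; untested pairs are empty (NaN), distinct from
an observed 0.0. Per-gene-set matrices restrict both numerator and
denominator to the set. Heatmap exports use empty fields, not 0, for
non-significant cells — significance implies |avg_logFC| ≥ 0.25, so 0 is
never a legal value there.

## Synthetic data

The generator draws counts `NB(mean = μ·f·σ_c, dispersion θ)` per gene and
cell, with baseline mean μ = 2.0, dispersion θ = 2.0 (variance μ + μ²/θ —
moderate overdispersion typical of full-length single-cell protocols),
per-cell log-normal size factors with unit mean and CV 0.3, and a
multiplicative fold `f` (default 4, reciprocal for down effects) on the
(region, class) groups that encode a planted gene's category. 200 cells per
group by default — the order of the smaller class-region groups in the data
this structure emulates. At fold 4 the expected avg_logFC (≈ ln 4 ≈ 1.39)
comfortably exceeds the 0.25 pre-filter, and the rank-sum test at 200 + 200
cells is essentially saturated, so planted recovery probes the set logic
rather than borderline test power.

Planted categories map one-to-one onto the pipeline's output vocabulary.
Two constructions deserve comment. *Divergent* genes are elevated in class A
in ALM and class B in VISp for one comparison pair, which yields the
opposite-sign pattern (plus region-specific side effects in other
comparisons — harmless, as a single comparison never satisfies a class set).
*Inconsistent decoys* cannot be produced by class-level folds within a
region — any consistent elevation pattern legitimately satisfies some class
set — so decoys are planted as VIP-elevated in ALM and SST-elevated in VISp:
their shared VIP-vs-SST comparison collapses to divergent and is excluded,
leaving each regional subset with a strict subset of every class set. Decoys
are therefore significant in several tests yet never class-relevant, which
is exactly the failure mode the class-set rule exists to reject.

What the generator does **not** emulate: zero-inflation beyond the NB model,
gene–gene correlation, batch effects, read-depth profiles of any particular
platform, or realistic library-size distributions. Passing recovery tests
therefore demonstrates the correctness of the statistical rule and the set
logic under the stated model, not robustness to real-data artifacts.

## Problem sizes used in tests and the acceptance script

Unit and integration tests run on reduced problems (5–60 cells per group,
40–120 genes) chosen so every code path executes in seconds; the recovery
study runs at the full default conditions (200 cells per group, 300 genes,
20 planted genes per regionality category, 5 decoys) where per-category
sensitivity is expected at ≥ 95 % — in practice 100 % across seeds, since
fold-4 effects at these sample sizes are far from the decision boundary.
Null calibration uses 200 genes × 50 cells per group with no planted
effects; with the effect-size pre-filter and Bonferroni correction the
observed fraction of significant (gene, comparison) pairs is ~10⁻⁴ or
below, well under the nominal 0.05.

## Known limitations

- The Bonferroni multiplier and the two-sidedness of the pre-filter are
  conventions of the emulated tooling, exposed as configuration; other
  choices change the significant set.
- Symbol matching between counts, gene sets and risk lists is exact
  (case-insensitive) string matching; no ortholog or alias resolution.
- The class taxonomy (7 classes, 2 regions) is fixed; datasets must contain
  every (region, class) combination for the full plan.
- Statistical enrichment of gene sets is out of scope: the package consumes
  gene lists, it does not derive them.
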