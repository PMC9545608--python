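"""Differential-expression engine: normalization, fold change, rank-sum test,
comparison plan, and the full significance rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circuitmarkers.datasets import ExpressionDataset, GLUT_CLASSES
from circuitmarkers.de import (
    ComparisonSpec,
    DETestConfig,
    NormalizationConfig,
    average_log_fold_change,
    build_comparison_plan,
    log_normalize,
    run_de_plan,
    run_de_test,
    wilcoxon_rank_sum,
)

from _oracles import exact_rank_sum_p


class TestLogNormalize:
    def test_hand_evaluated_values(self):
        # one cell expressing a single gene; one cell with count 5 of 10,000
        counts = np.array([[7, 5], [0, 9995]])
        norm = log_normalize(counts, NormalizationConfig())
        assert norm[1, 0] == 0.0  # zero count -> ln(1) = 0
        assert norm[0, 0] == pytest.approx(math.log(10_001), abs=1e-9)
        assert norm[0, 1] == pytest.approx(math.log(6), abs=1e-9)

    def test_zero_total_cell_is_named(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c2"):
            log_normalize(counts, cell_ids=["c1", "c2"])

    def test_scale_factor_validated(self):
        with pytest.raises(ValueError):
            NormalizationConfig(scale_factor=0)


class TestAverageLogFoldChange:
    def test_back_transformed_means(self):
        # group means of expm1(x) are 3.0 and 1.0 -> ln(4) - ln(2) = ln(2)
        a = np.log1p(np.array([2.0, 4.0]))
        b = np.log1p(np.array([1.0, 1.0]))
        assert average_log_fold_change(a, b) == pytest.approx(math.log(2))

    def test_identical_groups_zero(self):
        x = np.log1p(np.array([1.0, 5.0, 2.0]))
        assert average_log_fold_change(x, x) == pytest.approx(0.0)

    @given(
        st.lists(st.floats(0, 50), min_size=1, max_size=8),
        st.lists(st.floats(0, 50), min_size=1, max_size=8),
    )
    def test_antisymmetry(self, raw_a, raw_b):
        a, b = np.log1p(np.array(raw_a)), np.log1p(np.array(raw_b))
        fwd = average_log_fold_change(a, b)
        rev = average_log_fold_change(b, a)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestWilcoxonRankSum:
    def test_identical_multisets_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 3.0])
        assert wilcoxon_rank_sum(a, a.copy()) == pytest.approx(1.0, abs=0.05)

    def test_constant_equal_groups(self):
        assert wilcoxon_rank_sum(np.zeros(5), np.zeros(7)) == 1.0

    def test_fully_separated_small_groups(self):
        # exact enumeration over all 20 rank assignments gives p = 0.1
        p = wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1, abs=0.051)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 9, size=2)
        a = rng.integers(0, 6, size=na).astype(float)  # heavy ties
        b = rng.integers(0, 8, size=nb).astype(float)
        p_approx = wilcoxon_rank_sum(a, b)
        p_exact = exact_rank_sum_p(a, b)
        # the normal approximation tracks the exact null tightly where it
        # matters (small p); in mid-range p the discreteness of tiny tied
        # samples allows gaps up to ~0.12
        assert abs(p_approx - p_exact) <= max(0.06, 0.15 * p_exact)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 10))
        b = rng.normal(size=(4, 12))
        vec = wilcoxon_rank_sum(a, b)
        for i in range(4):
            assert vec[i] == pytest.approx(wilcoxon_rank_sum(a[i], b[i]))


class TestComparisonPlan:
    def test_full_plan_has_25_ordered_specs(self, tiny_dataset):
        specs = build_comparison_plan(tiny_dataset)
        assert len(specs) == 25
        within = [s for s in specs if s.kind == "within_region"]
        cross = [s for s in specs if s.kind == "cross_region"]
        assert len(within) == 18 and len(cross) == 7
        # analogous ALM/VISp specs carry identical class order
        alm = {s.pair_name: s for s in within if s.region == "ALM"}
        visp = {s.pair_name: s for s in within if s.region == "VISp"}
        assert alm.keys() == visp.keys()
        for name in alm:
            assert (alm[name].class_a, alm[name].class_b) == (
                visp[name].class_a,
                visp[name].class_b,
            )
        assert all(s.class_a == s.class_b for s in cross)

    def test_glutamatergic_only_plan(self):
        specs = build_comparison_plan(groups=("glutamatergic",))
        assert len(specs) == 6 * 2 + 4
        assert {s.pair_name for s in specs if s.kind == "within_region"} == {
            f"{a} vs {b}"
            for i, a in enumerate(GLUT_CLASSES)
            for b in GLUT_CLASSES[i + 1 :]
        }

    def test_missing_class_errors(self, tiny_dataset):
        keep = tiny_dataset.cells["class"] != "VIP"
        trimmed = ExpressionDataset(
            tiny_dataset.counts[:, keep.to_numpy()],
            tiny_dataset.genes,
            tiny_dataset.cells[keep],
        )
        with pytest.raises(ValueError, match="VIP"):
            build_comparison_plan(trimmed)

    def test_canonical_gaba_order(self):
        specs = build_comparison_plan(groups=("GABAergic",))
        names = [s.pair_name for s in specs if s.kind == "within_region" and s.region == "ALM"]
        assert names == ["VIP vs SST", "VIP vs PV", "SST vs PV"]


class TestRunDETest:
    def _planted_dataset(self, fold=6.0, n=40, seed=11):
        # enough null genes that the planted boost does not distort the
        # per-cell library sizes (compositional effect of the normalization)
        rng = np.random.default_rng(seed)
        genes = np.array(["planted"] + [f"null{i}" for i in range(24)], dtype=object)
        rows = []
        for region in ("ALM", "VISp"):
            for cls in ("VIP", "SST", "PV", "L2/3 IT", "L5 IT", "L5 PT", "L6 CT"):
                for i in range(n):
                    tag = cls.replace("/", "").replace(" ", "")
                    rows.append((f"{region}_{tag}_{i}", region, cls))
        cells = pd.DataFrame(rows, columns=["cell_id", "region", "class"])
        lam = np.full((len(genes), len(cells)), 5.0)
        boosted = (cells["class"] == "VIP").to_numpy()
        lam[0, boosted] *= fold
        counts = rng.poisson(lam)
        return ExpressionDataset(counts, genes, cells)

    def test_planted_gene_detected_with_positive_sign(self):
        ds = self._planted_dataset()
        spec = ComparisonSpec("within_region", "VIP", "PV", region="ALM")
        table = run_de_test(ds, spec, DETestConfig())
        assert list(table["gene"]) == ["planted"]
        assert (table["avg_logFC"] > 0).all()
        assert (table["p_adj"] < 0.05).all()

    def test_sign_convention_swap_negates(self):
        ds = self._planted_dataset()
        spec = ComparisonSpec("within_region", "VIP", "PV", region="ALM")
        fwd = run_de_test(ds, spec)
        rev = run_de_test(ds, spec.swapped())
        merged = fwd.merge(rev, on="gene", suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) > 0
        assert np.allclose(merged["avg_logFC_f"], -merged["avg_logFC_r"])
        assert np.allclose(merged["p_raw_f"], merged["p_raw_r"])

    def test_filter_monotonicity(self):
        ds = self._planted_dataset(fold=2.0)
        spec = ComparisonSpec("within_region", "VIP", "SST", region="ALM")
        base = run_de_test(ds, spec, DETestConfig(logfc_threshold=0.0, alpha=0.2))
        tighter_fc = run_de_test(ds, spec, DETestConfig(logfc_threshold=0.5, alpha=0.2))
        tighter_alpha = run_de_test(ds, spec, DETestConfig(logfc_threshold=0.0, alpha=0.01))
        assert set(tighter_fc["gene"]) <= set(base["gene"])
        assert set(tighter_alpha["gene"]) <= set(base["gene"])

    def test_empty_group_errors(self, tiny_dataset):
        spec = ComparisonSpec("within_region", "VIP", "PV", region="ALM")
        keep = ~((tiny_dataset.cells["class"] == "VIP") & (tiny_dataset.cells["region"] == "ALM"))
        trimmed = ExpressionDataset(
            tiny_dataset.counts[:, keep.to_numpy()],
            tiny_dataset.genes,
            tiny_dataset.cells[keep],
        )
        with pytest.raises(ValueError, match="empty group"):
            run_de_test(trimmed, spec)

    def test_null_dataset_yields_no_rows(self, small_synth):
        # family-wise control: an all-null comparison should emit ~nothing
        ds, truth = small_synth
        null_genes = set(truth.loc[truth["category"] == "null", "gene"])
        table = run_de_plan(ds)
        null_rows = table[table["gene"].isin(null_genes)]
        n_tests = 25 * len(null_genes)
        assert len(null_rows) / n_tests <= 0.05


def test_full_pipeline_matches_permutation_oracle_on_tiny_groups():
    """Significant sets agree with an exact-permutation reimplementation on
    groups of <= 8 cells, away from the decision boundary."""
    rng = np.random.default_rng(42)
    n_genes, na, nb = 20, 7, 8
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    rows = [(f"ALM_VIP_{i}", "ALM", "VIP") for i in range(na)]
    rows += [(f"ALM_PV_{i}", "ALM", "PV") for i in range(nb)]
    # pad the remaining (region, class) groups so the dataset validates
    for region in ("ALM", "VISp"):
        for cls in ("L2/3 IT", "L5 IT", "L5 PT", "L6 CT", "VIP", "SST", "PV"):
            if region == "ALM" and cls in ("VIP", "PV"):
                continue
            tag = cls.replace("/", "").replace(" ", "")
            rows += [(f"pad_{region}_{tag}_{i}", region, cls) for i in range(2)]
    cells = pd.DataFrame(rows, columns=["cell_id", "region", "class"])
    lam = np.full((n_genes, len(cells)), 4.0)
    vip = (cells["class"] == "VIP").to_numpy() & cells["cell_id"].str.startswith("ALM_").to_numpy()
    lam[:8, vip] *= 8.0  # strong planted effects in 8 genes
    counts = rng.poisson(lam)
    ds = ExpressionDataset(counts, genes, cells)

    config = DETestConfig()
    spec = ComparisonSpec("within_region", "VIP", "PV", region="ALM")
    table = run_de_test(ds, spec, config)
    package_sig = set(table["gene"])

    # oracle: same pre-filters, exact permutation p-values
    mask_a = ds.cell_mask(region="ALM", cls="VIP") & ~cells["cell_id"].str.startswith("pad").to_numpy()
    mask_b = ds.cell_mask(region="ALM", cls="PV") & ~cells["cell_id"].str.startswith("pad").to_numpy()
    norm = log_normalize(ds.counts)
    oracle_sig, boundary = set(), set()
    for gi, gene in enumerate(genes):
        pct = max((ds.counts[gi, mask_a] > 0).mean(), (ds.counts[gi, mask_b] > 0).mean())
        if pct < config.min_detect_fraction:
            continue
        fc = average_log_fold_change(norm[gi, mask_a], norm[gi, mask_b])
        if abs(fc) < config.logfc_threshold:
            continue
        p_exact = exact_rank_sum_p(norm[gi, mask_a], norm[gi, mask_b])
        p_adj = min(1.0, p_exact * n_genes)
        if p_adj < config.alpha:
            oracle_sig.add(gene)
        # genes whose exact adjusted p sits near the threshold may flip under
        # the normal approximation; exclude that band from the comparison
        if config.alpha / 5 < p_adj < config.alpha * 5:
            boundary.add(gene)
    assert package_sig - boundary == oracle_sig - boundary
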