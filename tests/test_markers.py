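"""Rank-sum testing and marker detection, against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

import trichoflow as tf
from oracles import monte_carlo_p, permutation_oracle
from trichoflow.markers import find_upregulated


class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        u, p = tf.wilcoxon_rank_sum([1, 2, 3], [3, 1, 2], mode="exact")
        assert p == 1.0

    def test_small_case_matches_enumeration(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        _, p = tf.wilcoxon_rank_sum(x, y, mode="exact")
        assert p == pytest.approx(permutation_oracle(x, y))
        assert p == pytest.approx(2 / 6)

    @pytest.mark.parametrize("seed,n_x,n_y,tied", [
        (0, 3, 4, False), (1, 2, 5, True), (2, 4, 4, True),
        (3, 5, 6, False), (4, 1, 6, True),
    ])
    def test_exact_mode_matches_permutation_oracle(self, seed, n_x, n_y, tied):
        rng = np.random.default_rng(seed)
        draw = (lambda n: rng.integers(0, 4, n).astype(float)) if tied \
            else (lambda n: rng.normal(size=n))
        x, y = draw(n_x), draw(n_y)
        _, p = tf.wilcoxon_rank_sum(x, y, mode="exact")
        assert p == pytest.approx(permutation_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_approximate_p_close_to_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1, 30)
        y = rng.normal(0.0, 1, 50)
        _, p = tf.wilcoxon_rank_sum(x, y, mode="approx")
        assert abs(p - monte_carlo_p(x, y, seed=seed)) < 0.02

    def test_exact_and_approx_agree_on_small_samples(self):
        """The normal approximation tracks the exact p even at tiny n
        (agreement to ~0.05 for continuous data; midrank ties coarsen
        the exact null so the bound is looser there)."""
        rng = np.random.default_rng(10)
        for _ in range(30):
            x, y = rng.normal(size=5), rng.normal(size=6)
            _, p_exact = tf.wilcoxon_rank_sum(x, y, mode="exact")
            _, p_approx = tf.wilcoxon_rank_sum(x, y, mode="approx")
            assert abs(p_exact - p_approx) < 0.05
        for _ in range(30):
            x = rng.integers(0, 5, 5).astype(float)
            y = rng.integers(0, 5, 6).astype(float)
            _, p_exact = tf.wilcoxon_rank_sum(x, y, mode="exact")
            _, p_approx = tf.wilcoxon_rank_sum(x, y, mode="approx")
            assert abs(p_exact - p_approx) < 0.2

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 6, 40).astype(float)
        y = rng.integers(0, 8, 55).astype(float)
        u, p = tf.wilcoxon_rank_sum(x, y, mode="approx")
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        x = rng.normal(1, 1, 25)
        y = rng.normal(0, 1, 30)
        _, p1 = tf.wilcoxon_rank_sum(x, y)
        _, p2 = tf.wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_all_identical_values_give_p_one(self):
        _, p = tf.wilcoxon_rank_sum([2.0] * 20, [2.0] * 30, mode="approx")
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            tf.wilcoxon_rank_sum([], [1.0])


class TestLog2FC:
    def test_identical_groups_give_zero(self):
        X = sp.csr_matrix(np.tile([[1.0, 2.0, 0.0]], (10, 1)))
        fc = tf.compute_log2fc(X, np.arange(5), np.arange(5, 10))
        np.testing.assert_allclose(fc, 0.0, atol=1e-12)

    def test_threshold_equals_printed_fold_factor(self):
        assert round(2 ** 0.36, 2) == 1.28

    def test_matches_hand_computation(self):
        X = np.log1p(np.array([
            [4.0, 0.0], [2.0, 1.0], [0.0, 3.0], [1.0, 1.0],
        ]))
        fc = tf.compute_log2fc(sp.csr_matrix(X), np.array([0, 1]), np.array([2, 3]))
        expected = np.log2((np.array([3.0, 0.5]) + 1) / (np.array([0.5, 2.0]) + 1))
        np.testing.assert_allclose(fc, expected, atol=1e-10)


class TestFindUpregulated:
    @pytest.fixture(scope="class")
    def de_fixture(self):
        rng = np.random.default_rng(13)
        n, g = 120, 40
        counts = rng.poisson(2.0, size=(n, g)).astype(float)
        labels = np.repeat([0, 1, 2], n // 3)
        counts[labels == 1, :5] += rng.poisson(6.0, size=(n // 3, 5))
        norm = tf.normalize_log1p(sp.csr_matrix(counts + (counts.sum(1, keepdims=True) == 0)))
        genes = np.array([f"g{j:02d}" for j in range(g)])
        return norm, labels, genes

    def test_spiked_genes_pass_in_their_cluster(self, de_fixture):
        norm, labels, genes = de_fixture
        table = find_upregulated(norm, labels, genes=genes)
        passing = table[(table["cluster"] == 1) & table["passed"]]
        assert {"g00", "g01", "g02", "g03", "g04"} <= set(passing["gene"])

    def test_pass_flag_self_consistent(self, de_fixture):
        norm, labels, genes = de_fixture
        t = find_upregulated(norm, labels, genes=genes)
        recomputed = (
            (t["log2fc"] >= 0.36) & (t["p_value"] <= 0.01) & (t["pct_in"] >= 0.25)
        )
        assert (t["passed"] == recomputed).all()

    def test_low_expressing_fraction_fails_min_pct(self):
        rng = np.random.default_rng(14)
        n = 200
        counts = rng.poisson(1.0, size=(n, 10)).astype(float) + 1
        labels = np.repeat([0, 1], n // 2)
        # gene 0: huge fold but expressed in only 24% of the target cluster
        counts[:, 0] = 0
        in_cluster = np.flatnonzero(labels == 1)
        expressing = in_cluster[: int(0.24 * len(in_cluster))]
        counts[expressing, 0] = 60
        norm = tf.normalize_log1p(sp.csr_matrix(counts))
        table = find_upregulated(norm, labels, genes=np.array([f"g{j}" for j in range(10)]))
        row = table[(table["cluster"] == 1) & (table["gene"] == "g0")].iloc[0]
        assert row["pct_in"] < 0.25
        assert not row["passed"]

    def test_small_cluster_flagged_low_power(self):
        rng = np.random.default_rng(15)
        counts = rng.poisson(3.0, size=(23, 8)) + 1
        labels = np.array([0] * 21 + [1] * 2)
        norm = tf.normalize_log1p(sp.csr_matrix(counts.astype(float)))
        table = find_upregulated(norm, labels)
        assert table[table["cluster"] == 1]["low_power"].all()
        assert not table[table["cluster"] == 0]["low_power"].any()

    def test_deterministic_ordering(self, de_fixture):
        norm, labels, genes = de_fixture
        t = find_upregulated(norm, labels, genes=genes)
        for _, group in t.groupby("cluster"):
            assert (group["log2fc"].diff().dropna() <= 1e-12).all()

    def test_single_cluster_rejected(self, de_fixture):
        norm, _, genes = de_fixture
        with pytest.raises(ValueError, match="2 clusters"):
            find_upregulated(norm, np.zeros(norm.shape[0], dtype=int), genes=genes)


class TestMarkerRecovery:
    def test_simulated_markers_recovered(self, default_run):
        """>= 90% of each type's markers pass in that type's cluster and
        non-marker genes rarely pass."""
        r = default_run.result
        truth = default_run.sim.truth
        passing = r.de_table[r.de_table["passed"]]
        rates = []
        for c in np.unique(r.cluster_labels):
            majority = default_run.majority_type(c)
            if majority not in truth.markers_by_type:
                continue
            markers = set(truth.markers_by_type[majority])
            found = set(passing[passing["cluster"] == c]["gene"])
            rates.append(len(markers & found) / len(markers))
        assert np.mean(rates) >= 0.9

        special = {g for gs in truth.markers_by_type.values() for g in gs}
        special |= {g for gs in truth.phase_genes.values() for g in gs}
        background = r.de_table[~r.de_table["gene"].isin(special)]
        assert background["passed"].mean() <= 0.02
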