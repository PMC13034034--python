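"""Transitional clusters, pseudotime, trends and branch contrasts."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

import trichoflow as tf


def y_shape_points(rng, n_per_arm=120, noise=0.05):
    """Geometric Y: trunk along +x, two arms diverging after x=1."""
    t = rng.uniform(0, 1, n_per_arm)
    trunk = np.column_stack([t, np.zeros(n_per_arm)])
    t2 = rng.uniform(0, 1, n_per_arm)
    arm_a = np.column_stack([1 + t2, t2])
    t3 = rng.uniform(0, 1, n_per_arm)
    arm_b = np.column_stack([1 + t3, -t3])
    X = np.vstack([trunk, arm_a, arm_b])
    X = X + rng.normal(scale=noise, size=X.shape)
    labels = np.array([0] * n_per_arm + [1] * n_per_arm + [2] * n_per_arm)
    times = np.concatenate([t, 1 + t2, 1 + t3])
    return X, labels, times


class TestDetectTransitional:
    def test_printed_ratios_fall_inside_default_window(self):
        lo, hi = tf.PipelineConfig().transitional_ratio_window
        for ratio in (0.93, 1.65, 1.49):
            assert lo <= ratio <= hi

    def test_single_class_cluster_never_flagged(self):
        rng = np.random.default_rng(0)
        n = 60
        X = sp.csr_matrix(rng.poisson(2.0, size=(n, 40)).astype(float))
        genes = np.array([f"g{j}" for j in range(40)])
        clusters = np.array([0] * 30 + [1] * 30)
        samples = np.array(["CL-1"] * 30 + ["CT"] * 30)  # cluster 0 pure CL
        report = tf.detect_transitional_clusters(
            clusters, samples, list(genes[:5]), list(genes[5:10]), X, genes
        )
        assert not report.set_index("cluster").loc[0, "transitional"]
        assert np.isinf(report.set_index("cluster").loc[0, "cl_ct_ratio"])

    def test_symmetric_in_marker_sets(self):
        rng = np.random.default_rng(1)
        X = sp.csr_matrix(rng.poisson(2.0, size=(80, 30)).astype(float))
        genes = np.array([f"g{j}" for j in range(30)])
        clusters = rng.integers(0, 3, 80)
        samples = rng.choice(["CL-1", "CT"], 80)
        a = tf.detect_transitional_clusters(
            clusters, samples, list(genes[:5]), list(genes[5:10]), X, genes
        )
        b = tf.detect_transitional_clusters(
            clusters, samples, list(genes[5:10]), list(genes[:5]), X, genes
        )
        pd.testing.assert_series_equal(a["transitional"], b["transitional"])

    def test_missing_sample_class_rejected(self):
        X = sp.csr_matrix(np.ones((10, 5)))
        genes = np.array(list("abcde"))
        with pytest.raises(ValueError, match="classes"):
            tf.detect_transitional_clusters(
                np.zeros(10, int), np.array(["CL-1"] * 10),
                ["a"], ["b"], X, genes,
            )

    def test_true_transitional_cluster_flagged(self, default_run):
        report = default_run.result.transitional
        flagged = set(report.loc[report["transitional"], "cluster"])
        tc_clusters = {
            c for c in np.unique(default_run.result.cluster_labels)
            if default_run.majority_type(c) == "transitional"
        }
        ep_tr = {
            c for c in np.unique(default_run.result.cluster_labels)
            if default_run.majority_type(c) in ("epidermis", "trichome")
        }
        assert flagged == tc_clusters
        assert not (flagged & ep_tr)


class TestComputePseudotime:
    def test_line_recovered_perfectly(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 10, 200))
        X = np.column_stack([t, np.zeros(200)])
        clusters = (t > 0.5).astype(int)  # root cluster at one end
        traj = tf.compute_pseudotime(X, clusters, root_cluster=0,
                                     n_landmarks=20, seed=0)
        rho = spearmanr(traj.pseudotime, t).statistic
        assert rho > 0.99

    def test_path_graph_gives_two_states_with_warning(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 10, 150)
        X = np.column_stack([t, 0.01 * rng.normal(size=150)])
        with pytest.warns(UserWarning, match="two states"):
            traj = tf.compute_pseudotime(X, (t > 1).astype(int), 0,
                                         n_landmarks=12, seed=1)
        assert traj.n_states == 2
        assert traj.branch_landmark is None

    def test_geometric_y_gives_three_states_and_branch(self):
        rng = np.random.default_rng(4)
        X, arms, times = y_shape_points(rng)
        clusters = arms.copy()
        traj = tf.compute_pseudotime(X, clusters, root_cluster=0,
                                     n_landmarks=25, seed=2)
        assert traj.n_states == 3
        assert traj.branch_landmark is not None
        # arm cells separate into states 2/3; trunk mostly state 1
        arm_states = traj.state[arms > 0]
        assert np.mean(arm_states > 1) > 0.8
        acc = max(
            np.mean((arms[arms > 0] == 1) == (arm_states == 2)),
            np.mean((arms[arms > 0] == 1) == (arm_states == 3)),
        )
        assert acc > 0.9
        rho = spearmanr(traj.pseudotime, times).statistic
        assert rho > 0.9

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(5)
        X, arms, _ = y_shape_points(rng, n_per_arm=80)
        traj = tf.compute_pseudotime(X, arms, 0, n_landmarks=15, seed=3)
        perm = rng.permutation(len(X))
        traj_p = tf.compute_pseudotime(X[perm], arms[perm], 0,
                                       n_landmarks=15, seed=3)
        np.testing.assert_allclose(traj.pseudotime[perm], traj_p.pseudotime,
                                   atol=1e-9)

    def test_pseudotime_nonnegative_zero_at_root(self):
        rng = np.random.default_rng(6)
        X, arms, _ = y_shape_points(rng, n_per_arm=60)
        traj = tf.compute_pseudotime(X, arms, 0, n_landmarks=12, seed=4)
        assert traj.pseudotime.min() >= 0
        at_root = traj.landmark_of_cell == traj.root_landmark
        # root-landmark cells carry no geodesic component: their
        # pseudotime is bounded by their distance to the landmark
        d = np.linalg.norm(X[at_root] - traj.landmarks[traj.root_landmark], axis=1)
        assert np.all(traj.pseudotime[at_root] <= d + 1e-9)

    def test_mst_weight_matches_prim_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3))
        # every point its own landmark: n_landmarks == n points
        traj = tf.compute_pseudotime(pts, np.zeros(10, int), 0,
                                     n_landmarks=10, seed=5)
        # independent Prim implementation
        from scipy.spatial.distance import cdist
        D = cdist(traj.landmarks, traj.landmarks)
        in_tree = {0}
        total = 0.0
        while len(in_tree) < len(D):
            best = min(
                ((D[i, j], j) for i in in_tree for j in range(len(D))
                 if j not in in_tree),
            )
            total += best[0]
            in_tree.add(best[1])
        assert traj.mst_edges[:, 2].sum() == pytest.approx(total, rel=1e-9)

    def test_missing_root_cluster_rejected(self):
        with pytest.raises(ValueError, match="root"):
            tf.compute_pseudotime(np.zeros((10, 2)), np.zeros(10, int), 5)


class TestGeneTrends:
    def test_three_sigmoid_classes_separated(self, default_run):
        sim = default_run.sim
        r = default_run.result
        genes3 = (sim.truth.markers_by_type["epidermis"]
                  + sim.truth.markers_by_type["transitional"]
                  + sim.truth.markers_by_type["trichome"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assign, _ = tf.gene_trend_modules(
                r.normalized[r.trajectory_cells], r.counts.genes,
                r.trajectory.pseudotime, gene_list=genes3, seed=1,
            )
        cls = {g: "early" for g in sim.truth.markers_by_type["epidermis"]}
        cls.update({g: "transient" for g in sim.truth.markers_by_type["transitional"]})
        cls.update({g: "late" for g in sim.truth.markers_by_type["trichome"]})
        ari = adjusted_rand_score([cls[g] for g in assign["gene"]],
                                  assign["module"])
        assert ari >= 0.8

    def test_modules_ordered_early_to_late(self, default_run):
        r = default_run.result
        tm = r.trend_modules.merge(r.trend_matrix.reset_index(), on="gene")
        peaks = tm.groupby("module").apply(
            lambda g: g.filter(like="bin").to_numpy().mean(axis=0).argmax(),
            include_groups=False,
        )
        assert list(peaks.index) == sorted(peaks.index)
        assert (peaks.diff().dropna() >= 0).all()

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        X = rng.normal(1, 0.2, size=(100, 4)).clip(min=0)
        X[:, 0] = 1.0  # constant
        genes = np.array(["const", "a", "b", "c"])
        with pytest.warns(UserWarning, match="constant"):
            assign, _ = tf.gene_trend_modules(
                sp.csr_matrix(X), genes, rng.uniform(0, 1, 100),
                n_modules=2, seed=0,
            )
        assert "const" not in set(assign["gene"])

    def test_single_module_holds_everything(self):
        rng = np.random.default_rng(9)
        X = sp.csr_matrix(rng.normal(1, 0.3, size=(80, 5)).clip(min=0))
        genes = np.array(list("abcde"))
        assign, _ = tf.gene_trend_modules(
            X, genes, rng.uniform(0, 1, 80), n_modules=1, seed=0
        )
        assert set(assign["module"]) == {1}

    def test_fewer_genes_than_modules_rejected(self):
        X = sp.csr_matrix(np.random.default_rng(0).normal(1, 0.3, (50, 2)))
        with pytest.raises(ValueError, match="modules"):
            tf.gene_trend_modules(X, np.array(["a", "b"]),
                                  np.random.default_rng(0).uniform(0, 1, 50),
                                  n_modules=3)


class TestBranchDependence:
    def make_states(self, rng, n=240):
        return np.array([1] * (n // 3) + [2] * (n // 3) + [3] * (n // 3))

    def test_identical_gene_has_large_p(self):
        rng = np.random.default_rng(10)
        states = self.make_states(rng)
        X = sp.csr_matrix(rng.normal(1, 0.3, size=(len(states), 5)).clip(min=0))
        genes = np.array(list("abcde"))
        out = tf.branch_dependence_test(X, genes, states)
        assert (out["p_value"] > 0.01).all()

    def test_branch_specific_gene_ranks_first(self):
        rng = np.random.default_rng(11)
        states = self.make_states(rng)
        X = rng.normal(1, 0.3, size=(len(states), 20)).clip(min=0)
        X[states == 3, 0] += 2.0  # branch-specific offset
        out = tf.branch_dependence_test(sp.csr_matrix(X),
                                        np.array([f"g{j}" for j in range(20)]),
                                        states)
        assert out["gene"].iloc[0] == "g0"

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(12)
        states = self.make_states(rng)
        X = rng.normal(1, 0.3, size=(len(states), 6)).clip(min=0)
        X[states == 2, 1] += 1.0
        genes = np.array([f"g{j}" for j in range(6)])
        a = tf.branch_dependence_test(sp.csr_matrix(X), genes, states)
        swapped = states.copy()
        swapped[states == 2] = 3
        swapped[states == 3] = 2
        b = tf.branch_dependence_test(sp.csr_matrix(X), genes, swapped)
        a = a.set_index("gene")
        b = b.set_index("gene")
        np.testing.assert_allclose(a["p_value"], b.loc[a.index, "p_value"],
                                   atol=1e-12)
        np.testing.assert_allclose(
            a["log2fc_branch2_vs_branch3"],
            -b.loc[a.index, "log2fc_branch2_vs_branch3"], atol=1e-12,
        )

    def test_tiny_branch_flagged_low_power(self):
        rng = np.random.default_rng(13)
        states = np.array([1] * 50 + [2] * 2 + [3] * 50)
        X = sp.csr_matrix(rng.normal(1, 0.3, size=(102, 4)).clip(min=0))
        with pytest.warns(UserWarning, match="low-power"):
            out = tf.branch_dependence_test(X, np.array(list("abcd")), states)
        assert out["low_power"].all()

    def test_guard_markers_dominate_branch_contrast(self, default_run):
        """With the branches taken at truth, the branch-specific (guard)
        markers rank in the top decile of the contrast."""
        r = default_run.result
        tid = r.trajectory_cells
        t_truth = default_run.truth_time[tid]
        branch = default_run.truth_branch[tid]
        b = default_run.sim.truth.branch_point
        states = np.ones(len(tid), dtype=int)
        states[(branch == "main") & (t_truth > b)] = 2
        states[branch == "guard"] = 3
        genes = sorted(r.de_table.loc[r.de_table["passed"], "gene"].unique())
        bt = tf.branch_dependence_test(
            r.normalized[tid], r.counts.genes, states, gene_list=genes
        ).reset_index(drop=True)
        guard = set(default_run.sim.truth.markers_by_type["guard"])
        ranks = bt.index[bt["gene"].isin(guard)].to_numpy()
        assert np.median(ranks) < len(bt) / 10


class TestRecovery:
    def test_pseudotime_tracks_latent_time(self, default_run):
        traj = default_run.result.trajectory
        tid = default_run.result.trajectory_cells
        t_truth = default_run.truth_time[tid]
        branch = default_run.truth_branch[tid]
        main = (branch == "main") & np.isfinite(t_truth)
        rho = spearmanr(traj.pseudotime[main], t_truth[main]).statistic
        assert abs(rho) >= 0.8

    def test_one_branch_point_three_states(self, default_run):
        traj = default_run.result.trajectory
        assert traj.n_states == 3
        assert traj.branch_landmark is not None

    def test_branch_state_assignment_accuracy(self, default_run):
        traj = default_run.result.trajectory
        tid = default_run.result.trajectory_cells
        t_truth = default_run.truth_time[tid]
        branch = default_run.truth_branch[tid]
        post = np.isfinite(t_truth) & (t_truth > default_run.sim.truth.branch_point)
        is_guard = branch[post] == "guard"
        acc = max(
            np.mean(np.where(is_guard, traj.state[post] == 2,
                             traj.state[post] == 3)),
            np.mean(np.where(is_guard, traj.state[post] == 3,
                             traj.state[post] == 2)),
        )
        assert acc >= 0.8
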