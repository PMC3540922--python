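import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupsyl import calculator, synth, twostep_cluster as tc
from pupsyl.features import features_from_table
from pupsyl.twostep_cluster import (
    CFEntry,
    CFTreeParams,
    agglomerate,
    check_collinearity,
    choose_k,
    fit,
    log_likelihood_distance,
    precluster,
    silhouette_cohesion,
)

# ---------------------------------------------------------------------------
# Independent oracles


def _xi_oracle(n, ls, ss, g):
    """Tightness from first principles: -n/2 * sum log(g + within-variance)."""
    mean = ls / n
    var = np.maximum(ss / n - mean**2, 0.0)
    return -n * 0.5 * np.sum(np.log(g + var))


def _dist_oracle(a, b, g):
    na, la, sa = a
    nb, lb, sb = b
    return (
        _xi_oracle(na, la, sa, g)
        + _xi_oracle(nb, lb, sb, g)
        - _xi_oracle(na + nb, la + lb, sa + sb, g)
    )


def _agglomerate_oracle(X, g, k_max):
    """Exhaustive O(n^3)-per-step greedy agglomeration, recomputed fresh."""
    clusters = [(1.0, x.copy(), x**2, frozenset([i])) for i, x in enumerate(X)]
    partitions = {}
    dists = {}

    def snapshot():
        k = len(clusters)
        labels = np.empty(X.shape[0], dtype=int)
        for lab, (_, _, _, members) in enumerate(clusters):
            for m in members:
                labels[m] = lab
        partitions[k] = labels

    snapshot()
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _dist_oracle(clusters[i][:3], clusters[j][:3], g)
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        ci, cj = clusters[i], clusters[j]
        merged = (ci[0] + cj[0], ci[1] + cj[1], ci[2] + cj[2], ci[3] | cj[3])
        clusters = [c for k_, c in enumerate(clusters) if k_ not in (i, j)]
        clusters.insert(i, merged)
        dists[len(clusters)] = d
        if len(clusters) <= k_max:
            snapshot()
    return partitions, dists


def _silhouette_oracle(X, labels):
    from sklearn.metrics import silhouette_score

    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    return silhouette_score(Z, labels)


def _partition_sets(labels):
    return {frozenset(np.flatnonzero(labels == c)) for c in np.unique(labels)}


# ---------------------------------------------------------------------------


class TestCFEntry:
    def test_merge_conserves_statistics(self, rng):
        a = CFEntry.from_row(rng.normal(size=4))
        b = CFEntry(3, rng.normal(size=4), rng.uniform(1, 2, 4))
        m = a.merge(b)
        assert m.n == a.n + b.n
        assert np.allclose(m.linear_sum, a.linear_sum + b.linear_sum)
        assert np.allclose(m.square_sum, a.square_sum + b.square_sum)

    def test_variance_nonnegative(self, rng):
        x = rng.normal(size=3)
        e = CFEntry.from_row(x)
        assert np.all(e.variance >= 0)
        assert np.allclose(e.variance, 0.0)


class TestLogLikelihoodDistance:
    def test_identical_singletons_zero(self, rng):
        x = rng.normal(size=4)
        g = np.ones(4)
        a, b = CFEntry.from_row(x), CFEntry.from_row(x)
        assert log_likelihood_distance(a, b, g) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        g = rng.uniform(0.5, 2.0, 3)
        for _ in range(20):
            a = CFEntry(int(rng.integers(1, 5)), rng.normal(size=3), rng.uniform(2, 9, 3))
            b = CFEntry(int(rng.integers(1, 5)), rng.normal(size=3), rng.uniform(2, 9, 3))
            assert log_likelihood_distance(a, b, g) == pytest.approx(
                log_likelihood_distance(b, a, g), rel=1e-12
            )

    @pytest.mark.parametrize("delta", [0.5, 1.0, 3.0, 10.0])
    def test_closed_form_two_singletons(self, delta):
        # One variable, global variance 1: d = log(1 + delta^2 / 4).
        a = CFEntry.from_row([0.0])
        b = CFEntry.from_row([delta])
        d = log_likelihood_distance(a, b, np.ones(1))
        assert d == pytest.approx(np.log(1 + delta**2 / 4), rel=1e-9)

    def test_matches_oracle(self, rng):
        g = rng.uniform(0.5, 2.0, 3)
        for _ in range(50):
            na, nb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            Xa, Xb = rng.normal(size=(na, 3)), rng.normal(size=(nb, 3))
            a = CFEntry(na, Xa.sum(0), (Xa**2).sum(0))
            b = CFEntry(nb, Xb.sum(0), (Xb**2).sum(0))
            expect = _dist_oracle((na, a.linear_sum, a.square_sum),
                                  (nb, b.linear_sum, b.square_sum), g)
            assert log_likelihood_distance(a, b, g) == pytest.approx(
                max(expect, 0.0), rel=1e-9, abs=1e-12
            )

    def test_mismatched_variables_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood_distance(
                CFEntry.from_row([0.0]), CFEntry.from_row([0.0, 1.0]), np.ones(1)
            )


class TestPrecluster:
    def test_disabled_gives_singletons(self, rng):
        X = rng.normal(size=(10, 2))
        entries = precluster(X, CFTreeParams(disable=True))
        assert len(entries) == 10
        assert all(e.n == 1 for e in entries)

    def test_duplicates_absorbed(self):
        X = np.tile([[1.0, 2.0]], (7, 1))
        X = np.vstack([X, [[5.0, 5.0]]])
        entries = precluster(X, global_variances=np.ones(2))
        counts = sorted(e.n for e in entries)
        assert counts == [1, 7]

    def test_conservation_and_capacity(self, rng):
        centers = np.array([[0, 0], [30, 0], [0, 30], [30, 30]], dtype=float)
        lab = rng.integers(0, 4, 1000)
        X = centers[lab] + rng.normal(0, 1, (1000, 2))
        entries = precluster(X)
        assert sum(e.n for e in entries) == 1000
        assert len(entries) <= 512  # max_branches ** max_depth

    def test_no_entry_mixes_components(self, rng):
        centers = np.array([[0, 0], [30, 0], [0, 30], [30, 30]], dtype=float)
        lab = rng.integers(0, 4, 1000)
        X = centers[lab] + rng.normal(0, 1, (1000, 2))
        # Re-run the sequential pass and track member components per entry by
        # re-assigning rows to their nearest entry mean.
        entries = precluster(X)
        means = np.array([e.mean for e in entries])
        assign = np.argmin(((X[:, None, :] - means[None]) ** 2).sum(-1), axis=1)
        for e_idx in range(len(entries)):
            members = lab[assign == e_idx]
            assert np.unique(members).size <= 1


class TestAgglomerate:
    def test_matches_bruteforce_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        X[10:20] += 8.0
        g = X.var(axis=0)
        entries = precluster(X, CFTreeParams(disable=True))
        tree = agglomerate(entries, g, k_max=30)
        partitions, dists = _agglomerate_oracle(X, g, k_max=30)
        for k in range(1, 31):
            assert _partition_sets(tree.labels_by_k[k]) == _partition_sets(partitions[k])
        for k in dists:
            assert tree.merge_distance_to[k] == pytest.approx(max(dists[k], 0), abs=1e-9)

    def test_far_groups_join_last(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(100, 0.1, (5, 2))])
        g = X.var(axis=0)
        entries = precluster(X, CFTreeParams(disable=True))
        tree = agglomerate(entries, g, k_max=10)
        labels2 = tree.labels_by_k[2]
        assert _partition_sets(labels2) == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_identical_entries_zero_distances(self):
        X = np.tile([[1.0, 2.0]], (6, 1))
        entries = precluster(X, CFTreeParams(disable=True))
        tree = agglomerate(entries, np.ones(2), k_max=6)
        assert all(d == pytest.approx(0.0, abs=1e-12) for d in tree.merge_distance_to.values())

    def test_merge_distances_monotone_nondecreasing(self, rng):
        X = rng.normal(size=(40, 2))
        g = X.var(axis=0)
        tree = agglomerate(precluster(X, CFTreeParams(disable=True)), g, k_max=40)
        seq = [tree.merge_distance_to[k] for k in sorted(tree.merge_distance_to, reverse=True)]
        assert all(seq[i] <= seq[i + 1] + 1e-9 for i in range(len(seq) - 1))

    def test_single_entry_trivial(self):
        tree = agglomerate([CFEntry.from_row([1.0])], np.ones(1), k_max=5)
        assert tree.labels_by_k[1].tolist() == [0]


class TestChooseK:
    def test_four_separated_gaussians(self, rng):
        centers = np.array([[0, 0], [12, 0], [0, 12], [12, 12]], dtype=float)
        lab = rng.integers(0, 4, 4000)
        X = centers[lab] + rng.normal(0, 1, (4000, 2))
        model = fit(pd.DataFrame(X, columns=["x", "y"]), variables=["x", "y"])
        assert model.k == 4
        assert calculator.agreement(lab, model.assignments).coherence_pct > 99.0

    def test_one_gaussian_gives_one(self, rng):
        X = rng.normal(size=(2000, 3))
        model = fit(pd.DataFrame(X, columns=list("abc")), variables=list("abc"))
        assert model.k == 1
        assert model.silhouette is None

    def test_degenerate_constant_data(self):
        df = pd.DataFrame({"a": [1.0] * 200, "b": [2.0] * 200})
        with pytest.warns(UserWarning, match="constant"):
            model = fit(df, variables=["a", "b"])
        assert model.k == 1

    def test_recovery_over_replicates(self):
        hits = 0
        for s in range(20):
            rep = synth.generate_repertoire(
                synth.RepertoireSpec(n_syllables=800, seed=500 + s)
            )
            feats = features_from_table(rep)
            model = fit(feats)
            hits += model.k == 4
        assert hits >= 18


class TestSilhouette:
    def test_matches_sklearn_oracle(self, rng):
        X = rng.normal(size=(60, 3))
        X[:30] += 4.0
        labels = np.array([0] * 30 + [1] * 30)
        ours = silhouette_cohesion(X, labels)
        assert ours == pytest.approx(_silhouette_oracle(X, labels), abs=1e-9)

    def test_three_cluster_oracle(self, rng):
        centers = np.array([[0, 0], [6, 0], [0, 6]], dtype=float)
        lab = rng.integers(0, 3, 90)
        X = centers[lab] + rng.normal(0, 1, (90, 2))
        assert silhouette_cohesion(X, lab) == pytest.approx(
            _silhouette_oracle(X, lab), abs=1e-9
        )

    def test_tight_separated_clusters_high(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (50, 2)), rng.normal(10, 0.05, (50, 2))])
        labels = np.array([0] * 50 + [1] * 50)
        assert silhouette_cohesion(X, labels) > 0.9

    def test_random_split_near_zero(self, rng):
        X = rng.normal(size=(400, 2))
        labels = rng.integers(0, 2, 400)
        assert abs(silhouette_cohesion(X, labels)) <= 0.1

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_cohesion(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))


class TestCollinearity:
    def test_identical_columns_flagged(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.warns(UserWarning, match="correlated"):
            rep = check_collinearity(df)
        assert rep.flagged_pairs[0][:2] == ("a", "b")
        assert rep.flagged_pairs[0][2] == pytest.approx(1.0)

    def test_independent_columns_clean(self, rng):
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        rep = check_collinearity(df)
        assert abs(rep.pairwise_r.loc["a", "b"]) < 0.05
        assert rep.flagged_pairs == []

    def test_constant_column_undefined(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            rep = check_collinearity(df)
        assert rep.undefined == ["b"]

    def test_cluster_variables_admissible(self, default_features):
        rep = check_collinearity(
            default_features[["n_steps", "start_khz", "middle_khz", "end_khz"]]
        )
        assert all(abs(r) <= 0.9 for *_unused, r in rep.flagged_pairs) or not rep.flagged_pairs

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            check_collinearity(pd.DataFrame({"a": [1.0, 2.0]}))


class TestFit:
    def test_default_repertoire_recovers_truth(self, default_repertoire, fitted_model):
        assert fitted_model.k == 4
        rep = calculator.agreement(
            default_repertoire["true_label"], fitted_model.assignments
        )
        assert rep.coherence_pct >= 95.0

    def test_silhouette_above_half(self, fitted_model):
        assert fitted_model.silhouette is not None
        assert fitted_model.silhouette > 0.5

    def test_sizes_conserve_n(self, fitted_model):
        assert fitted_model.sizes.sum() == 4000
        assert fitted_model.assignments.size == 4000

    def test_robustness_without_step_variable(self, default_features, fitted_model):
        reduced = fit(default_features, variables=("start_khz", "middle_khz", "end_khz"))
        rep = calculator.agreement(fitted_model.assignments, reduced.assignments)
        assert 100.0 - rep.coherence_pct <= 10.0

    def test_small_table_matches_oracle_at_same_k(self, rng):
        X = rng.normal(size=(30, 2))
        X[:15] += 6.0
        g = X.var(axis=0)
        df = pd.DataFrame(X, columns=["x", "y"])
        with pytest.warns(UserWarning, match="rows"):
            model = fit(df, variables=["x", "y"], params=CFTreeParams(disable=True))
        partitions, _ = _agglomerate_oracle(X, g, k_max=15)
        oracle_labels = partitions[model.k]
        agree = calculator.agreement(oracle_labels, model.assignments).coherence_pct
        assert agree == 100.0

    def test_row_order_invariance_with_distinct_data(self, rng):
        X = rng.normal(size=(40, 2))
        X[:20] += 7.0
        df = pd.DataFrame(X, columns=["x", "y"])
        perm = rng.permutation(40)
        with pytest.warns(UserWarning, match="rows"):
            m1 = fit(df, variables=["x", "y"], params=CFTreeParams(disable=True))
            m2 = fit(df.iloc[perm].reset_index(drop=True), variables=["x", "y"],
                     params=CFTreeParams(disable=True))
        inv = np.empty(40, dtype=int)
        inv[perm] = np.arange(40)
        assert _partition_sets(m1.assignments) == _partition_sets(m2.assignments[inv])

    def test_missing_values_rejected_per_row(self, default_features):
        df = default_features.head(200).copy()
        df.loc[df.index[5], "start_khz"] = np.nan
        with pytest.warns(UserWarning):
            model = fit(df)
        assert model.rejected_rows.tolist() == [5]
        assert model.assignments.size == 199

    def test_missing_variable_rejected(self, default_features):
        with pytest.raises(ValueError, match="missing"):
            fit(default_features, variables=("nope",))
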