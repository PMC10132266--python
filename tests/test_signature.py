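import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netomicspass import (
    class_statistics,
    coexpression_scores,
    cross_validate,
    export_signature,
    fit_signature,
    load_signature,
    pareto_scale,
    predict,
    soft_threshold,
    to_partial_correlations,
)
from netomicspass.signature import (
    EdgeScoreMatrix,
    discriminant_scores,
    shrunken_centroids,
    stratified_folds,
)
from netomicspass.simulate import SimConfig, generate, sample_mvn, make_precision

from conftest import make_table


def simple_network(feature_ids, edges_with_r, modality=None):
    """PrecisionNetwork stub carrying only an edge list."""
    from netomicspass import PrecisionNetwork

    mod = modality or {f: "protein" for f in feature_ids}
    p = len(feature_ids)
    return PrecisionNetwork(
        feature_ids=list(feature_ids),
        omega=np.eye(p),
        lambda_star=0.1,
        gamma=0.5,
        edges=[(a, b, r, mod[a], mod[b]) for a, b, r in edges_with_r],
    )


def scores_matrix(values, labels, edges=None):
    """EdgeScoreMatrix + labels from a subjects × edges array."""
    values = np.asarray(values, float)
    n, m = values.shape
    edges = edges or [(f"a{j}", f"b{j}", 1) for j in range(m)]
    idx = [f"s{i}" for i in range(n)]
    scores = pd.DataFrame(values, index=idx,
                          columns=[f"{a}|{b}" for a, b, _ in edges])
    return EdgeScoreMatrix(edges, scores), pd.Series(list(labels), index=idx)


# ---------------------------------------------------------------------------
# brute-force nearest-shrunken-centroid oracle

def brute_force_nsc(X, y, delta):
    """Independent shrunken-centroid implementation (loops, no shortcuts)."""
    classes = list(dict.fromkeys(y))
    n, m = X.shape
    K = len(classes)
    xbar = X.mean(axis=0)
    cent = np.zeros((m, K))
    s2 = np.zeros(m)
    for k, c in enumerate(classes):
        rows = [i for i in range(n) if y[i] == c]
        for j in range(m):
            cent[j, k] = np.mean([X[i, j] for i in rows])
    for j in range(m):
        total = 0.0
        for k, c in enumerate(classes):
            rows = [i for i in range(n) if y[i] == c]
            total += sum((X[i, j] - cent[j, k]) ** 2 for i in rows)
        s2[j] = total / (n - K)
    s = np.sqrt(s2)
    s0 = float(np.median(s))
    n_k = np.array([sum(1 for yy in y if yy == c) for c in classes], float)
    m_k = np.sqrt(1 / n_k - 1 / n)
    d = np.zeros((m, K))
    for j in range(m):
        for k in range(K):
            d[j, k] = (cent[j, k] - xbar[j]) / (m_k[k] * (s[j] + s0))
    d_shr = np.sign(d) * np.clip(np.abs(d) - delta, 0, None)
    cent_shr = np.zeros((m, K))
    for j in range(m):
        for k in range(K):
            cent_shr[j, k] = xbar[j] + m_k[k] * (s[j] + s0) * d_shr[j, k]
    priors = n_k / n
    preds = []
    for i in range(n):
        best, best_delta = None, np.inf
        for k, c in enumerate(classes):
            dk = sum(
                (X[i, j] - cent_shr[j, k]) ** 2 / (s[j] + s0) ** 2 for j in range(m)
            ) - 2 * np.log(priors[k])
            if dk < best_delta:
                best, best_delta = c, dk
        preds.append(best)
    return {
        "classes": classes, "d": d, "s": s, "s0": s0, "cent": cent,
        "cent_shr": cent_shr, "priors": priors, "pred": np.array(preds, object),
    }


# ---------------------------------------------------------------------------
# co-expression scores

class TestCoexpressionScores:
    def _table(self, z):
        t = make_table(z, feature_ids=["a", "b"])
        t.scale_state = "standardized"
        return t

    def test_positive_edge_is_scaled_sum(self):
        net = simple_network(["a", "b"], [("a", "b", 0.5)])
        E = coexpression_scores(self._table([[1.0, 1.0]]), net)
        assert E.scores.iloc[0, 0] == pytest.approx(np.sqrt(2.0))
        assert E.edges == [("a", "b", 1)]

    def test_negative_edge_is_scaled_difference(self):
        net = simple_network(["a", "b"], [("a", "b", -0.5)])
        E = coexpression_scores(self._table([[1.0, 1.0]]), net)
        assert E.scores.iloc[0, 0] == pytest.approx(0.0)

    def test_missing_node_propagates(self):
        net = simple_network(["a", "b"], [("a", "b", 0.5)])
        E = coexpression_scores(self._table([[1.0, np.nan]]), net)
        assert np.isnan(E.scores.iloc[0, 0])

    def test_absent_node_drops_edge_with_warning(self):
        net = simple_network(["a", "b", "zzz"], [("a", "zzz", 0.5), ("a", "b", 0.4)])
        with pytest.warns(UserWarning, match="dropped"):
            E = coexpression_scores(self._table([[1.0, 2.0]]), net)
        assert E.edges == [("a", "b", 1)]

    def test_unit_variance_for_independent_nodes(self, rng):
        # independent standardized nodes give unit-variance scores for
        # either edge sign
        z = rng.normal(size=(20000, 2))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        t = self._table(z)
        for r in (0.5, -0.5):
            E = coexpression_scores(t, simple_network(["a", "b"], [("a", "b", r)]))
            assert E.scores.iloc[:, 0].var(ddof=1) == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# class statistics

class TestClassStatistics:
    def test_worked_example(self):
        E, y = scores_matrix([[0.0], [2.0], [-2.0], [0.0]], ["A", "A", "B", "B"])
        stats = class_statistics(E, y)
        assert stats.overall_centroid[0] == pytest.approx(0.0)
        assert stats.class_centroids[0].tolist() == pytest.approx([1.0, -1.0])
        assert stats.pooled_sd[0] == pytest.approx(np.sqrt(2.0))
        assert stats.s0 == pytest.approx(np.sqrt(2.0))
        assert stats.m_k.tolist() == pytest.approx([0.5, 0.5])
        assert stats.d_scores[0, 0] == pytest.approx(1 / (0.5 * 2 * np.sqrt(2.0)))

    def test_identical_distributions_zero_d(self, rng):
        x = rng.normal(size=(40, 3))
        E, y = scores_matrix(np.vstack([x, x]), ["A"] * 40 + ["B"] * 40,
                             edges=[("a", "b", 1), ("c", "d", 1), ("e", "f", -1)])
        stats = class_statistics(E, y)
        assert np.allclose(stats.d_scores, 0.0)

    def test_balanced_classes_antisymmetric_d(self, rng):
        E, y = scores_matrix(rng.normal(size=(30, 4)), ["A", "B"] * 15)
        stats = class_statistics(E, y)
        assert np.allclose(stats.d_scores[:, 0], -stats.d_scores[:, 1])

    def test_priors_sum_to_one(self, rng):
        E, y = scores_matrix(rng.normal(size=(30, 2)), ["A"] * 10 + ["B"] * 20)
        stats = class_statistics(E, y)
        assert stats.priors.sum() == pytest.approx(1.0, abs=1e-12)
        assert stats.priors.tolist() == pytest.approx([1 / 3, 2 / 3])

    def test_tiny_class_rejected(self):
        E, y = scores_matrix([[0.0], [1.0], [2.0]], ["A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            class_statistics(E, y)

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(18, 6))
        y = ["A"] * 9 + ["B"] * 9
        E, ys = scores_matrix(X, y)
        stats = class_statistics(E, ys)
        ref = brute_force_nsc(X, y, 0.0)
        assert np.allclose(stats.d_scores, ref["d"])
        assert np.allclose(stats.pooled_sd, ref["s"])
        assert stats.s0 == pytest.approx(ref["s0"])
        assert np.allclose(stats.class_centroids, ref["cent"])


class TestSoftThreshold:
    @pytest.mark.parametrize("d,delta,expected", [
        (2.5, 1.0, 1.5),
        (-0.5, 1.0, 0.0),
        (-2.0, 0.5, -1.5),
        (0.7, 0.0, 0.7),
    ])
    def test_examples(self, d, delta, expected):
        assert soft_threshold(np.array([d]), delta)[0] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-50, 50), st.floats(0, 50))
    def test_shrinks_toward_zero_preserving_sign(self, d, delta):
        out = float(soft_threshold(np.array([d]), delta)[0])
        assert abs(out) <= abs(d)
        assert out == 0 or np.sign(out) == np.sign(d)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)


# ---------------------------------------------------------------------------
# cross-validation

class TestCrossValidate:
    def test_full_shrinkage_error_is_minority_rate(self, rng):
        # huge delta => empty signature => everyone classified to the
        # largest-prior class; error ~ 1 - max prior
        X = rng.normal(size=(60, 3))
        E, y = scores_matrix(X, ["A"] * 40 + ["B"] * 20)
        curve, _ = cross_validate(E, y, grid=[1e6], n_folds=5, seed=0)
        assert curve[0][1] == pytest.approx(1 / 3, abs=0.02)

    def test_perfect_separation_reaches_zero_error(self):
        X = np.r_[np.full((20, 2), 3.0), np.full((20, 2), -3.0)]
        X += np.random.default_rng(0).normal(scale=0.1, size=X.shape)
        E, y = scores_matrix(X, ["A"] * 20 + ["B"] * 20)
        curve, delta_star = cross_validate(E, y, n_folds=5, seed=0)
        assert min(e for _, e in curve) == 0.0

    def test_curve_contract(self, rng):
        E, y = scores_matrix(rng.normal(size=(40, 2)), ["A", "B"] * 20)
        grid = np.linspace(0, 3, 7)
        curve, delta_star = cross_validate(E, y, grid=grid, n_folds=4, seed=0)
        assert len(curve) == len(grid)
        assert all(0.0 <= e <= 1.0 for _, e in curve)
        assert delta_star in set(grid)

    def test_single_class_rejected(self, rng):
        E, y = scores_matrix(rng.normal(size=(10, 2)), ["A"] * 10)
        with pytest.raises(ValueError):
            cross_validate(E, y, n_folds=2, seed=0)

    def test_small_class_reduces_folds_with_warning(self, rng):
        E, y = scores_matrix(rng.normal(size=(12, 2)), ["A"] * 8 + ["B"] * 4)
        with pytest.warns(UserWarning, match="folds"):
            cross_validate(E, y, grid=[0.5], n_folds=10, seed=0)

    def test_folds_are_stratified_and_seeded(self):
        y = pd.Series(["A"] * 30 + ["B"] * 30)
        f1 = stratified_folds(y, 10, seed=3)
        f2 = stratified_folds(y, 10, seed=3)
        assert (f1 == f2).all()
        for fold in range(10):
            members = y[f1 == fold]
            assert (members == "A").sum() == 3
            assert (members == "B").sum() == 3


# ---------------------------------------------------------------------------
# oracle equivalence and fitting

class TestShrunkenCentroidOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_delta_zero_classification_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 20, 8
        X = rng.normal(size=(n, m))
        X[:10] += 0.8
        y = ["A"] * 10 + ["B"] * 10
        E, ys = scores_matrix(X, y)
        stats = class_statistics(E, ys)
        ref = brute_force_nsc(X, y, 0.0)
        d_shr, cent = shrunken_centroids(stats, 0.0)
        assert np.allclose(cent, ref["cent_shr"])
        delta = discriminant_scores(X, cent, stats.pooled_sd + stats.s0, stats.priors)
        pred = np.asarray(stats.classes, object)[np.argmin(delta, axis=1)]
        assert (pred == ref["pred"]).all()

    @pytest.mark.parametrize("delta_val", [0.3, 0.8, 1.5])
    def test_shrunken_centroids_match_brute_force(self, delta_val):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(16, 5))
        y = ["A"] * 8 + ["B"] * 8
        E, ys = scores_matrix(X, y)
        stats = class_statistics(E, ys)
        ref = brute_force_nsc(X, y, delta_val)
        d_shr, cent = shrunken_centroids(stats, delta_val)
        assert np.allclose(d_shr, np.sign(ref["d"]) * np.clip(np.abs(ref["d"]) - delta_val, 0, None))
        assert np.allclose(cent, ref["cent_shr"])


class TestFitSignature:
    def _dataset(self, seed=0, effect=2.0):
        ds = generate(SimConfig(
            n_per_class=40, modality_sizes={"protein": 20}, n_signal_edges=4,
            effect=effect, missing_rate=0.0, seed=seed,
        ))
        from netomicspass import log_transform
        table = pareto_scale(log_transform(ds.table))
        net = to_partial_correlations(
            ds.true_precision, ds.table.feature_ids, ds.table.modality
        )
        return ds, table, net

    def test_zero_threshold_keeps_every_edge(self):
        ds, table, net = self._dataset()
        model = fit_signature(table, net, ds.labels, grid=[0.0], n_folds=3,
                              noninfo_alpha=1.0)
        assert model.n_edges == net.n_edges
        assert model.threshold == 0.0

    def test_oversized_threshold_gives_empty_signature(self):
        ds, table, net = self._dataset()
        with pytest.warns(UserWarning, match="empty"):
            model = fit_signature(table, net, ds.labels, grid=[1e6], n_folds=3)
        assert model.n_edges == 0

    def test_shrinkage_monotone_in_delta(self):
        ds, table, net = self._dataset()
        E = coexpression_scores(table, net)
        stats = class_statistics(E, ds.labels)
        sizes = []
        for delta in np.linspace(0, np.abs(stats.d_scores).max() * 1.01, 8):
            d_shr, _ = shrunken_centroids(stats, delta)
            sizes.append(int((d_shr != 0).any(axis=1).sum()))
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0

    def test_signal_edges_recovered(self):
        ds, table, net = self._dataset(seed=3)
        model = fit_signature(table, net, ds.labels, n_folds=5, seed=1)
        feats = ds.table.feature_ids
        signal = {(feats[i], feats[j]) for i, j, _ in ds.signal_edges}
        found = {(a, b) for a, b, _ in model.edges}
        assert len(found & signal) / len(signal) >= 0.75

    def test_sparse_edges_excluded_from_search(self):
        ds, table, net = self._dataset()
        # blank out one edge's nodes for 60% of subjects
        a, b, *_ = net.edges[0]
        table.values.iloc[: int(0.6 * len(table.subject_ids)),
                          [table.feature_ids.index(a)]] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            model = fit_signature(table, net, ds.labels, grid=[0.0], n_folds=3,
                                  noninfo_alpha=1.0, min_edge_obs=0.5)
        assert (a, b) not in {(x, y) for x, y, _ in model.edges}

    def test_export_round_trip_predicts_identically(self, tmp_path):
        ds, table, net = self._dataset(seed=5)
        model = fit_signature(table, net, ds.labels, n_folds=5, seed=1)
        paths = export_signature(model, tmp_path / "sig")
        back = load_signature(paths["model"])
        p1 = predict(model, table).probabilities
        p2 = predict(back, table).probabilities
        pd.testing.assert_frame_equal(p1, p2)
        sig = pd.read_csv(paths["signature"], sep="\t")
        assert len(sig) == model.n_edges

    def test_empty_signature_export(self, tmp_path):
        ds, table, net = self._dataset()
        with pytest.warns(UserWarning):
            model = fit_signature(table, net, ds.labels, grid=[1e6], n_folds=3)
        paths = export_signature(model, tmp_path / "sig")
        sig = pd.read_csv(paths["signature"], sep="\t")
        assert len(sig) == 0
        assert list(sig.columns)[:3] == ["node_a", "node_b", "sign"]
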