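import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kesvr.data_io import DataError
from kesvr.embedded_clustering import (
    ClusterPartition,
    LabeledData,
    fit_svr,
    train_global_svr,
)
from kesvr.embedding import ReducedDataset
from kesvr.local_ensemble import (
    RadiusLadder,
    SelectionContext,
    beta_score,
    compute_radius_ladder,
    neighbors,
    predict_candidates,
    select_prediction,
    spearman,
    train_local_svrs,
)

from oracles import neighbors_oracle, spearman_oracle, svr_predict_oracle


def _labeled(features, labels):
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return LabeledData(
        [f"c{i:02d}" for i in range(features.shape[0])],
        [f"g{j}" for j in range(features.shape[1])],
        features,
        np.asarray(labels, dtype=float),
    )


def _partition(labels, cell_ids):
    labels = np.asarray(labels, dtype=int)
    K = labels.max() + 1
    cents = np.zeros((K, 2))
    return ClusterPartition(K, labels, cents, list(cell_ids))


class TestTrainLocalSvrs:
    def test_single_cluster_reproduces_global_procedure(self, rng):
        q = _labeled(rng.standard_normal((24, 5)), rng.uniform(0, 5, 24))
        part = _partition(np.zeros(24, dtype=int), q.cell_ids)
        local = train_local_svrs(q, part, seed=3)
        global_model, grec = train_global_svr(q, seed=3)
        assert local.splits[0].train_ids == grec.train_ids
        assert np.array_equal(
            local.models[0].predict(q.features), global_model.predict(q.features)
        )

    def test_small_cluster_fit_on_all_members(self, rng):
        labels = np.array([0] * 3 + [1] * 17)
        q = _labeled(rng.standard_normal((20, 3)), rng.uniform(0, 5, 20))
        local = train_local_svrs(q, _partition(labels, q.cell_ids), seed=0)
        assert local.splits[0].test_ids == []
        assert len(local.splits[0].train_ids) == 3

    def test_singleton_cluster_constant_predictor(self, rng):
        labels = np.array([0] + [1] * 15)
        q = _labeled(rng.standard_normal((16, 3)), rng.uniform(0, 5, 16))
        local = train_local_svrs(q, _partition(labels, q.cell_ids), seed=0)
        assert local.models[0].kind == "constant"
        assert local.models[0].constant == q.labels[0]

    def test_two_linear_regimes_fit_better_locally(self, rng):
        x = rng.uniform(-1, 1, size=(40, 1))
        labels = np.array([0] * 20 + [1] * 20)
        y = np.where(labels == 0, 5 * x[:, 0], -5 * x[:, 0] + 10)
        q = _labeled(x, y)
        local = train_local_svrs(q, _partition(labels, q.cell_ids), seed=1)
        pooled = fit_svr(q.features, q.labels)
        pooled_mse = np.mean((y - pooled.predict(q.features)) ** 2)
        local_pred = np.empty(40)
        for k in (0, 1):
            idx = labels == k
            local_pred[idx] = local.models[k].predict(q.features[idx])
        assert np.mean((y - local_pred) ** 2) < pooled_mse


class TestPredictCandidates:
    def test_k1_equals_single_svr(self, rng):
        q = _labeled(rng.standard_normal((20, 4)), rng.uniform(0, 5, 20))
        local = train_local_svrs(q, _partition(np.zeros(20, int), q.cell_ids), seed=0)
        x = rng.standard_normal(4)
        cand = predict_candidates(local, x)
        assert cand.shape == (1,)
        assert cand[0] == local.models[0].predict(x.reshape(1, -1))[0]

    def test_three_clusters_match_per_model_oracle(self, rng):
        labels = np.repeat([0, 1, 2], 8)
        q = _labeled(rng.standard_normal((24, 4)), rng.uniform(0, 5, 24))
        local = train_local_svrs(q, _partition(labels, q.cell_ids), seed=2)
        x = rng.standard_normal(4)
        cand = predict_candidates(local, x)
        expect = [svr_predict_oracle(m, x.reshape(1, -1))[0] for m in local.models]
        assert np.allclose(cand, expect, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        q = _labeled(rng.standard_normal((10, 4)), rng.uniform(0, 5, 10))
        local = train_local_svrs(q, _partition(np.zeros(10, int), q.cell_ids), seed=0)
        with pytest.raises(DataError, match="dimension"):
            predict_candidates(local, np.zeros(7))


def _clustered_z(auc, ordinate, labels):
    auc = np.asarray(auc, dtype=float)
    return ReducedDataset(
        [f"c{i:02d}" for i in range(auc.size)], auc,
        np.asarray(ordinate, float), 1, np.asarray(labels, int),
    )


class TestRadiusLadder:
    def test_single_cluster_span(self):
        z = _clustered_z([0, 1, 5], [0, 0, 0], [0, 0, 0])
        lad = compute_radius_ladder(z)
        assert list(lad.spans) == [5] and lad.r == 5

    def test_sorted_ascending_smallest_active(self):
        z = _clustered_z([0, 7, 2, 5], [0, 0, 0, 0], [0, 0, 1, 1])
        lad = compute_radius_ladder(z)
        assert list(lad.spans) == [3, 7] and lad.r == 3

    def test_singleton_cluster_zero_span_escalates_at_query(self, rng):
        # cluster 0 is a singleton (span 0); cluster 1 has span 4
        z = _clustered_z([2.0, 5.0, 9.0], [10.0, 0.0, 0.0], [0, 1, 1])
        lad = compute_radius_ladder(z)
        assert lad.r == 0.0
        feats = rng.standard_normal((3, 6))
        ctx = SelectionContext(z, lad, feats)
        # candidates far from every point at r=0 -> escalate to r=4
        trace = select_prediction(
            "q", rng.standard_normal(6), 0.0, np.array([6.0, 6.0]), ctx,
            global_prediction=0.0,
        )
        assert trace.radius_used == 4.0
        assert not trace.fallback


class TestNeighbors:
    def test_r_zero_no_coincident_points_empty(self):
        idx = neighbors(np.array([1.0, 2.0]), np.array([0.0, 0.0]), (0.0, 0.0), 0.0)
        assert idx.size == 0

    def test_radius_beyond_diameter_saturates(self, rng):
        auc, ordv = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        idx = neighbors(auc, ordv, (0.5, 0.5), 10.0)
        assert idx.size == 20

    def test_hand_placed_points_match_brute_force(self):
        pts = np.array([[1.0, 2.0], [2.4, 0.1], [-2.0, -1.0], [0.0, 2.5], [3.0, 3.0]])
        got = neighbors(pts[:, 0], pts[:, 1], (0.0, 0.0), 2.5)
        expect = neighbors_oracle(pts, (0.0, 0.0), 2.5)
        assert list(got) == expect

    def test_closed_ball_boundary_included(self):
        idx = neighbors(np.array([3.0]), np.array([4.0]), (0.0, 0.0), 5.0)
        assert list(idx) == [0]


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), r=st.floats(0, 3), n=st.integers(1, 60))
def test_neighbor_search_equals_quadratic_scan(seed, r, n):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-2, 2, size=(n, 2))
    center = tuple(rng.uniform(-2, 2, size=2))
    got = list(neighbors(pts[:, 0], pts[:, 1], center, r))
    assert got == neighbors_oracle(pts, center, r)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_neighbor_sets_grow_with_radius(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-2, 2, size=(30, 2))
    center = (0.0, 0.0)
    prev: set = set()
    for r in (0.5, 1.0, 2.0, 6.0):
        cur = set(neighbors(pts[:, 0], pts[:, 1], center, r))
        assert prev <= cur
        prev = cur
    assert prev == set(range(30))  # r beyond diameter saturates


class TestBetaScore:
    def test_empty_neighborhood_scores_zero(self, rng):
        assert beta_score(rng.standard_normal(5), [], {}) == 0.0

    def test_monotone_transforms_score_one(self, rng):
        x = rng.standard_normal(6)
        feats = {"a": 2 * x + 1, "b": np.exp(x)}
        assert beta_score(x, ["a", "b"], feats) == pytest.approx(1.0)

    def test_mean_of_rank_then_pearson_oracle(self):
        x = np.array([0.3, 1.2, -0.5, 0.9])
        feats = {
            "a": np.array([1.0, 2.0, 0.0, 1.5]),
            "b": np.array([-1.0, 0.4, 2.0, 0.2]),
            "c": np.array([5.0, 5.5, 4.0, 7.0]),
        }
        expect = np.mean([spearman_oracle(x, feats[c]) for c in "abc"])
        assert beta_score(x, ["a", "b", "c"], feats) == pytest.approx(expect, abs=1e-12)

    def test_constant_profile_contributes_zero(self, rng):
        x = rng.standard_normal(4)
        feats = {"flat": np.ones(4), "inc": x.copy()}
        assert beta_score(x, ["flat"], feats) == 0.0
        assert beta_score(x, ["flat", "inc"], feats) == pytest.approx(0.5)

    def test_duplicating_a_neighbor_pulls_beta_toward_it(self, rng):
        x = np.arange(5.0)
        near = x + rng.normal(0, 0.1, 5)      # high correlation
        far = -x                               # correlation -1
        feats = {"n": near, "f": far, "f2": far}
        b1 = beta_score(x, ["n", "f"], feats)
        b2 = beta_score(x, ["n", "f", "f2"], feats)
        assert b2 < b1  # duplicated anti-correlated neighbour drags beta down

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 8), g=st.integers(2, 12))
    def test_beta_always_within_unit_interval(self, seed, n, g):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(g)
        feats = {f"c{i}": rng.standard_normal(g) for i in range(n)}
        b = beta_score(x, list(feats), feats)
        assert -1.0 <= b <= 1.0


def test_spearman_matches_scipy_definition(rng):
    from scipy.stats import spearmanr

    for _ in range(10):
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        assert spearman(a, b) == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)


class TestSelectPrediction:
    def _ctx(self, rng, n=30, K=3):
        labels = np.arange(n) % K
        auc = rng.uniform(0, 10, n)
        ordv = rng.uniform(-2, 2, n)
        z = _clustered_z(auc, ordv, labels)
        feats = rng.standard_normal((n, 6))
        return SelectionContext(z, compute_radius_ladder(z), feats)

    def test_highest_beta_wins(self, rng):
        ctx = self._ctx(rng)
        # craft an input equal to one training profile: its cluster's beta
        # includes a perfect match
        i = 4
        x = ctx.train_features[i]
        cands = np.array([ctx.z.auc[i], ctx.z.auc[i], ctx.z.auc[i]])
        tr = select_prediction("q", x, float(ctx.z.ordinate[i]), cands, ctx,
                               global_prediction=0.0)
        assert tr.selected_value in cands
        assert np.all((-1 <= tr.betas) & (tr.betas <= 1))
        assert tr.betas[tr.selected_cluster] == tr.betas.max()

    def test_single_candidate_returned_unchanged(self, rng):
        n = 12
        z = _clustered_z(rng.uniform(0, 5, n), rng.uniform(-1, 1, n), np.zeros(n, int))
        ctx = SelectionContext(z, compute_radius_ladder(z), rng.standard_normal((n, 4)))
        tr = select_prediction("q", rng.standard_normal(4), 0.0, np.array([3.3]), ctx,
                               global_prediction=99.0)
        assert tr.selected_value == 3.3 and tr.selected_cluster == 0

    def test_escalation_matches_oracle_replay(self, rng):
        from oracles import replay_selection

        # tight cluster spans force escalation for a distant candidate
        auc = np.array([0.0, 0.4, 5.0, 5.3, 5.6, 9.9, 10.0, 10.1])
        ordv = np.zeros(8)
        labels = np.array([0, 0, 1, 1, 1, 2, 2, 2])
        z = _clustered_z(auc, ordv, labels)
        feats = rng.standard_normal((8, 5))
        ctx = SelectionContext(z, compute_radius_ladder(z), feats)
        x = rng.standard_normal(5)
        cands = np.array([2.0, 7.5, 12.0])
        tr = select_prediction("q", x, 0.0, cands, ctx, global_prediction=-1.0)
        sel_k, sel_v, r_used, counts, betas, fb = replay_selection(
            x, 0.0, cands, labels, auc, ordv, feats, z_ladder := ctx.ladder.spans,
            -1.0)
        assert (tr.selected_cluster, tr.selected_value, tr.radius_used, tr.fallback) == (
            sel_k, sel_v, r_used, fb)
        assert list(tr.neighbor_counts) == counts
        assert np.allclose(tr.betas, betas, atol=1e-12)

    def test_ladder_exhausted_falls_back_to_global(self, rng):
        auc = np.array([0.0, 0.1, 0.2])
        z = _clustered_z(auc, np.zeros(3), np.zeros(3, int))
        ctx = SelectionContext(z, compute_radius_ladder(z), rng.standard_normal((3, 4)))
        tr = select_prediction("q", rng.standard_normal(4), 50.0, np.array([40.0]), ctx,
                               global_prediction=7.7)
        assert tr.fallback and tr.selected_value == 7.7
        assert tr.selected_cluster is None

    def test_selected_value_always_a_candidate_or_fallback(self, rng):
        ctx = self._ctx(rng, n=40, K=4)
        for _ in range(20):
            cands = rng.uniform(0, 10, 4)
            tr = select_prediction("q", rng.standard_normal(6),
                                   float(rng.uniform(-2, 2)), cands, ctx,
                                   global_prediction=123.0)
            assert tr.fallback or tr.selected_value in cands
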