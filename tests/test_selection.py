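import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pclfsx as px
from conftest import make_grid


def brute_force_ext(g, n_pclfs, t):
    """Independent enumerator: test every size j < n_pclfs for the strict
    local-maximum and gradient conditions, return the minimum qualifying j."""
    qualifying = []
    for j in range(1, n_pclfs):
        left = g[j - 2] if j >= 2 else -math.inf
        right = g[j]
        if not (g[j - 1] > left and g[j - 1] > right):
            continue
        gradient = (g[n_pclfs - 1] - g[j - 1]) / (n_pclfs - j)
        if gradient < t:
            qualifying.append(j)
    if qualifying:
        return min(qualifying), False
    return n_pclfs, True


class TestPclfsSelect:
    @pytest.mark.parametrize(
        "g, expected",
        [
            ([0.2, 0.9, 0.9], 2),  # smallest argmax on tie
            ([0.5], 1),
            ([0.1, 0.2, 0.3, 0.4], 4),  # strictly increasing -> n
            ([0.9, 0.1, 0.9], 1),
        ],
    )
    def test_smallest_argmax(self, g, expected):
        assert px.pclfs_select(make_grid(g)) == expected


class TestLocalMaxima:
    def test_interior_peaks(self):
        g = [0.60, 0.70, 0.65, 0.72, 0.71, 0.80]
        assert px.local_maxima(make_grid(g), 6) == [2, 4]

    def test_strictly_increasing_has_none(self):
        assert px.local_maxima(make_grid([0.1, 0.2, 0.3, 0.4]), 4) == []

    def test_left_edge_peak_qualifies(self):
        assert px.local_maxima(make_grid([0.9, 0.5, 0.4, 1.0]), 4) == [1]

    def test_plateau_ties_disqualify(self):
        g = [0.5, 0.7, 0.7, 0.6, 0.9]
        assert px.local_maxima(make_grid(g), 5) == []


class TestThreshold:
    def test_spect_value(self):
        assert px.threshold(0.05, 44) == pytest.approx(0.0011, abs=5e-5)

    def test_simulation_value(self):
        assert px.threshold(0.05, 30) == pytest.approx(0.0017, abs=5e-5)

    def test_zero_tolerance(self):
        assert px.threshold(0.0, 17) == 0.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            px.threshold(-0.1, 10)


class TestExtSelect:
    def test_worked_gradients(self):
        from pclfsx.selection import candidate_gradients

        g = [0.60, 0.70, 0.65, 0.72, 0.71, 0.80]
        grid = make_grid(g)
        cands = {j: grad for j, _, grad in candidate_gradients(grid, 6)}
        assert cands[2] == pytest.approx(0.025)
        assert cands[4] == pytest.approx(0.04)
        assert px.ext_select(grid, 6, 0.03) == (2, False)

    def test_tiny_threshold_falls_back(self):
        g = [0.60, 0.70, 0.65, 0.72, 0.71, 0.80]
        assert px.ext_select(make_grid(g), 6, 0.0001) == (6, True)

    def test_single_point_grid_falls_back(self):
        assert px.ext_select(make_grid([0.5]), 1, 0.5) == (1, True)

    def test_packaged_demo_grid_reduces_29_to_10(self):
        grid, n_informative, T = px.load_demo_grid()
        n_pclfs = px.pclfs_select(grid)
        t = px.threshold(T, len(grid))
        n_proposed, fallback = px.ext_select(grid, n_pclfs, t)
        assert n_pclfs == 29
        assert (n_proposed, fallback) == (10, False)
        assert n_proposed == n_informative

    @given(
        g=st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=50),
        t=st.floats(0, 0.2, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_brute_force_enumerator(self, g, t):
        grid = make_grid(g)
        n_pclfs = px.pclfs_select(grid)
        assert px.ext_select(grid, n_pclfs, t) == brute_force_ext(g, n_pclfs, t)

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = rng.random(rng.integers(2, 40))
            grid = make_grid(g)
            n_pclfs = px.pclfs_select(grid)
            n = len(g)
            sizes = [px.ext_select(grid, n_pclfs, px.threshold(T, n))[0]
                     for T in (0.0, 0.01, 0.05, 0.2, 1.0)]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_candidate_gradients_nonnegative_and_loss_bounded(self):
        rng = np.random.default_rng(1)
        from pclfsx.selection import candidate_gradients

        for _ in range(200):
            g = rng.random(rng.integers(1, 40))
            grid = make_grid(g)
            n_pclfs = px.pclfs_select(grid)
            assert all(grad >= 0 for _, _, grad in candidate_gradients(grid, n_pclfs))
            T = float(rng.random())
            t = px.threshold(T, len(g))
            n_prop, _ = px.ext_select(grid, n_pclfs, t)
            loss = grid.score_at(n_pclfs) - grid.score_at(n_prop)
            assert loss <= t * (n_pclfs - n_prop) + 1e-12
            assert loss <= T + 1e-12


class TestExtSubset:
    def _imp(self, values):
        return px.ImportanceScores(values=np.asarray(values, float), classifier_id="x")

    def _ranking(self, order):
        order = np.asarray(order)
        return px.RankedFeatures(order=order, scores=np.zeros(order.size))

    def test_identity_when_all_kept(self):
        ranking = self._ranking([3, 1, 0, 2])
        out = px.ext_subset(self._imp([0.5, 0.2, 0.9]), ranking, 3)
        assert set(out.tolist()) == {3, 1, 0}

    def test_top_importance_wins(self):
        ranking = self._ranking([0, 1, 2, 3])  # active: A=0, B=1, C=2
        out = px.ext_subset(self._imp([0.1, 0.9, 0.5]), ranking, 2)
        assert set(out.tolist()) == {1, 2}

    def test_equal_importances_fall_back_to_rank_order(self):
        ranking = self._ranking([4, 2, 0, 1, 3])
        out = px.ext_subset(self._imp([0.3, 0.3, 0.3]), ranking, 2)
        assert out.tolist() == [4, 2]

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            px.ext_subset(self._imp([0.1, 0.2]), self._ranking([0, 1, 2]), 3)


class TestGridScores:
    def test_length_and_determinism(self, balanced_dataset):
        train, test = px.split(balanced_dataset, 0.25, True, 0)
        ranking = px.pclfs_rank(train.X)
        g1 = px.grid_scores(train, test, ranking, "logit", seed=0)
        g2 = px.grid_scores(train, test, ranking, "logit", seed=0)
        assert len(g1) == balanced_dataset.n_features
        assert np.array_equal(g1.g, g2.g)
        assert ((g1.g >= 0) & (g1.g <= 1)).all()

    def test_perfectly_separating_first_feature(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        X = np.column_stack([np.where(y == 1, 5.0, -5.0) + 0.01 * rng.standard_normal(60),
                             rng.standard_normal(60)])
        ds = px.Dataset(X, y, ["sep", "noise"])
        train, test = px.split(ds, 0.25, True, 0)
        ranking = px.pclfs_rank(train.X)
        assert ranking.order[0] == 0
        g = px.grid_scores(train, test, ranking, "logit", seed=0)
        assert g.score_at(1) == 1.0


class TestRunPclfsExt:
    def test_zero_tolerance_equals_pclfs(self, balanced_dataset):
        train, test = px.split(balanced_dataset, 0.25, True, 0)
        pclfs_res, ext_res = px.run_pclfs_ext(train, test, "logit", T=0.0, seed=0)
        assert ext_res.fallback
        assert ext_res.n_proposed == pclfs_res.n_pclfs
        assert set(ext_res.subset.tolist()) == set(pclfs_res.selected.tolist())

    def test_proposed_never_exceeds_pclfs(self, imbalanced_dataset):
        train, test = px.split(imbalanced_dataset, 0.25, True, 0)
        pclfs_res, ext_res = px.run_pclfs_ext(train, test, "logit", T=0.05, seed=0)
        assert ext_res.n_proposed <= pclfs_res.n_pclfs
        assert len(ext_res.subset) == ext_res.n_proposed

    def test_reduces_subset_with_high_recovery(self):
        """On well-separated data the reduced subsets recover the informative
        features: median size shrinks (or holds) and ext TPR_fs stays >= 0.8."""
        n_pclfs_all, n_prop_all, tprs = [], [], []
        for seed in range(20):
            ds = px.generate_dataset(
                px.SynthSpec(n_samples=1000, n_features=30, n_informative=10,
                             class_sep=2.0, seed=seed)
            )
            train, test = px.split(ds, 0.25, True, seed)
            pclfs_res, ext_res = px.run_pclfs_ext(train, test, "logit", T=0.05, seed=seed)
            n_pclfs_all.append(pclfs_res.n_pclfs)
            n_prop_all.append(ext_res.n_proposed)
            tprs.append(px.tpr_fs(ext_res.subset, ds.informative_indices))
        assert np.median(n_prop_all) <= np.median(n_pclfs_all)
        assert np.mean(tprs) >= 0.8


class TestEstimators:
    def test_pclfs_selector_transform_shape(self, balanced_dataset):
        sel = px.PCLFS(estimator="logit", random_state=0)
        Xt = sel.fit_transform(balanced_dataset.X, balanced_dataset.y)
        assert Xt.shape == (1000, sel.n_selected_)
        assert sel.support_.sum() == sel.n_selected_
        assert sel.grid_scores_.shape == (30,)

    def test_ext_selector_contract_and_params(self, balanced_dataset):
        sel = px.PCLFSExt(estimator="logit", T=0.05, random_state=0)
        sel.fit(balanced_dataset.X, balanced_dataset.y)
        assert sel.n_selected_ <= sel.n_pclfs_
        assert sel.threshold_ == pytest.approx(0.05 / 30)
        params = sel.get_params()
        assert params["T"] == 0.05
        clone_sel = px.PCLFSExt(**params)
        clone_sel.fit(balanced_dataset.X, balanced_dataset.y)
        assert clone_sel.n_selected_ == sel.n_selected_

    def test_sklearn_pipeline_compatible(self, balanced_dataset):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([
            ("select", px.PCLFSExt(estimator="logit", random_state=0)),
            ("clf", LogisticRegression(max_iter=2000)),
        ])
        pipe.fit(balanced_dataset.X, balanced_dataset.y)
        acc = pipe.score(balanced_dataset.X, balanced_dataset.y)
        assert acc > 0.9
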