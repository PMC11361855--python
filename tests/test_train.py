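"""Label clipping, splits, training loop, ensemble inference, metrics."""

import numpy as np
import pytest

import cycloperm as cp
from cycloperm.errors import InputError
from conftest import tiny_model


class TestClipLabels:
    @pytest.mark.parametrize("raw, expected",
                             [(-9.3, -8.0), (-3.8, -4.0), (-6.0, -6.0),
                              (-8.0, -8.0), (-4.0, -4.0)])
    def test_clipping_rules(self, raw, expected):
        assert cp.clip_labels([raw])[0] == expected

    def test_idempotent(self):
        vals = np.array([-10.0, -6.2, -3.0])
        once = cp.clip_labels(vals)
        assert np.array_equal(cp.clip_labels(once), once)

    def test_nonfinite_raises(self):
        with pytest.raises(InputError):
            cp.clip_labels([np.nan])


def naive_kennard_stone(X, k):
    """Literal O(n^3) reference implementation of the greedy KS rule."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    sel = [min(i, j), max(i, j)]
    while len(sel) < k:
        best, best_val = None, -1.0
        for c in range(n):
            if c in sel:
                continue
            val = min(d[c][s] for s in sel)
            if val > best_val:
                best, best_val = c, val
        sel.append(best)
    return sel


class TestKennardStone:
    def test_max_distance_pair_toy(self):
        X = np.array([[0, 0, 0, 0], [0, 0, 0, 1], [1, 1, 1, 1]], dtype=float)
        assert set(cp.kennard_stone_split(X, 2 / 3)) == {0, 2}

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(30, 16)).astype(float)
        assert (cp.kennard_stone_split(X, 0.3)
                == cp.kennard_stone_split(X, 0.3))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_naive_reference_on_random_bit_vectors(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(20, 8)).astype(float)
        got = cp.kennard_stone_split(X, 0.25)
        assert got == naive_kennard_stone(X, 5)

    def test_bad_fraction_raises(self):
        with pytest.raises(InputError):
            cp.kennard_stone_split(np.zeros((4, 2)), 1.5)


class TestSplitPlan:
    def test_folds_disjoint_and_cover(self):
        rng = np.random.default_rng(1)
        fps = rng.integers(0, 2, size=(60, 32)).astype(float)
        ids = [f"p{i}" for i in range(60)]
        plan = cp.make_split(ids, fps, test_fraction=0.1, val_fraction=0.1,
                             n_val_folds=3, seed=5)
        groups = [plan.test_ids, plan.train_ids] + plan.validation_ids
        flat = [i for g in groups for i in g]
        assert sorted(flat) == sorted(ids)  # cover, no duplicates
        assert len(plan.validation_ids) == 3
        assert len(plan.test_ids) == 6

    def test_train_pool_excludes_active_fold(self):
        rng = np.random.default_rng(2)
        fps = rng.integers(0, 2, size=(40, 16)).astype(float)
        ids = [f"p{i}" for i in range(40)]
        plan = cp.make_split(ids, fps, 0.1, 0.1, 3, seed=0)
        pool = set(plan.train_pool(0))
        assert not (pool & set(plan.validation_ids[0]))
        assert set(plan.validation_ids[1]) <= pool


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = cp.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (rep.mae, rep.mse, rep.r, rep.r2) == (0.0, 0.0, 1.0, 1.0)

    def test_constant_offset(self):
        rep = cp.evaluate([1.5, 2.5, 3.5], [1.0, 2.0, 3.0])
        assert rep.mae == pytest.approx(0.5)
        assert rep.r == pytest.approx(1.0)
        assert rep.r2 < 1.0

    def test_anticorrelated(self):
        rep = cp.evaluate([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert rep.r == pytest.approx(-1.0)

    def test_zero_label_variance_flagged(self):
        rep = cp.evaluate([1.0, 2.0], [5.0, 5.0])
        assert rep.degenerate and np.isnan(rep.r)

    def test_agrees_with_independent_formulas(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        p = y + rng.normal(0, 0.3, 50)
        rep = cp.evaluate(p, y)
        assert rep.mae == pytest.approx(np.mean(np.abs(p - y)), abs=1e-9)
        assert rep.mse == pytest.approx(np.mean((p - y) ** 2), abs=1e-9)
        assert rep.r == pytest.approx(np.corrcoef(p, y)[0, 1], abs=1e-9)
        assert rep.r2 == pytest.approx(
            1 - ((p - y) ** 2).sum() / ((y - y.mean()) ** 2).sum(), abs=1e-9)
        assert rep.mse >= rep.mae**2 - 1e-12


class TestTrainingLoop:
    def test_identical_seed_identical_trajectory(self, small_cohort):
        ds = small_cohort["dataset"]
        rows = np.arange(len(ds))
        ps, ms = cp.fit_feature_standardizers(ds, rows)
        sds = cp.apply_standardizers(ds, ps, ms)
        histories = []
        for _ in range(2):
            model = tiny_model(n_max=ds.n_max, seed=4)
            hist = cp.train(model, sds,
                            config=cp.TrainConfig(epochs=4, batch_size=4,
                                                  seed=9))
            histories.append(hist["total_loss"].to_numpy())
        assert np.array_equal(histories[0], histories[1])

    def test_zero_gammas_make_total_equal_fusion(self, small_cohort):
        ds = small_cohort["dataset"]
        rows = np.arange(len(ds))
        ps, ms = cp.fit_feature_standardizers(ds, rows)
        sds = cp.apply_standardizers(ds, ps, ms)
        model = tiny_model(n_max=ds.n_max,
                           fusion={"gamma_sub": 0.0, "gamma_layer": 0.0})
        hist = cp.train(model, sds,
                        config=cp.TrainConfig(epochs=3, batch_size=4, seed=0))
        assert np.allclose(hist["total_loss"], hist["fusion_loss"], rtol=1e-5)

    def test_empty_split_raises(self, small_cohort):
        ds = small_cohort["dataset"].subset(np.array([], dtype=int))
        model = tiny_model(n_max=4)
        with pytest.raises(InputError):
            cp.train(model, ds)


class TestStandardizerLeakage:
    def test_validation_features_use_train_statistics(self, small_cohort):
        """Refitting the standardizer with held-out rows included changes
        the held-out features: the pipeline must therefore fit on the
        training rows only."""
        ds = small_cohort["dataset"]
        train_rows = np.arange(0, 7)
        val_rows = np.arange(7, len(ds))
        ps_train, ms_train = cp.fit_feature_standardizers(ds, train_rows)
        ps_all, ms_all = cp.fit_feature_standardizers(
            ds, np.arange(len(ds)))
        val_desc = ds.arrays["desc"][val_rows].astype(float)
        assert not np.allclose(ps_train.apply(val_desc),
                               ps_all.apply(val_desc), atol=1e-8)


class TestEnsemble:
    def test_single_replica_identity_and_mean_bounds(self, small_cohort):
        ds = small_cohort["dataset"]
        rows = np.arange(len(ds))
        ps, ms = cp.fit_feature_standardizers(ds, rows)
        sds = cp.apply_standardizers(ds, ps, ms)
        model = tiny_model(n_max=ds.n_max)
        one = sds.subset(np.array([0]))
        single = cp.predict_ensemble(model, one)
        assert single == pytest.approx(
            float(cp.predict_rows(model, one)[0]))

    def test_mean_of_two_values(self):
        # ensemble = arithmetic mean of per-replica fusion outputs
        assert np.mean([-6.0, -7.0]) == -6.5

    def test_mixed_peptides_rejected(self, small_cohort):
        ds = small_cohort["dataset"]
        model = tiny_model(n_max=ds.n_max)
        with pytest.raises(InputError):
            cp.predict_ensemble(model, ds)  # ten different peptides
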