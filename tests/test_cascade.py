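"""Cascade classifier: weak learners, boosting, thresholds, SVM substitution."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from vesscade.cascade import (AdaBoostLayer, CascadeModel, CascadeTargets,
                              CascadeTrainingError, WeakClassifier,
                              adaboost_round, calibrate_layer_threshold,
                              cascade_rates, feature_utilization, init_weights,
                              strong_response, train_adaboost_layer,
                              train_cascade, train_svm_layer, train_weak)


def exhaustive_interval(values, labels, weights):
    """Brute-force oracle: best [lo, hi] over all boundary pairs."""
    uniq = np.unique(values)
    mids = np.concatenate([[uniq[0] - 1.0],
                           0.5 * (uniq[1:] + uniq[:-1]),
                           [uniq[-1] + 1.0]])
    pos_total = weights[labels > 0].sum()
    best = np.inf
    for i in range(len(mids)):
        for j in range(i, len(mids)):
            inside = (values >= mids[i]) & (values <= mids[j])
            gain = weights[(labels > 0) & inside].sum() - \
                weights[(labels < 0) & inside].sum()
            err = pos_total - gain
            best = min(best, err)
    return best


class TestInitWeights:
    def test_example(self):
        w_p, w_n = init_weights(3, 7)
        assert w_p == pytest.approx(0.25)
        assert w_n == pytest.approx(1.0 / 28)

    @given(p=hst.integers(1, 5000), q=hst.integers(1, 5000))
    @settings(max_examples=200, deadline=None)
    def test_identities(self, p, q):
        w_p, w_n = init_weights(p, q)
        assert w_p == pytest.approx(q * w_n, rel=1e-12)
        assert p * w_p + q * w_n == pytest.approx(1.0, rel=1e-12)

    def test_balanced_ratio(self):
        w_p, w_n = init_weights(10, 10)
        assert w_p / w_n == pytest.approx(10.0)

    def test_degenerate_class(self):
        with pytest.raises(CascadeTrainingError):
            init_weights(0, 5)


class TestTrainWeak:
    def test_separable_interval(self, rng):
        pos = rng.uniform(2, 3, 50)
        neg = np.concatenate([rng.uniform(0, 1.5, 40), rng.uniform(3.5, 5, 40)])
        values = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(50), -np.ones(80)])
        w = np.full(130, 1 / 130)
        wc, eps = train_weak(values, labels, w)
        assert eps == pytest.approx(0.0, abs=1e-12)
        assert wc.t_lower <= 2.0 and wc.t_upper >= 3.0

    def test_matches_exhaustive_oracle_small_sets(self, rng):
        """Semiexhaustive search equals full O(m^2) enumeration on all random
        sets of size <= 12."""
        for _ in range(300):
            m = int(rng.integers(2, 13))
            values = np.round(rng.normal(size=m), 2)
            labels = rng.choice([-1, 1], m)
            if len(np.unique(labels)) < 2:
                labels[0] = -labels[0]
            w = rng.uniform(0.1, 1, m)
            w /= w.sum()
            wc, eps = train_weak(values, labels, w)
            oracle = exhaustive_interval(values, labels, w)
            assert eps == pytest.approx(oracle, abs=1e-12)

    def test_constant_channel_degenerate(self):
        wc, eps = train_weak(np.full(10, 3.0),
                             np.array([1, 1, 1, -1, -1, -1, -1, -1, -1, -1]),
                             np.full(10, 0.1))
        assert wc.degenerate
        assert eps == pytest.approx(0.3)

    def test_quantile_grid_large_set(self, rng):
        """On large sets the quantile grid + refinement stays within a small
        margin of a fine exhaustive reference."""
        values = rng.normal(size=3000)
        labels = np.where(np.abs(values) < 0.8, 1, -1)
        w = np.full(3000, 1 / 3000)
        _, eps = train_weak(values, labels, w)
        assert eps <= 0.02  # near-separable by construction


class TestAdaBoost:
    def _toy(self, rng, n=400):
        X = np.zeros((n, 1, 5))
        labels = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        X[:n // 2, 0, 0] = rng.normal(0, 0.5, n // 2)
        X[n // 2:, 0, 0] = rng.normal(2.5, 0.5, n // 2)
        X[:, 0, 1:] = rng.normal(size=(n, 4))
        return X, labels

    def test_beta_formula(self, rng):
        # engineered 25% weighted error -> beta = ln 3
        values = np.array([0.0, 0.0, 0.0, 10.0])
        labels = np.array([1, 1, -1, -1])
        X = np.zeros((4, 1, 5))
        X[:, 0, 0] = values
        # other channels constant -> degenerate, channel 0 chosen
        w = np.full(4, 0.25)
        out = adaboost_round(X, labels, w, 0)
        assert out is not None
        wc, eps, neww = out
        assert eps == pytest.approx(0.25)
        assert wc.beta == pytest.approx(np.log(3))

    def test_post_update_error_is_half(self, rng):
        """Classical identity: the selected weak classifier has weighted
        error exactly 0.5 on the updated weights."""
        for _ in range(20):
            X, labels = self._toy(rng)
            w = np.full(len(labels), 1 / len(labels))
            out = adaboost_round(X, labels, w, 0)
            assert out is not None
            wc, eps, neww = out
            if eps <= 1e-9:
                # separable round: nothing misclassified, weights unchanged
                assert np.allclose(neww, w)
                continue
            votes = wc.votes(X[:, 0, wc.feature])
            miscl = (votes > 0.5) != (labels > 0)
            assert neww[miscl].sum() == pytest.approx(0.5, abs=1e-9)

    def test_training_error_bound(self, rng):
        """Classical AdaBoost guarantee: the 0/1 training error of the
        boosted sum (at threshold half the vote mass) stays below the
        exponential bound prod_t 2 sqrt(eps_t (1 - eps_t)), which shrinks
        with every informative round (checked on 20 random sets)."""
        for _ in range(20):
            X, labels = self._toy(rng, n=200)
            w = np.full(200, 1 / 200)
            layer = AdaBoostLayer(weaks=[[]])
            bound = 1.0
            for _t in range(6):
                out = adaboost_round(X, labels, w, 0)
                if out is None:
                    break
                wc, eps, w = out
                layer.weaks[0].append(wc)
                bound *= 2.0 * np.sqrt(eps * (1.0 - eps))
                resp = strong_response(layer, X)
                half = 0.5 * sum(wk.beta for wk in layer.weaks[0])
                err = np.mean((resp >= half) != (labels > 0))
                assert err <= bound + 1e-9


class TestStrongResponse:
    def test_single_weak(self):
        layer = AdaBoostLayer(weaks=[[WeakClassifier(0, 0, -1, 1, beta=1.0)]])
        X = np.zeros((1, 1, 5))
        assert strong_response(layer, X)[0] == pytest.approx(1.0)

    def test_max_over_scales(self):
        layer = AdaBoostLayer(weaks=[
            [WeakClassifier(0, 0, -1, 1, beta=0.4)],
            [WeakClassifier(0, 1, -1, 1, beta=0.9)]])
        X = np.zeros((1, 2, 5))
        assert strong_response(layer, X)[0] == pytest.approx(0.9)

    def test_monotone_in_votes(self):
        layer = AdaBoostLayer(weaks=[[WeakClassifier(0, 0, -1, 1, beta=0.7),
                                      WeakClassifier(1, 0, -1, 1, beta=0.3)]])
        inside = np.zeros((1, 1, 5))
        outside = np.full((1, 1, 5), 5.0)
        assert strong_response(layer, inside)[0] > strong_response(layer, outside)[0]


class TestThresholdCalibration:
    def _layer(self):
        return AdaBoostLayer(weaks=[[WeakClassifier(0, 0, -2, 2, beta=1.0),
                                     WeakClassifier(1, 0, -2, 2, beta=1.0)]])

    def test_full_detection(self, rng):
        layer = self._layer()
        X = rng.normal(0, 1, size=(100, 1, 5))
        y = np.where(np.abs(X[:, 0, 0]) < 1, 1, -1)
        theta = calibrate_layer_threshold(layer, X, y, 1.0)
        resp = layer.response(X)
        assert theta <= resp[y > 0].min()
        assert layer.achieved_d == 1.0

    def test_counting_at_099(self, rng):
        layer = self._layer()
        Xp = rng.normal(0, 0.5, size=(100, 1, 5))
        Xn = rng.normal(3, 0.5, size=(50, 1, 5))
        X = np.concatenate([Xp, Xn])
        y = np.concatenate([np.ones(100), -np.ones(50)])
        calibrate_layer_threshold(layer, X, y, 0.99)
        resp = layer.response(X)
        assert int(np.sum(resp[y > 0] < layer.theta)) <= 1

    def test_e_monotone_in_theta(self, rng):
        layer = self._layer()
        X = rng.normal(0, 2, size=(200, 1, 5))
        y = rng.choice([-1, 1], 200)
        resp = layer.response(X)
        es = []
        for theta in np.linspace(resp.min(), resp.max(), 7):
            es.append(np.mean(resp[y < 0] >= theta))
        assert np.all(np.diff(es) <= 1e-12)


def make_xor_pools(rng, n=1200, n_scales=1):
    """Positives on the (+,+)/(−,−) diagonal, negatives on the other:
    inseparable by any additive per-channel score, trivial for an RBF.

    The three remaining channels are constant (degenerate), so boosting's
    greedy selection always works on the two informative coordinates.
    """
    pos = np.zeros((n, n_scales, 5))
    neg = np.zeros((n, n_scales, 5))
    s1 = rng.choice([-1.0, 1.0], n)
    pos[:, 0, 0] = s1 + rng.normal(0, 0.05, n)
    pos[:, 0, 1] = s1 + rng.normal(0, 0.05, n)
    s2 = rng.choice([-1.0, 1.0], n)
    neg[:, 0, 0] = s2 + rng.normal(0, 0.05, n)
    neg[:, 0, 1] = -s2 + rng.normal(0, 0.05, n)
    return pos, neg


class TestLayerTraining:
    def test_separable_layer_succeeds(self, rng):
        pos = rng.normal(0, 0.3, size=(400, 2, 5))
        neg = rng.normal(3, 0.3, size=(400, 2, 5))
        layer, ok = train_adaboost_layer(pos, neg, CascadeTargets(), rng)
        assert ok
        assert layer.achieved_e <= 0.3
        assert layer.n_weaks <= 2 * 2  # few weaks needed per scale

    def test_xor_layer_fails_with_queue(self, rng):
        """Interval-inseparable XOR data defeats the AdaBoost layer within
        its weak-classifier budget; the feature queue is returned."""
        pos, neg = make_xor_pools(rng)
        layer, ok = train_adaboost_layer(pos, neg,
                                         CascadeTargets(n_th=8), rng)
        assert not ok
        assert len(layer.queue) > 0
        assert len(layer.queue) <= 8 * pos.shape[1]

    def test_svm_rescues_xor(self, rng):
        pos, neg = make_xor_pools(rng)
        ab, ok = train_adaboost_layer(pos, neg, CascadeTargets(n_th=8), rng)
        assert not ok
        svm = train_svm_layer(pos, neg, ab.queue, CascadeTargets(), rng)
        assert svm.achieved_d >= 0.99 - 1e-9
        assert svm.achieved_e <= 0.3

    def test_svm_ignores_unselected_channels(self, rng):
        pos, neg = make_xor_pools(rng)
        svm = train_svm_layer(pos, neg, [(0, 0), (1, 0)], CascadeTargets(), rng)
        X = np.concatenate([pos[:50], neg[:50]])
        base = svm.response(X)
        X2 = X.copy()
        X2[:, 0, 4] = rng.normal(size=100)  # permute an unselected channel
        assert np.allclose(svm.response(X2), base)


class TestCascade:
    def test_rate_bookkeeping_ten_layers(self):
        D, E = cascade_rates(0.99, 0.3, 10)
        assert D == pytest.approx(0.99**10)
        assert D > 0.9
        assert E == pytest.approx(0.3**10)
        assert E < 6e-6

    def test_separable_single_layer(self, rng):
        pos = rng.normal(0, 0.3, size=(500, 1, 5))
        neg = rng.normal(4, 0.3, size=(800, 1, 5))
        model = train_cascade(pos, neg, CascadeTargets(), seed=0)
        assert len(model.layers) <= 2
        _, E = model.overall_rates()
        assert E <= 6e-6 or E == 0.0

    def test_generalization_rates(self, rng):
        """Held-out detection and false-positive rates track the per-layer
        bookkeeping within a binomial envelope."""
        def sample(n):
            X = np.zeros((n, 1, 5))
            X[:, 0, 0] = rng.normal(0, 1, n)
            X[:, 0, 1] = rng.normal(0, 1, n)
            return X
        pos = sample(2000) * 0.4
        neg = sample(2000) * 0.4 + 1.6
        model = train_cascade(pos, neg, CascadeTargets(), seed=1)
        D, E = model.overall_rates()
        held_pos = sample(2000) * 0.4
        held_neg = sample(2000) * 0.4 + 1.6
        d_emp = model.predict(held_pos).mean()
        e_emp = model.predict(held_neg).mean()
        assert d_emp >= D - 3 * np.sqrt(D * (1 - D) / 2000) - 0.02
        assert e_emp <= E + 3 * np.sqrt(max(E * (1 - E), 1e-4) / 2000) + 0.02

    def test_negative_pool_shrinks(self, rng, capsys):
        pos = rng.normal(0, 0.5, size=(500, 1, 5))
        neg = rng.normal(2, 1.0, size=(2000, 1, 5))
        model = train_cascade(pos, neg, CascadeTargets(), seed=2, verbose=True)
        out = capsys.readouterr().out
        left = [int(line.rsplit("=", 1)[1]) for line in out.splitlines()
                if "negatives left" in line]
        assert all(b < a for a, b in zip([2000] + left, left))

    def test_predict_short_circuit_counts(self, rng):
        pos = rng.normal(0, 0.3, size=(300, 1, 5))
        neg = rng.normal(4, 0.3, size=(600, 1, 5))
        model = train_cascade(pos, neg, CascadeTargets(), seed=3)
        X = np.concatenate([pos, neg])
        accepted, counts = model.predict_with_counts(X)
        assert sum(counts) == len(X) - accepted.sum()

    def test_empty_cascade_vacuous_pass(self):
        model = CascadeModel([], CascadeTargets(), n_scales=1)
        with pytest.warns(UserWarning):
            pred = model.predict(np.zeros((3, 1, 5)))
        assert pred.all()

    def test_dimension_mismatch_errors(self, rng):
        pos = rng.normal(0, 0.3, size=(100, 1, 5))
        neg = rng.normal(4, 0.3, size=(100, 1, 5))
        model = train_cascade(pos, neg, CascadeTargets(), seed=0)
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 2, 5)))

    def test_bit_reproducible(self, rng):
        pos, neg = make_xor_pools(rng, n=600)
        m1 = train_cascade(pos, neg, CascadeTargets(n_th=8), seed=42)
        m2 = train_cascade(pos, neg, CascadeTargets(n_th=8), seed=42)
        assert json.dumps(m1.to_dict()) == json.dumps(m2.to_dict())

    def test_json_round_trip_exact(self, rng):
        pos, neg = make_xor_pools(rng, n=600)
        model = train_cascade(pos, neg, CascadeTargets(n_th=8), seed=5)
        assert any(l.kind == "svm" for l in model.layers)
        back = CascadeModel.from_dict(json.loads(json.dumps(model.to_dict())))
        X = np.concatenate([pos[:100], neg[:100]])
        assert np.array_equal(model.predict(X), back.predict(X))
        assert json.dumps(back.to_dict()) == json.dumps(model.to_dict())


class TestUtilization:
    def _model(self, queues):
        layers = []
        for q in queues:
            layers.append(AdaBoostLayer(weaks=[[]], achieved_d=1, achieved_e=0,
                                        queue=q))
        return CascadeModel(layers, CascadeTargets(), n_scales=1)

    def test_counting(self):
        model = self._model([[(0, 0)], [(0, 0), (0, 0), (3, 0), (3, 0)]])
        u = feature_utilization(model, rear_layer_count=2)
        assert u[0] == pytest.approx(60.0)
        assert u[3] == pytest.approx(40.0)

    def test_sums_to_100(self, rng):
        queues = [[(int(rng.integers(5)), 0) for _ in range(10)]
                  for _ in range(4)]
        model = self._model(queues)
        assert feature_utilization(model).sum() == pytest.approx(100.0)

    def test_single_layer_warns(self):
        model = self._model([[(2, 0), (2, 0)]])
        with pytest.warns(UserWarning):
            u = feature_utilization(model, rear_layer_count=2)
        assert u[2] == pytest.approx(100.0)


class TestCAvsCAS:
    def test_svm_cascade_needs_fewer_layers(self, rng):
        """On a pool with an interval-inseparable negative cluster the
        SVM-enabled cascade reaches its overall target with strictly fewer
        layers than the AdaBoost-only cascade at its lowered targets."""
        pos, neg = make_xor_pools(rng, n=1500)
        cas = train_cascade(pos, neg, CascadeTargets(0.99, 0.3, 15, 6e-6),
                            seed=7, svm_enabled=True)
        ca = train_cascade(pos, neg, CascadeTargets(0.90, 0.4, 20, 1e-4),
                           seed=7, svm_enabled=False)
        assert any(l.kind == "svm" for l in cas.layers)
        assert len(cas.layers) < len(ca.layers)
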