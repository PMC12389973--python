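import numpy as np
import pytest

from corticlass.autograd import Tensor
from corticlass.model import DepressionClassifier, ModelConfig, normalize_adjacency
from corticlass.optim import SGD
from corticlass.pipeline import Sample
from corticlass.training import (
    TrainConfig,
    ablation_run,
    adversarial_loss,
    center_loss,
    center_loss_features,
    cross_entropy_logits,
    evaluate,
    extract_features,
    focal_loss,
    focal_loss_logits,
    joint_loss,
    predict,
    train,
)


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy(self):
        assert focal_loss([0.5], gamma=0.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_gamma_two(self):
        # (1 - 0.9)^2 * (-ln 0.9) = 1.0536e-3
        assert focal_loss([0.9], gamma=2.0) == pytest.approx(1.0536e-3, rel=1e-3)

    def test_perfect_prediction_vanishes(self):
        assert focal_loss([1.0 - 1e-12], gamma=2.0) == pytest.approx(0.0, abs=1e-20)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            val = focal_loss([0.0], gamma=0.0)
        assert val == pytest.approx(-np.log(1e-12))

    def test_monotone_decreasing_in_p(self):
        grid = np.linspace(0.01, 0.99, 50)
        for gamma in (0.0, 1.0, 2.0, 5.0):
            losses = [focal_loss([p], gamma=gamma) for p in grid]
            assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_class_balance_weights(self):
        beta = np.array([2.0, 0.5])
        val = focal_loss([0.5, 0.5], labels=[0, 1], gamma=0.0, beta=beta)
        assert val == pytest.approx(2.5 * np.log(2), abs=1e-12)

    def test_reduction_conventions(self):
        s = focal_loss([0.5, 0.8], gamma=0.0, reduction="sum")
        m = focal_loss([0.5, 0.8], gamma=0.0, reduction="mean")
        assert s == pytest.approx(2 * m, abs=1e-12)

    def test_logits_path_matches_reference(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((5, 2))
        labels = np.array([0, 1, 1, 0, 1])
        beta = np.array([1.3, 0.7])
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        p_true = probs[np.arange(5), labels]
        ref = focal_loss(p_true, labels, gamma=2.0, beta=beta, reduction="mean")
        t = focal_loss_logits(Tensor(logits), labels, 2.0, beta, "mean")
        assert float(t.data) == pytest.approx(ref, rel=1e-9)


class TestAdversarialLoss:
    def test_uniform_two_domains(self):
        assert adversarial_loss([[0.5, 0.5]], [0]) == pytest.approx(np.log(2))

    def test_one_hot_correct(self):
        assert adversarial_loss([[1.0, 0.0]], [0]) == pytest.approx(0.0, abs=1e-9)

    def test_hand_three_sample_batch(self):
        probs = [[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]]
        labels = [0, 1, 0]
        expected = -(np.log(0.7) + np.log(0.8) + np.log(0.5))
        assert adversarial_loss(probs, labels) == pytest.approx(expected, abs=1e-12)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            adversarial_loss([[0.7, 0.7]], [0])


class TestCenterLoss:
    def test_features_at_centers(self):
        centers = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert center_loss(centers, [0, 1], centers) == 0.0

    def test_single_sample_distance_two(self):
        centers = np.zeros((2, 1))
        assert center_loss([[2.0]], [0], centers) == 4.0

    def test_hand_batch_of_three(self):
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        feats = np.array([[1.0, 0.0], [1.0, 2.0], [0.0, 0.0]])
        labels = [0, 1, 1]
        expected = 1.0 + (0.0 + 1.0) + (1.0 + 1.0)
        assert center_loss(feats, labels, centers) == pytest.approx(expected)


class TestJointLoss:
    def test_reduces_to_focal(self):
        assert joint_loss(1.7, 5.0, 3.0, gamma_center=0.0, lambda_adv=0.0) == 1.7

    def test_arithmetic(self):
        assert joint_loss(1.0, 1.0, 1.0, gamma_center=0.5, lambda_adv=0.2) == \
            pytest.approx(1.3)


def tiny_model(n_domains=3, seed=42):
    cfg = ModelConfig(d_in=6, heads=2, fa_layers=1, gcn_layers=1,
                      hidden_dim=5, dropout=0.0)
    return DepressionClassifier(cfg, n_domains=n_domains, seed=seed)


def tiny_inputs(seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((4, 6))
    a = (rng.random((4, 4)) > 0.5).astype(int)
    a = np.triu(a, 1)
    return x, normalize_adjacency(a + a.T)


class TestGradientStructure:
    def test_joint_gradient_matches_component_finite_differences(self):
        """Extractor gradient = dFocal + gc*dCenter - lam*dAdv (via the GRL)."""
        lam, gc = 0.3, 0.5
        model = tiny_model()
        x, a_hat = tiny_inputs()
        labels, dlabels = np.array([0]), np.array([1])
        centers = 0.1 * np.ones((2, 5))

        feats = model.extract(x, a_hat)
        loss = (focal_loss_logits(model.classify(feats), labels, 2.0, np.ones(2))
                + gc * center_loss_features(feats, labels, centers)
                + cross_entropy_logits(model.discriminate(feats, lam), dlabels))
        loss.backward()
        grads = [p.grad.copy() for p in model.extractor_parameters()]

        def component(f):
            for p in model.parameters():
                p.zero_grad()
            f().backward()
            return [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
                    for p in model.extractor_parameters()]

        g_focal = component(lambda: focal_loss_logits(
            model.classify(model.extract(x, a_hat)), labels, 2.0, np.ones(2)))
        g_center = component(lambda: center_loss_features(
            model.extract(x, a_hat), labels, centers))
        # lam=-1 turns the GRL into the identity: plain adversarial gradient.
        g_adv = component(lambda: cross_entropy_logits(
            model.discriminate(model.extract(x, a_hat), -1.0), dlabels))

        for g, gf, gc_, ga in zip(grads, g_focal, g_center, g_adv):
            np.testing.assert_allclose(g, gf + 0.5 * gc_ - lam * ga, atol=1e-10)

        # and each component matches central finite differences
        eps = 1e-6
        params = model.extractor_parameters()

        def focal_value():
            return float(focal_loss_logits(
                model.classify(model.extract(x, a_hat)), labels, 2.0,
                np.ones(2)).data)

        p = params[0]
        for k in range(3):
            old = p.data.ravel()[k]
            p.data.ravel()[k] = old + eps
            lp = focal_value()
            p.data.ravel()[k] = old - eps
            lm = focal_value()
            p.data.ravel()[k] = old
            assert g_focal[0].ravel()[k] == pytest.approx((lp - lm) / (2 * eps),
                                                          abs=1e-4)

    def test_grl_step_equals_two_term_update(self):
        """One SGD step with the GRL == theta - eta (dFocal - lam dAdv)."""
        lam, eta = 0.3, 0.01
        labels, dlabels = np.array([0]), np.array([1])
        x, a_hat = tiny_inputs()

        m1 = tiny_model()
        opt = SGD(m1.extractor_parameters(), lr=eta)
        feats = m1.extract(x, a_hat)
        loss = (focal_loss_logits(m1.classify(feats), labels, 0.0, np.ones(2))
                + cross_entropy_logits(m1.discriminate(feats, lam), dlabels))
        loss.backward()
        opt.step()

        m2 = tiny_model()
        feats = m2.extract(x, a_hat)
        focal_loss_logits(m2.classify(feats), labels, 0.0, np.ones(2)).backward()
        g_focal = [p.grad.copy() for p in m2.extractor_parameters()]
        for p in m2.parameters():
            p.zero_grad()
        feats = m2.extract(x, a_hat)
        cross_entropy_logits(m2.discriminate(feats, -1.0), dlabels).backward()
        g_adv = [p.grad.copy() for p in m2.extractor_parameters()]
        for p, gf, ga in zip(m2.extractor_parameters(), g_focal, g_adv):
            p.data -= eta * (gf - lam * ga)

        for p1, p2 in zip(m1.extractor_parameters(), m2.extractor_parameters()):
            np.testing.assert_allclose(p1.data, p2.data, atol=1e-6)


class TestEvaluate:
    def test_balanced_85(self):
        pred = np.concatenate([np.zeros(85), np.ones(15),   # true DP
                               np.ones(85), np.zeros(15)])  # true HC
        true = np.concatenate([np.zeros(100), np.ones(100)])
        rep = evaluate(pred, true)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (85, 85, 15, 15)
        assert rep.acc == rep.pre == rep.rec == rep.f1 == 85.00

    def test_all_correct(self):
        rep = evaluate([0, 1, 0, 1], [0, 1, 0, 1])
        assert rep.acc == rep.pre == rep.rec == rep.f1 == 100.00

    def test_degenerate_precision(self):
        rep = evaluate([1, 1, 1], [0, 1, 1])
        assert rep.pre == 0.0
        assert rep.degenerate

    def test_metrics_identity(self):
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 2, 200)
        true = rng.integers(0, 2, 200)
        rep = evaluate(pred, true)
        m = rep.tp + rep.tn + rep.fp + rep.fn
        assert m == 200
        assert rep.acc == pytest.approx(round(100.0 * (rep.tp + rep.tn) / m, 2))
        np.testing.assert_array_equal(rep.confusion,
                                      [[rep.tp, rep.fn], [rep.fp, rep.tn]])


def synthetic_samples(n_dp=3, n_hc=3, epochs_per_subject=6, n=4, d=8,
                      sep=2.0, seed=0):
    """Directly constructed feature samples: class signal in column 0."""
    rng = np.random.default_rng(seed)
    samples = []
    for s in range(n_dp + n_hc):
        label = 0 if s < n_dp else 1
        shift = rng.normal(0, 0.3)  # subject-level offset
        for e in range(epochs_per_subject):
            x = rng.standard_normal((n, d)) + shift
            x[:, 0] += sep * (1 - label)
            a = (rng.random((n, n)) > 0.5).astype(int)
            a = np.triu(a, 1)
            samples.append(Sample(
                x=x, a_hat=normalize_adjacency(a + a.T), label=label,
                subject_id=f"sub-{s:03d}", domain_id=f"sub-{s:03d}",
                epoch_index=e))
    return samples


FAST = dict(epochs=8, patience=8, learning_rate=1e-2,
            model=ModelConfig(d_in=8, heads=2, fa_layers=1, gcn_layers=1,
                              hidden_dim=8, dropout=0.1))


class TestTrainLoop:
    def test_deterministic_history(self):
        samples = synthetic_samples()
        cfg = TrainConfig(seed=3, **FAST)
        h1 = train(samples, cfg).history
        h2 = train(samples, cfg).history
        assert h1 == h2

    def test_history_structure_and_splits(self):
        samples = synthetic_samples()
        res = train(samples, TrainConfig(seed=4, **FAST))
        assert res.history
        row = res.history[0]
        assert {"epoch", "l_focal", "l_adv", "l_center", "l_fada",
                "val_acc"} <= set(row)
        groups = [set(res.split[k]) for k in ("train", "val", "test")]
        assert not (groups[0] & groups[1] or groups[0] & groups[2]
                    or groups[1] & groups[2])
        assert res.test_report is not None

    def test_single_class_rejected(self):
        samples = [s for s in synthetic_samples() if s.label == 0]
        with pytest.raises(ValueError, match="single class"):
            train(samples, TrainConfig(seed=5, **FAST))

    def test_separable_data_learned(self):
        samples = synthetic_samples(n_dp=4, n_hc=4, sep=4.0, seed=6)
        cfg = TrainConfig(seed=6, epochs=20, patience=20, learning_rate=3e-2,
                          model=FAST["model"])
        res = train(samples, cfg)
        assert res.best_val_acc >= 0.9

    def test_predict_and_extract_shapes(self):
        samples = synthetic_samples()
        res = train(samples, TrainConfig(seed=7, **FAST))
        preds = predict(res.state, samples[:5])
        assert preds.shape == (5,)
        feats = extract_features(res.state, samples[:5])
        assert feats.shape == (5, 8)


class TestAblation:
    def test_s8_matches_direct_training(self):
        cortical = synthetic_samples(seed=8)
        scalp = synthetic_samples(seed=9, d=6)
        cfg = TrainConfig(seed=8, **FAST)
        rows = ablation_run(cortical, scalp, cfg,
                            grid=(("S8", True, True, True),))
        direct = train(cortical, cfg)
        assert rows[0]["ACC"] == direct.test_report.acc
        assert rows[0]["index"] == "S8"

    def test_s1_uses_scalp_samples(self):
        cortical = synthetic_samples(seed=10)
        scalp = synthetic_samples(seed=11, d=6)
        cfg = TrainConfig(seed=10, **FAST)
        rows = ablation_run(cortical, scalp, cfg,
                            grid=(("S1", False, False, False),))
        direct = train(scalp, TrainConfig(
            seed=10, use_fada=False, epochs=8, patience=8, learning_rate=1e-2,
            model=ModelConfig(d_in=6, heads=2, fa_layers=1, gcn_layers=1,
                              hidden_dim=8, dropout=0.1, use_fa=False)))
        assert rows[0]["ACC"] == direct.test_report.acc

    def test_full_grid_shape(self):
        cortical = synthetic_samples(seed=12, epochs_per_subject=3)
        scalp = synthetic_samples(seed=13, epochs_per_subject=3, d=6)
        cfg = TrainConfig(seed=12, epochs=2, patience=2, learning_rate=1e-2,
                          model=FAST["model"])
        rows = ablation_run(cortical, scalp, cfg)
        assert [r["index"] for r in rows] == [f"S{i}" for i in range(1, 9)]
        assert all("ACC" in r for r in rows)
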