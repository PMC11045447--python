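import numpy as np
import pytest

from choicebias.data import LotShape, Problem
from choicebias.models import (MAX_SUPPORT, TrainSchedule, base_matrix,
                               to_context_input, train_model)
from choicebias.nets import SparseMLP, set_step


class TestContextInput:
    def test_sure_thing_has_single_unit_probability(self):
        p = Problem(id="s", ha=50, p_ha=1.0, la=0, hb=10, p_hb=0.5, lb=0)
        xa, pa, xb, pb = to_context_input(p)
        assert np.count_nonzero(pa) == 1 and pa.max() == pytest.approx(1.0)

    def test_padding_probabilities_are_zero_and_real_mass_sums_to_one(self):
        p = Problem(id="w", ha=96, p_ha=0.9, la=12,
                    hb=96, p_hb=0.85, lb=12,
                    lot_shape_b=LotShape.SYMM, lot_num_b=3)
        xa, pa, xb, pb = to_context_input(p)
        for vec in (pa, pb):
            assert vec.sum() == pytest.approx(1.0)
            assert len(vec) == MAX_SUPPORT
        assert np.count_nonzero(pb) == 4  # 3 expanded high outcomes + Lb

    def test_oversized_support_rejected(self):
        p = Problem(id="big", ha=1, p_ha=0.5, la=0, hb=100, p_hb=0.5, lb=0,
                    lot_shape_b=LotShape.R_SKEW, lot_num_b=12)
        with pytest.raises(ValueError, match="support"):
            to_context_input(p, max_support=10)


class TestSetStep:
    def _layer(self, seed=0, density=0.5, shape=(6, 5)):
        net = SparseMLP(shape[0], [shape[1]], seed=seed, density=density)
        return net.layers[0]

    def test_connection_count_conserved(self):
        rng = np.random.default_rng(0)
        layer = self._layer()
        before = layer.n_connections()
        for _ in range(5):
            set_step(layer, 0.3, rng)
            assert layer.n_connections() == before

    def test_zeta_zero_is_identity(self):
        rng = np.random.default_rng(1)
        layer = self._layer(seed=2)
        w, mask = layer.w.copy(), layer.mask.copy()
        set_step(layer, 0.0, rng)
        assert np.array_equal(layer.w, w) and np.array_equal(layer.mask, mask)

    def test_extremal_weights_removed_on_toy_layer(self):
        rng = np.random.default_rng(3)
        layer = self._layer(seed=4, density=1.0 - 1e-9, shape=(5, 1))
        layer.mask = np.ones((5, 1), dtype=bool)
        layer.w = np.array([[0.9], [0.1], [-0.05], [-0.8], [0.5]])
        set_step(layer, 0.5, rng)  # 1 of 3 positive, 1 of 2 negative
        # smallest positive (0.1) and largest negative (-0.05) are pruned
        assert not (layer.mask[1, 0] and layer.w[1, 0] == 0.1)
        assert not (layer.mask[2, 0] and layer.w[2, 0] == -0.05)
        assert layer.w[0, 0] == 0.9 and layer.w[3, 0] == -0.8
        assert layer.n_connections() == 5

    def test_dense_layer_rejected(self):
        rng = np.random.default_rng(5)
        net = SparseMLP(4, [3], seed=6, density=1.0)
        with pytest.raises(ValueError):
            set_step(net.layers[0], 0.3, rng)


@pytest.fixture(scope="module")
def tiny_observations():
    from choicebias.beast import BeastConfig
    from choicebias.synth import SynthConfig, generate_lab_rates, sample_problem_space
    problems = sample_problem_space(SynthConfig(n_problems=60, seed=30))
    return generate_lab_rates(problems, BeastConfig(n_agents=400, seed=31))


class TestTrainModel:
    @pytest.mark.parametrize("kind", ["rf", "svm", "peterson"])
    def test_predictions_bounded(self, kind, tiny_observations):
        schedule = TrainSchedule(finetune_epochs=15)
        model = train_model(kind, tiny_observations, schedule=schedule, seed=1)
        preds = model.predict([o.problem for o in tiny_observations])
        assert np.all((preds >= 0) & (preds <= 1))

    def test_bourgin_reproducible_and_bounded(self, tiny_observations):
        schedule = TrainSchedule(pretrain_epochs=10, finetune_epochs=10)
        m1 = train_model("bourgin", tiny_observations, pretrain=tiny_observations,
                         schedule=schedule, seed=2)
        m2 = train_model("bourgin", tiny_observations, pretrain=tiny_observations,
                         schedule=schedule, seed=2)
        problems = [o.problem for o in tiny_observations]
        p1, p2 = m1.predict(problems), m2.predict(problems)
        assert np.array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))  # sigmoid output is open-interval

    def test_unregularized_net_overfits_tiny_dataset(self, tiny_observations):
        # dense, dropout-free MLP memorizes 10 problems
        rng = np.random.default_rng(0)
        x = base_matrix([o.problem for o in tiny_observations[:10]])
        x = (x - x.mean(0)) / np.maximum(x.std(0), 1e-9)
        y = np.array([o.b_rate for o in tiny_observations[:10]])
        net = SparseMLP(10, [200, 275, 100], seed=3, activation="srelu",
                        dropout=0.0, density=1.0, optimizer="rmsprop", lr=1e-3)
        net.fit(x, y, epochs=2000, batch_size=10)
        assert net.loss(x, y) < 1e-3

    def test_empty_training_data_rejected(self):
        with pytest.raises(ValueError):
            train_model("rf", [])

    def test_unknown_kind_rejected(self, tiny_observations):
        with pytest.raises(ValueError):
            train_model("boosted", tiny_observations)

    def test_pretrain_checkpoint_improves_start(self, tiny_observations):
        # fine-tuning at lr 1e-6 barely moves weights, so pre-training must
        # carry the fit: compare against a model fine-tuned from scratch
        from choicebias.transfer import evaluate
        schedule = TrainSchedule(pretrain_epochs=60, finetune_epochs=5)
        with_pre = train_model("bourgin", tiny_observations,
                               pretrain=tiny_observations, schedule=schedule, seed=4)
        without = train_model("bourgin", tiny_observations, schedule=schedule, seed=4)
        assert (evaluate(with_pre, tiny_observations)
                < evaluate(without, tiny_observations))
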