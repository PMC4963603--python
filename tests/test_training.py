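import math

import numpy as np
import pytest

from pathcnn.corpus_io import ValidationError
from pathcnn.embeddings import build_table
from pathcnn.network import forward, init_params
from pathcnn.sdp import PADDING, PROTEIN1, PROTEIN2
from pathcnn.training import (
    AdadeltaState,
    TrainingConfig,
    adadelta_step,
    backward,
    embedding_gradient,
    fit_network,
    gradient_check,
    nll,
)

TOKENS = (PROTEIN1, "nsubj", "binds", "dobj", PROTEIN2)


def make_tables(variant, rng, d=3, seed=5):
    pre = {w: rng.normal(size=d) for w in ("binds", "dobj")}
    vocab = set(TOKENS)
    if variant == "random":
        return [build_table(vocab, d, seed, trainable=False)]
    if variant == "random_update":
        return [build_table(vocab, d, seed, trainable=True)]
    if variant == "pretrained":
        return [build_table(vocab, d, seed, pretrained_records=pre, trainable=False)]
    return [
        build_table(vocab, d, seed, pretrained_records=pre, trainable=False),
        build_table(vocab, d, seed + 1, trainable=True),
    ]


class TestNll:
    def test_uniform_output(self):
        assert nll(np.array([0.5, 0.5]), 1) == pytest.approx(math.log(2), abs=1e-12)

    def test_confident_correct_is_near_zero(self):
        assert nll(np.array([1 - 1e-15, 1e-15]), 0) == pytest.approx(0.0, abs=1e-12)

    def test_clamp_keeps_loss_finite(self):
        assert np.isfinite(nll(np.array([1.0, 0.0]), 1))

    def test_matches_independent_log_path(self, rng):
        for _ in range(50):
            p = rng.uniform(0.01, 0.99)
            S = np.array([p, 1 - p])
            y = int(rng.integers(0, 2))
            assert nll(S, y) == pytest.approx(-math.log(S[y]), rel=1e-12)


class TestBackward:
    @pytest.mark.parametrize("variant", ["random", "random_update", "pretrained", "combined"])
    def test_finite_difference_agreement(self, variant, rng):
        """Analytic gradients match central finite differences (step 1e-5)
        within 1e-4 for every parameter, in all four embedding variants."""
        tables = make_tables(variant, rng)
        params = init_params(n_fixed=5, dim=3, window=3, n_filters=2, hidden=4,
                             n_channels=len(tables), seed=3)
        for y in (0, 1):
            assert gradient_check(params, tables, TOKENS, y, step=1e-5) < 1e-4

    def test_gradient_zero_off_argmax(self, rng):
        """Pooling routes gradient only into the argmax window: positions
        of P outside every selected window receive zero gradient."""
        tables = make_tables("random", rng)
        params = init_params(n_fixed=5, dim=3, window=3, n_filters=2, hidden=4, seed=3)
        P = np.stack([np.stack([tables[0].vector(t) for t in TOKENS])])
        trace = forward(P, params)
        grads = backward(trace, 1, params)
        covered = set()
        for m in range(2):
            p = int(trace.argmax_positions[0, m])
            covered.update(range(p, p + 3))
        for i in set(range(5)) - covered:
            np.testing.assert_array_equal(grads.dP[0, i], 0.0)

    def test_padding_row_gradient_is_zero(self, rng):
        tables = make_tables("random_update", rng)
        toks = (PROTEIN1, "nsubj", PROTEIN2, PADDING, PADDING)
        params = init_params(n_fixed=5, dim=3, window=3, n_filters=2, hidden=4, seed=3)
        P = np.stack([np.stack([tables[0].vector(t) for t in toks])])
        trace = forward(P, params)
        grads = backward(trace, 0, params)
        dD = embedding_gradient(grads.dP[0], toks, tables[0])
        np.testing.assert_array_equal(dD[tables[0].padding_row], 0.0)


class TestAdadelta:
    def test_zero_gradient_leaves_parameters_unchanged(self, rng):
        theta = {"w": rng.normal(size=4)}
        before = theta["w"].copy()
        state = AdadeltaState()
        adadelta_step(theta, {"w": np.zeros(4)}, state)
        np.testing.assert_array_equal(theta["w"], before)

    def test_first_step_closed_form(self, rng):
        rho, eps = 0.95, 1e-6
        g = rng.normal(size=3)
        theta = {"w": np.zeros(3)}
        adadelta_step(theta, {"w": g}, AdadeltaState(), rho, eps)
        expected = -np.sqrt(eps) / np.sqrt((1 - rho) * g**2 + eps) * g
        np.testing.assert_allclose(theta["w"], expected, rtol=1e-12)
        assert np.all(np.sign(theta["w"]) == -np.sign(g))

    def test_descends_convex_quadratic(self):
        """On f(x) = x'Ax the objective decreases monotonically after a
        short accumulator burn-in."""
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        x = {"x": np.array([3.0, -2.0])}
        state = AdadeltaState()
        values = []
        for _ in range(100):
            values.append(float(x["x"] @ A @ x["x"]))
            adadelta_step(x, {"x": 2 * A @ x["x"]}, state)
        tail = values[10:]
        assert all(b <= a + 1e-12 for a, b in zip(tail, tail[1:]))
        assert values[-1] < values[0]


class TestFitNetwork:
    def _data(self, rng, n=20):
        verbs = {1: "binds", 0: "near"}
        seqs, labels = [], []
        for i in range(n):
            y = i % 2
            seqs.append((PROTEIN1, "nsubj", verbs[y], "dobj", PROTEIN2))
            labels.append(y)
        return seqs, labels

    def _vocab(self, seqs):
        return {t for s in seqs for t in s} | {PADDING}

    def test_determinism_same_seed(self, rng):
        seqs, labels = self._data(rng)
        results = []
        for _ in range(2):
            table = build_table(self._vocab(seqs), 4, seed=2, trainable=True)
            params = init_params(n_fixed=5, dim=4, window=3, n_filters=3, hidden=4, seed=2)
            losses, _ = fit_network(seqs, labels, [table], params, TrainingConfig(epochs=3, seed=9))
            results.append((params.W.copy(), table.D.copy(), losses))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        np.testing.assert_array_equal(results[0][1], results[1][1])
        assert results[0][2] == results[1][2]

    def test_loss_finite_every_epoch(self, rng):
        seqs, labels = self._data(rng)
        table = build_table(self._vocab(seqs), 4, seed=2)
        params = init_params(n_fixed=5, dim=4, window=3, n_filters=3, hidden=4, seed=2)
        losses, _ = fit_network(seqs, labels, [table], params, TrainingConfig(epochs=5, seed=0))
        assert all(np.isfinite(l) for l in losses)

    def test_loss_decreases_on_separable_data(self, rng):
        """Mean epoch loss drops over the first epochs on separable data,
        for the majority of seeds."""
        seqs, labels = self._data(rng, n=30)
        wins = 0
        for seed in range(5):
            table = build_table(self._vocab(seqs), 6, seed=seed)
            params = init_params(n_fixed=5, dim=6, window=3, n_filters=4, hidden=8, seed=seed)
            losses, _ = fit_network(seqs, labels, [table], params,
                                    TrainingConfig(epochs=5, seed=seed))
            wins += losses[4] < losses[0]
        assert wins >= 3

    def test_frozen_table_bit_unchanged(self, rng):
        seqs, labels = self._data(rng)
        table = build_table(self._vocab(seqs), 4, seed=2, trainable=False)
        before = table.D.copy()
        params = init_params(n_fixed=5, dim=4, window=3, n_filters=3, hidden=4, seed=2)
        fit_network(seqs, labels, [table], params, TrainingConfig(epochs=3, seed=0))
        np.testing.assert_array_equal(table.D, before)

    def test_trainable_updates_only_observed_rows(self, rng):
        seqs, labels = self._data(rng)
        vocab = self._vocab(seqs) | {"unobserved-token"}
        table = build_table(vocab, 4, seed=2, trainable=True)
        before = table.D.copy()
        params = init_params(n_fixed=5, dim=4, window=3, n_filters=3, hidden=4, seed=2)
        fit_network(seqs, labels, [table], params, TrainingConfig(epochs=3, seed=0))
        observed = {t for s in seqs for t in s}
        changed = {w for w, i in table.vocab.items() if not np.array_equal(table.D[i], before[i])}
        assert changed <= observed
        assert changed  # training did move some embeddings
        np.testing.assert_array_equal(
            table.D[table.vocab["unobserved-token"]], before[table.vocab["unobserved-token"]]
        )
        np.testing.assert_array_equal(table.D[table.padding_row], 0.0)

    def test_single_class_warns_but_trains(self, rng, caplog):
        seqs, labels = self._data(rng)
        labels = [1] * len(labels)
        table = build_table(self._vocab(seqs), 4, seed=2)
        params = init_params(n_fixed=5, dim=4, window=3, n_filters=3, hidden=4, seed=2)
        fit_network(seqs, labels, [table], params, TrainingConfig(epochs=1, seed=0))
        assert any("single class" in r.message for r in caplog.records)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            fit_network([], [], [], None, TrainingConfig(epochs=1))


class TestTrainingConfig:
    @pytest.mark.parametrize("kw", [{"epochs": 0}, {"rho": 1.0}, {"rho": 0.0},
                                    {"eps": 0.0}, {"variant": "bogus"}])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValidationError):
            TrainingConfig(**kw)
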