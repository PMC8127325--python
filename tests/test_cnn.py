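"""Convolutional classifier: architecture, splits, balancing, grid, training."""

import numpy as np
import pytest

from introness import cnn
from introness.encoding import encode_windows
from introness.scoring import roc_auc

import oracles


class TestBuildModel:
    def test_zero_weights_give_half(self):
        m = cnn.build_model(cnn.CnnConfig(n_filters=4, window=4, fc_units=4), 50)
        for k in m.net.params:
            m.net.params[k][...] = 0.0
        probs = m.net.predict_proba(np.random.default_rng(0).random((5, 50, 4)))
        assert np.allclose(probs, 0.5)

    def test_probabilities_normalized(self, rng):
        m = cnn.build_model(cnn.CnnConfig(n_filters=8, window=6, seed=1), 60)
        probs = m.net.predict_proba(rng.random((7, 60, 4)).astype(np.float32))
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_closed_form(self):
        cfg = cnn.CnnConfig(n_filters=32, window=16, fc_units=64)
        m = cnn.build_model(cfg, 500)
        assert m.n_parameters() == oracles.conv_param_count(32, 16, 64)

    def test_window_exceeding_input_errors(self):
        with pytest.raises(ValueError):
            cnn.build_model(cnn.CnnConfig(window=200), 100)


class TestGroupedSplit:
    def _genes(self, n=100):
        ids = [f"g{i}" for i in range(n)]
        labels = ["essential" if i % 2 else "nonessential" for i in range(n)]
        return ids, labels

    def test_test_fraction(self):
        ids, labels = self._genes(100)
        plan = cnn.grouped_split(ids, labels, test_fraction=0.2, seed=0)
        assert len(plan.genes("test")) == 20

    def test_deterministic(self):
        ids, labels = self._genes()
        p1 = cnn.grouped_split(ids, labels, seed=7)
        p2 = cnn.grouped_split(ids, labels, seed=7)
        assert p1.assignment == p2.assignment

    def test_partitions_disjoint_and_exhaustive_over_seeds(self):
        ids, labels = self._genes(60)
        for seed in range(50):
            plan = cnn.grouped_split(ids, labels, seed=seed)
            assert sorted(plan.assignment) == sorted(ids)
            parts = set(plan.assignment.values())
            assert parts <= {"test", "cv1", "cv2", "cv3"}

    def test_stratified(self):
        ids, labels = self._genes(100)
        plan = cnn.grouped_split(ids, labels, test_fraction=0.2, seed=3)
        test_labels = [labels[ids.index(g)] for g in plan.genes("test")]
        assert test_labels.count("essential") == 10

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            cnn.grouped_split(["a", "b"], ["essential", "nonessential"])


class TestBalancedBatches:
    def test_epoch_class_totals_equal(self, rng):
        y = np.array([1] * 10 + [0] * 90)
        batches = list(cnn.balanced_batches(y, 10, rng))
        drawn = np.concatenate(batches)
        assert (y[drawn] == 1).sum() == (y[drawn] == 0).sum() == 90

    def test_within_batch_balance(self, rng):
        y = np.array([1] * 10 + [0] * 90)
        for b in cnn.balanced_batches(y, 10, rng):
            n1 = int(y[b].sum())
            assert abs(n1 - (len(b) - n1)) <= 1

    def test_fixed_seed_identical_stream(self):
        y = np.array([1] * 20 + [0] * 30)
        b1 = list(cnn.balanced_batches(y, 8, np.random.default_rng(5)))
        b2 = list(cnn.balanced_batches(y, 8, np.random.default_rng(5)))
        assert all(np.array_equal(a, b) for a, b in zip(b1, b2))


class TestGridSearch:
    def test_default_grid_has_36_configs(self):
        grid = cnn.default_grid()
        assert len(grid) == 36
        assert len(set(grid)) == 36  # all distinct

    def test_grid_spans_stated_axes(self):
        grid = cnn.default_grid()
        assert {c.dropout for c in grid} == {0.0, 0.2, 0.5}
        assert {c.window for c in grid} == {16, 24}
        assert {c.activation for c in grid} == {"relu", "elu"}
        assert {c.l2 for c in grid} == {1e-4, 1e-6, 0.0}

    def test_single_combo_returned(self):
        cfg = cnn.CnnConfig()
        best, _ = cnn.grid_search([cfg], lambda c, f: 0.5)
        assert best == cfg

    def test_planted_winner_selected(self):
        grid = cnn.default_grid()
        target = grid[17]

        def evaluate(c, fold):
            return 0.9 if c == target else 0.6 + 0.001 * fold

        best, table = cnn.grid_search(grid, evaluate)
        assert best == target
        assert len(table) == 36

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            cnn.grid_search([], lambda c, f: 0.5)


def _planted_toy(rng, n=200, length=120):
    """Introns where a fixed motif is present iff the gene is essential."""
    motif = "TAACGTTGGAT"
    seqs, ys = [], []
    for i in range(n):
        y = i % 2
        s = list("GT" + "".join(rng.choice(list("ACGT"), length - 4)) + "AG")
        if y:
            pos = int(rng.integers(5, length - len(motif) - 5))
            s[pos : pos + len(motif)] = list(motif)
        seqs.append("".join(s))
        ys.append(y)
    return seqs, np.array(ys)


class TestTrain:
    def test_separable_toy_learns(self, rng):
        seqs, y = _planted_toy(rng)
        X = encode_windows(seqs, "first", k=120)
        cfg = cnn.CnnConfig(n_filters=8, window=12, fc_units=16, dropout=0.0,
                            epochs=30, seed=0)
        m = cnn.build_model(cfg, 120)
        cnn.train(m, X, y, seed=0)
        auc = roc_auc(cnn.score_introns(m, X), y).auc
        assert auc > 0.9

    def test_label_permutation_null(self, rng):
        seqs, y = _planted_toy(rng, n=150)
        y_perm = rng.permutation(y)
        X = encode_windows(seqs, "first", k=120)
        cfg = cnn.CnnConfig(n_filters=8, window=12, fc_units=16, dropout=0.0,
                            epochs=5, seed=1)
        m = cnn.build_model(cfg, 120)
        cnn.train(m, X[:100], y_perm[:100], seed=1)
        auc = roc_auc(cnn.score_introns(m, X[100:]), y_perm[100:]).auc
        assert 0.3 < auc < 0.7

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        seqs, y = _planted_toy(rng, n=20)
        X = encode_windows(seqs, "first", k=120)
        cfg = cnn.CnnConfig(n_filters=4, window=8, fc_units=8, epochs=0, seed=2)
        m = cnn.build_model(cfg, 120)
        before = {k: v.copy() for k, v in m.net.params.items()}
        cnn.train(m, X, y, seed=2)
        assert all(np.array_equal(before[k], m.net.params[k]) for k in before)

    def test_training_deterministic(self, rng):
        seqs, y = _planted_toy(rng, n=60)
        X = encode_windows(seqs, "first", k=120)
        cfg = cnn.CnnConfig(n_filters=4, window=8, fc_units=8, epochs=2, seed=3)
        runs = []
        for _ in range(2):
            m = cnn.build_model(cfg, 120)
            cnn.train(m, X, y, seed=3)
            runs.append(cnn.score_introns(m, X))
        assert np.array_equal(runs[0], runs[1])

    def test_batch_scoring_matches_one_by_one(self, rng):
        seqs, y = _planted_toy(rng, n=30)
        X = encode_windows(seqs, "first", k=120)
        m = cnn.build_model(cnn.CnnConfig(n_filters=4, window=8, seed=4), 120)
        batch = cnn.score_introns(m, X)
        single = np.array([cnn.score_introns(m, X[i : i + 1])[0] for i in range(30)])
        assert np.allclose(batch, single, atol=1e-6)


class TestSaveLoad:
    def test_round_trip(self, tmp_path, rng):
        seqs, y = _planted_toy(rng, n=30)
        X = encode_windows(seqs, "first", k=120)
        cfg = cnn.CnnConfig(n_filters=4, window=8, fc_units=8, epochs=1, seed=5)
        m = cnn.build_model(cfg, 120, "last_window")
        cnn.train(m, X, y, seed=5)
        path = tmp_path / "model.npz"
        cnn.save_model(m, path)
        back = cnn.load_model(path)
        assert back.config == cfg
        assert back.input_kind == "last_window"
        assert np.allclose(cnn.score_introns(back, X), cnn.score_introns(m, X))
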