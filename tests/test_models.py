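import numpy as np
import pytest

from secgram import _autodiff as ad
from secgram.models import (
    CNNSecretionClassifier, GRUCellParams, GRUSecretionClassifier,
    LSTMCellParams, LSTMSecretionClassifier, ModelSpec,
    RandomForestSecretionClassifier, SVMSecretionClassifier, TrainConfig,
    auroc_score, build_model, class_weights, downsample_majority, evaluate,
    gru_step, lstm_step, stratified_split, threshold_at_specificity, train,
)


def scalar_sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_gru(x, h, p):
    """Independent scalar transcription of the printed GRU equations."""
    z = scalar_sigmoid(p["Wz"] * x + p["Uz"] * h + p["bz"])
    r = scalar_sigmoid(p["Wr"] * x + p["Ur"] * h + p["br"])
    hp = np.tanh(p["Wh"] * x + p["Uh"] * (r * h) + p["bh"])
    return (1 - z) * h + z * hp


def oracle_lstm(x, h, c, p):
    i = scalar_sigmoid(p["Wi"] * x + p["Ui"] * h + p["bi"])
    f = scalar_sigmoid(p["Wf"] * x + p["Uf"] * h + p["bf"])
    o = scalar_sigmoid(p["Wo"] * x + p["Uo"] * h + p["bo"])
    c_new = f * c + i * np.tanh(p["Wc"] * x + p["Uc"] * h + p["bc"])
    return o * np.tanh(c_new), c_new


def zeros_gru(d=1, h=1):
    z = np.zeros
    return GRUCellParams(z((d, h)), z((h, h)), z(h), z((d, h)), z((h, h)), z(h),
                         z((d, h)), z((h, h)), z(h))


def zeros_lstm(d=1, h=1):
    z = np.zeros
    return LSTMCellParams(*([z((d, h)), z((h, h)), z(h)] * 4))


class TestCellRecurrences:
    def test_gru_zero_params_closed_form(self):
        # sigma(0)=0.5, tanh(0)=0 => h_new = 0.5 * h_prev
        h = gru_step(np.zeros(1), np.array([0.8]), zeros_gru())
        assert h == pytest.approx([0.4])

    def test_gru_carry_gate_saturation(self):
        p = zeros_gru()
        p.b_z[:] = -50.0  # z ~ 0 => h_new ~ h_prev
        h = gru_step(np.zeros(1), np.array([0.8]), p)
        assert h == pytest.approx([0.8], abs=1e-12)

    def test_lstm_zero_params_closed_form(self):
        h, c = lstm_step(np.zeros(1), np.zeros(1), np.array([1.0]), zeros_lstm())
        assert c == pytest.approx([0.5])
        assert h == pytest.approx([0.5 * np.tanh(0.5)])

    def test_lstm_zero_cell(self):
        h, c = lstm_step(np.zeros(1), np.zeros(1), np.zeros(1), zeros_lstm())
        assert h == pytest.approx([0.0])

    def test_gru_matches_scalar_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            vals = {k: rng.normal() for k in
                    ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh")}
            p = GRUCellParams(
                np.array([[vals["Wz"]]]), np.array([[vals["Uz"]]]), np.array([vals["bz"]]),
                np.array([[vals["Wr"]]]), np.array([[vals["Ur"]]]), np.array([vals["br"]]),
                np.array([[vals["Wh"]]]), np.array([[vals["Uh"]]]), np.array([vals["bh"]]),
            )
            x, h = rng.normal(), rng.normal()
            got = gru_step(np.array([x]), np.array([h]), p)[0]
            assert got == pytest.approx(oracle_gru(x, h, vals), abs=1e-12)

    def test_lstm_matches_scalar_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            vals = {k: rng.normal() for k in
                    ("Wi", "Ui", "bi", "Wf", "Uf", "bf", "Wo", "Uo", "bo",
                     "Wc", "Uc", "bc")}
            p = LSTMCellParams(
                np.array([[vals["Wi"]]]), np.array([[vals["Ui"]]]), np.array([vals["bi"]]),
                np.array([[vals["Wf"]]]), np.array([[vals["Uf"]]]), np.array([vals["bf"]]),
                np.array([[vals["Wo"]]]), np.array([[vals["Uo"]]]), np.array([vals["bo"]]),
                np.array([[vals["Wc"]]]), np.array([[vals["Uc"]]]), np.array([vals["bc"]]),
            )
            x, h, c = rng.normal(), rng.normal(), rng.normal()
            gh, gc = lstm_step(np.array([x]), np.array([h]), np.array([c]), p)
            oh, oc = oracle_lstm(x, h, c, vals)
            assert gh[0] == pytest.approx(oh, abs=1e-12)
            assert gc[0] == pytest.approx(oc, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gru_step(np.zeros(3), np.zeros(1), zeros_gru(d=1, h=1))
        with pytest.raises(ValueError):
            lstm_step(np.zeros(3), np.zeros(1), np.zeros(1), zeros_lstm())

    def test_fused_layer_matches_stepwise_cell(self):
        """The training-path GRU layer and the reference gru_step agree."""
        rng = np.random.default_rng(13)
        clf = GRUSecretionClassifier(hidden_size=6, n_layers=1, max_len=9)
        params = clf._init_params(np.random.default_rng(13))
        X = rng.random((2, 9, 4))
        mask = np.ones((2, 9))
        out = ad.gru_layer(ad.Tensor(X), mask, params, 0)
        cell = GRUCellParams(
            params["W_z0"].data, params["U_z0"].data, params["b_z0"].data.ravel(),
            params["W_r0"].data, params["U_r0"].data, params["b_r0"].data.ravel(),
            params["W_h0"].data, params["U_h0"].data, params["b_h0"].data.ravel(),
        )
        h = np.zeros((2, 6))
        for t in range(9):
            h = gru_step(X[:, t], h, cell)
        np.testing.assert_allclose(out.data[:, -1], h, atol=1e-12)


class TestClassWeights:
    def test_inverse_frequency(self):
        w = class_weights({"IC": 100, "EC": 25})
        assert w == {"IC": pytest.approx(0.625), "EC": pytest.approx(2.5)}

    def test_balanced_is_unit(self):
        assert class_weights({"IC": 50, "EC": 50}) == {"IC": 1.0, "EC": 1.0}

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights({"IC": 10, "EC": 0})

    def test_unit_weights_recover_unweighted_loss(self):
        rng = np.random.default_rng(14)
        logits = ad.Tensor(rng.normal(size=(8, 1)))
        y = rng.integers(0, 2, 8).astype(float)
        lw = ad.weighted_bce_with_logits(logits, y, np.ones(8))
        z = logits.data.ravel()
        unweighted = np.mean(np.logaddexp(0, z) - y * z)
        assert float(lw.data) == pytest.approx(unweighted)

    def test_loss_symmetric_under_label_and_weight_swap(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=(10, 1))
        y = rng.integers(0, 2, 10).astype(float)
        w = np.where(y == 1, 2.5, 0.625)
        loss = float(ad.weighted_bce_with_logits(ad.Tensor(z), y, w).data)
        # swapping class labels and the weight map together leaves every
        # item's weight unchanged while flipping labels and logits
        loss2 = float(ad.weighted_bce_with_logits(ad.Tensor(-z), 1 - y, w).data)
        assert loss == pytest.approx(loss2)


class TestBuildModel:
    def test_rf_spec(self):
        m = build_model(ModelSpec("rf", {"n_trees": 50, "max_depth": 20}))
        assert isinstance(m, RandomForestSecretionClassifier)
        assert m.n_trees == 50 and m.max_depth == 20

    def test_cnn_default_head(self):
        m = build_model(ModelSpec("cnn"))
        assert m.head_widths == (1024, 128)

    def test_gru_parameter_count_closed_form(self):
        # per cell: 3 gates x (d*H + H*H + H); head: H + 1
        m = build_model(ModelSpec("gru", {"hidden_size": 32, "n_layers": 2}))
        params = m._init_params(np.random.default_rng(0))
        total = sum(p.data.size for p in params.values())
        H = 32
        expected = (3 * (4 * H + H * H + H)) + (3 * (H * H + H * H + H)) + H + 1
        assert total == expected

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("transformer")


class TestXavier:
    def test_variance_close_to_glorot(self):
        rng = np.random.default_rng(16)
        w = ad.xavier(rng, 100, 100, shape=(10000,))
        target = 2.0 / (100 + 100)
        assert abs(w.var() - target) / target < 0.2


class TestTrainingFixture:
    def test_perfect_separation_and_history(self, tiny_planted, tiny_gru):
        seqs, labels = tiny_planted
        probs = tiny_gru.secretion_probability(seqs)
        acc = ((probs >= 0.5).astype(int) == labels).mean()
        assert acc == 1.0
        # training loss non-increasing over first 5 epochs (<= 1 increase)
        tl = tiny_gru.history_["train_loss"][:5]
        increases = sum(b > a for a, b in zip(tl, tl[1:]))
        assert increases <= 1
        assert probs[labels == 1].mean() > probs[labels == 0].mean()

    def test_determinism_same_seed_same_params(self, tiny_planted):
        seqs, labels = tiny_planted
        kw = dict(hidden_size=8, n_layers=1, max_epochs=5, batch_size=16,
                  validation_fraction=0.0, random_state=3)
        a = GRUSecretionClassifier(**kw).fit(seqs, labels)
        b = GRUSecretionClassifier(**kw).fit(seqs, labels)
        for k in a.params_:
            np.testing.assert_array_equal(a.params_[k].data, b.params_[k].data)

    def test_batch_vs_single_inference(self, tiny_planted, tiny_gru):
        seqs, _ = tiny_planted
        batch = tiny_gru.secretion_probability(seqs[:5])
        single = [tiny_gru.secretion_probability([s])[0] for s in seqs[:5]]
        np.testing.assert_allclose(batch, single, atol=1e-12)

    def test_checkpoint_round_trip(self, tiny_gru, tiny_planted, tmp_path):
        seqs, _ = tiny_planted
        path = tmp_path / "model.npz"
        tiny_gru.save(path)
        loaded = GRUSecretionClassifier.load(path)
        np.testing.assert_allclose(
            tiny_gru.secretion_probability(seqs),
            loaded.secretion_probability(seqs),
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            GRUSecretionClassifier(max_epochs=1).fit(["ACGTACGT"] * 4, [1, 1, 1, 1])

    def test_lstm_and_cnn_learn_the_fixture(self, tiny_planted):
        seqs, labels = tiny_planted
        for cls, kw in (
            (LSTMSecretionClassifier,
             dict(hidden_size=16, n_layers=1, learning_rate=0.01, batch_size=40,
                  max_epochs=150, patience=150, dropout=0.0,
                  validation_fraction=0.0, random_state=0)),
            (CNNSecretionClassifier,
             dict(conv_plan=((16, 1),), head_widths=(32, 16), learning_rate=0.005,
                  batch_size=40, max_epochs=120, patience=120,
                  validation_fraction=0.0, random_state=0)),
        ):
            clf = cls(**kw).fit(seqs, labels)
            probs = clf.secretion_probability(seqs)
            assert auroc_score(labels, probs) > 0.95, cls.__name__

    def test_classical_models_fit_tabular(self, tiny_planted):
        from secgram.features import featurize_records
        from secgram.io import SmallRNARecord

        seqs, labels = tiny_planted
        recs = [SmallRNARecord(f"r{i}", s) for i, s in enumerate(seqs)]
        X, _names = featurize_records(recs, ks=[1, 2, 3])
        for model in (SVMSecretionClassifier(kernel="linear"),
                      RandomForestSecretionClassifier(n_trees=50)):
            model.fit(X, labels)
            probs = model.secretion_probability(X)
            assert auroc_score(labels, probs) > 0.8


class TestTrainRegime:
    def test_downsampling_and_split_fractions(self):
        rng = np.random.default_rng(17)
        y = np.array([1] * 50 + [0] * 500)
        X = np.arange(550.0).reshape(-1, 1)
        Xd, yd, kept = downsample_majority(X, y, ratio=4.0, rng=rng)
        assert (yd == 1).sum() == 50
        assert (yd == 0).sum() == 200
        tr, va, te = stratified_split(yd, (0.8, 0.1, 0.1), seed=0)
        assert len(tr) + len(va) + len(te) == len(yd)
        assert abs(len(tr) - 0.8 * len(yd)) <= 2
        # stratification preserves class ratio in each split
        for idx in (tr, va, te):
            frac_pos = (yd[idx] == 1).mean()
            assert abs(frac_pos - 0.2) < 0.05

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split_fractions=(0.7, 0.2, 0.2))

    def test_train_wrapper_runs_deep(self, tiny_planted):
        seqs, labels = tiny_planted
        clf = GRUSecretionClassifier(hidden_size=8, n_layers=1)
        model, hist = train(clf, list(seqs), labels,
                            TrainConfig(seed=0, max_epochs=3, batch_size=16,
                                        ic_downsample_ratio=1.0,
                                        split_fractions=(0.6, 0.2, 0.2)))
        assert "train_loss" in hist and len(hist["train_loss"]) <= 3
        assert {"train_idx", "val_idx", "test_idx"} <= set(hist)


class TestEvaluate:
    def test_perfect_separation(self):
        r = evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auroc == 1.0
        assert r.auprc == 1.0
        assert (r.tp, r.fp, r.tn, r.fn) == (2, 0, 2, 0)

    def test_inverted(self):
        r = evaluate([0.1, 0.9], [1, 0])
        assert r.auroc == 0.0

    def test_at_specificity_picks_smallest_threshold(self):
        probs = [0.95, 0.9, 0.1, 0.2, 0.6, 0.8]
        labels = [1, 1, 0, 0, 0, 0]
        r = evaluate(probs, labels, at_specificity=0.75)
        assert 0.6 < r.threshold <= 0.8
        assert r.specificity == pytest.approx(3 / 4)

    def test_auroc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = np.round(rng.random(n), 1)  # force ties
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
            oracle = wins / (len(pos) * len(neg))
            assert auroc_score(y, p) == pytest.approx(oracle)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            evaluate([0.5, 0.6], [1, 1])

    def test_bootstrap_band_shape_and_bounds(self):
        rng = np.random.default_rng(19)
        probs = rng.random(60)
        labels = (probs + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        r = evaluate(probs, labels, bootstrap=50, seed=4)
        band = r.roc_band
        assert band["fpr"].shape == band["tpr_mean"].shape
        assert np.all(band["tpr_lo"] <= band["tpr_hi"])
        assert np.all((band["tpr_mean"] >= 0) & (band["tpr_mean"] <= 1))

    def test_threshold_at_specificity_direct(self):
        t = threshold_at_specificity(np.array([0.1, 0.2, 0.6, 0.8]), 0.75)
        assert 0.6 < t <= 0.8
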