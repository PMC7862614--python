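"""Autoencoder unit behavior on tiny models (full-scale regression lives in
test_acceptance)."""

import numpy as np
import pytest

from cgrgen.autoencoder import (
    AEConfig,
    Seq2SeqAutoencoder,
    TrainConfig,
    build_model,
    lstm_param_count,
)
from cgrgen.errors import ConfigError, DataError, VocabularyError
from cgrgen.tokenizer import Vocabulary

TINY = ["CCO", "OCC", "CC(=O)O", "c1ccccc1", "OB(O)C"]


@pytest.fixture(scope="module")
def vocab():
    return Vocabulary.from_corpus(TINY)


class TestBuild:
    def test_default_architecture_report(self, vocab):
        model = build_model(AEConfig(), vocab)
        report = dict((n, shape) for n, shape, _c in model.layer_report())
        # two bidirectional encoder layers of 128 units
        assert report["enc0_fwd.U"] == (128, 512)
        assert report["enc1_bwd.U"] == (128, 512)
        # bottleneck dense of width 128 fed by all final states
        assert report["bottleneck.W"] == (2 * 128 * 2, 128)
        # two forward decoder layers of 256 units
        assert report["dec0.U"] == (256, 1024)
        assert report["dec1.U"] == (256, 1024)
        # per-position softmax over the vocabulary
        assert report["out.W"] == (256, len(vocab))

    def test_single_token_vocab_builds(self):
        v = Vocabulary(["C"])
        model = build_model(AEConfig(max_len=4, latent_dim=3, enc_layers=1,
                                     enc_units=2, dec_layers=1, dec_units=2), v)
        assert model.num_params() > 0

    def test_param_count_follows_closed_form(self, vocab):
        V = len(vocab)
        cfg = AEConfig(max_len=16, latent_dim=8, enc_layers=1, enc_units=64,
                       dec_layers=1, dec_units=128)
        model = build_model(cfg, vocab)
        expected = (
            2 * lstm_param_count(V, 64)  # bidirectional encoder
            + (2 * 64) * 8 + 8  # bottleneck
            + 8 * (2 * 128) + 2 * 128  # decoder state init
            + lstm_param_count(V + 8, 128)  # decoder (input + latent)
            + 128 * V + V  # output projection
        )
        assert model.num_params() == expected
        half = build_model(
            AEConfig(max_len=16, latent_dim=8, enc_layers=1, enc_units=32,
                     dec_layers=1, dec_units=64), vocab)
        assert half.num_params() < model.num_params()

    def test_bad_config_rejected(self, vocab):
        with pytest.raises(ConfigError):
            build_model(AEConfig(latent_dim=0), vocab)

    def test_deterministic_init(self, vocab):
        a = build_model(AEConfig(max_len=8, latent_dim=4, enc_layers=1,
                                 enc_units=4, dec_layers=1, dec_units=4), vocab, seed=5)
        b = build_model(AEConfig(max_len=8, latent_dim=4, enc_layers=1,
                                 enc_units=4, dec_layers=1, dec_units=4), vocab, seed=5)
        for (n1, p1, _), (n2, p2, _) in zip(a.parameters(), b.parameters()):
            assert n1 == n2
            assert np.array_equal(p1, p2)


@pytest.fixture(scope="module")
def memorizer(vocab):
    cfg = AEConfig(max_len=16, latent_dim=12, enc_layers=1, enc_units=24,
                   dec_layers=1, dec_units=48)
    model = Seq2SeqAutoencoder(cfg, vocab, seed=0)
    model.train(TINY, TrainConfig(lr=0.01, batch_size=8, max_epochs=150,
                                  patience=5, val_fraction=0.0, seed=0))
    return model


class TestTrain:
    def test_tiny_corpus_memorized(self, memorizer):
        rate, hits = memorizer.reconstruction_rate(TINY)
        assert rate == 1.0
        assert hits == len(TINY)

    def test_history_records_losses_and_lr(self, memorizer):
        hist = memorizer.history
        assert hist[0]["train_loss"] > hist[-1]["train_loss"]
        assert all({"epoch", "train_loss", "val_loss", "lr"} <= set(h) for h in hist)

    def test_plateau_reduces_lr(self, vocab):
        cfg = AEConfig(max_len=16, latent_dim=4, enc_layers=1, enc_units=4,
                       dec_layers=1, dec_units=4)
        model = Seq2SeqAutoencoder(cfg, vocab, seed=0)
        # learning rate of zero cannot improve: plateau must trigger
        hist = model.train(TINY, TrainConfig(lr=1e-12, min_lr=1e-15, batch_size=8,
                                             max_epochs=6, patience=2, seed=0))
        events = [e for h in hist for e in h["events"]]
        assert any(e.startswith("lr_reduced") for e in events)

    def test_empty_corpus_rejected(self, vocab):
        model = build_model(AEConfig(max_len=8, latent_dim=4, enc_layers=1,
                                     enc_units=4, dec_layers=1, dec_units=4), vocab)
        with pytest.raises(DataError):
            model.train([], TrainConfig())

    def test_reproducible_training(self, vocab):
        losses = []
        for _ in range(2):
            cfg = AEConfig(max_len=16, latent_dim=6, enc_layers=1, enc_units=8,
                           dec_layers=1, dec_units=8)
            model = Seq2SeqAutoencoder(cfg, vocab, seed=3)
            hist = model.train(TINY, TrainConfig(lr=0.01, batch_size=8,
                                                 max_epochs=3, seed=3))
            losses.append([h["train_loss"] for h in hist])
        assert np.allclose(losses[0], losses[1], rtol=1e-6)


class TestEncodeDecode:
    def test_roundtrip_identity_on_memorized(self, memorizer):
        z = memorizer.encode(TINY)
        assert z.shape == (len(TINY), 12)
        assert np.isfinite(z).all()
        assert memorizer.decode(z) == TINY

    def test_greedy_decoding_deterministic(self, memorizer):
        z = memorizer.encode(TINY[:2])
        assert memorizer.decode(z) == memorizer.decode(z)

    def test_perturbed_latents_report_parse_rate(self, memorizer):
        from cgrgen.smiles import parse_smiles_cgr

        rng = np.random.default_rng(0)
        z = memorizer.encode(TINY)
        noisy = np.repeat(z, 10, axis=0) + rng.normal(0, 0.05, (len(TINY) * 10, 12))
        decoded = memorizer.decode(noisy.astype(np.float32))
        ok = 0
        for s in decoded:
            try:
                parse_smiles_cgr(s)
                ok += 1
            except Exception:
                pass
        assert 0 <= ok <= len(decoded)  # rate reported, no threshold asserted

    def test_oov_token_rejected(self, memorizer):
        with pytest.raises(VocabularyError):
            memorizer.encode(["CN"])

    def test_untrained_model_reconstructs_nothing(self, vocab):
        model = build_model(AEConfig(max_len=16, latent_dim=6, enc_layers=1,
                                     enc_units=8, dec_layers=1, dec_units=8), vocab)
        rate, _ = model.reconstruction_rate(TINY)
        assert rate <= 0.2

    def test_save_load_roundtrip(self, memorizer, tmp_path):
        path = tmp_path / "model.npz"
        memorizer.save(path)
        again = Seq2SeqAutoencoder.load(path)
        assert again.decode(again.encode(TINY)) == TINY
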