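"""Sequence-to-sequence recurrent autoencoder over tokenized SMILES/CGR.

Architecture: one-hot token input -> stacked bidirectional LSTM encoder ->
dense bottleneck producing the latent vector -> stacked forward LSTM decoder
(teacher forcing during training; greedy argmax or temperature sampling at
generation time) -> per-position token softmax.  The bottleneck consumes the
concatenated final hidden states of every encoder layer and direction; the
latent vector is additionally concatenated to the decoder input at every
step so that generation from sampled latent vectors does not rely on the
initial state alone.

Implemented directly on numpy (forward and backward passes, Adam,
plateau learning-rate schedule); float32 arithmetic throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, VocabularyError
from .tokenizer import EOS, PAD, SOS, Vocabulary, detokenize, tokenize

F32 = np.float32


@dataclass
class AEConfig:
    """Network shape; defaults follow the full-scale architecture."""

    max_len: int = 256
    latent_dim: int = 128
    enc_layers: int = 2
    enc_units: int = 128
    dec_layers: int = 2
    dec_units: int = 256

    def validate(self):
        if min(self.max_len, self.latent_dim, self.enc_layers, self.enc_units,
               self.dec_layers, self.dec_units) <= 0:
            raise ConfigError("all AEConfig dimensions must be positive")


@dataclass
class TrainConfig:
    lr: float = 0.005
    batch_size: int = 256
    patience: int = 2
    max_epochs: int = 34
    seed: int = 0
    lr_factor: float = 0.5
    min_lr: float = 1e-5
    min_delta: float = 1e-4
    clip_norm: float = 5.0
    val_fraction: float = 0.1

    def validate(self):
        if self.lr <= 0 or self.patience < 1 or self.batch_size < 1:
            raise ConfigError("invalid TrainConfig")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _Dense:
    def __init__(self, rng, d_in, d_out, name):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = rng.normal(0, scale, (d_in, d_out)).astype(F32)
        self.b = np.zeros(d_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = name

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x = self._x
        self.dW += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.db += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _LSTM:
    """Single-direction LSTM over padded batches (pads at the sequence end)."""

    def __init__(self, rng, d_in, units, name):
        scale = np.sqrt(1.0 / (d_in + units))
        self.W = rng.normal(0, scale, (d_in, 4 * units)).astype(F32)
        self.U = rng.normal(0, scale, (units, 4 * units)).astype(F32)
        self.b = np.zeros(4 * units, dtype=F32)
        self.b[units:2 * units] = 1.0  # forget-gate bias
        self.units = units
        self.name = name
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    def forward(self, X, mask, h0=None, c0=None):
        B, T, _ = X.shape
        U = self.units
        h = np.zeros((B, U), dtype=F32) if h0 is None else h0
        c = np.zeros((B, U), dtype=F32) if c0 is None else c0
        Zx = X.reshape(B * T, -1) @ self.W
        Zx = Zx.reshape(B, T, 4 * U)
        H = np.empty((B, T, U), dtype=F32)
        cache = []
        for t in range(T):
            z = Zx[:, t] + h @ self.U + self.b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t:t + 1].astype(F32)
            h_next = m * h_new + (1 - m) * h
            c_next = m * c_new + (1 - m) * c
            cache.append((h, c, i, f, g, o, tc, m))
            h, c = h_next, c_next
            H[:, t] = h
        self._cache = (X, mask, cache)
        return H, h, c

    def backward(self, dH, dh_last=None, dc_last=None):
        X, mask, cache = self._cache
        B, T, _ = X.shape
        U = self.units
        dh = np.zeros((B, U), dtype=F32) if dh_last is None else dh_last.copy()
        dc = np.zeros((B, U), dtype=F32) if dc_last is None else dc_last.copy()
        dZx = np.empty((B, T, 4 * U), dtype=F32)
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tc, m = cache[t]
            dh_t = dh + (dH[:, t] if dH is not None else 0.0)
            dh_new = m * dh_t
            dh_pass = (1 - m) * dh_t
            dc_new = m * dc + dh_new * o * (1 - tc * tc)
            dc_pass = (1 - m) * dc
            do = dh_new * tc
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dZx[:, t] = dz
            self.dU += h_prev.T @ dz
            dh = dz @ self.U.T + dh_pass
            dc = dc_new * f + dc_pass
        flatX = X.reshape(B * T, -1)
        flatZ = dZx.reshape(B * T, -1)
        self.dW += flatX.T @ flatZ
        self.db += flatZ.sum(axis=0)
        dX = (flatZ @ self.W.T).reshape(X.shape)
        return dX, dh, dc

    def step(self, x, h, c):
        """One inference step (no cache)."""
        U = self.units
        z = x @ self.W + h @ self.U + self.b
        i = _sigmoid(z[:, :U])
        f = _sigmoid(z[:, U:2 * U])
        g = np.tanh(z[:, 2 * U:3 * U])
        o = _sigmoid(z[:, 3 * U:])
        c = f * c + i * g
        h = o * np.tanh(c)
        return h, c

    def params(self):
        return [("W", self.W, self.dW), ("U", self.U, self.dU), ("b", self.b, self.db)]


class Seq2SeqAutoencoder:
    """Autoencoder mapping SMILES/CGR strings to latent vectors and back."""

    def __init__(self, cfg: AEConfig, vocab: Vocabulary, seed: int = 0):
        cfg.validate()
        if len(vocab) == 0:
            raise ConfigError("empty vocabulary")
        self.cfg = cfg
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        V = len(vocab)
        E, Z, D = cfg.enc_units, cfg.latent_dim, cfg.dec_units
        self.enc = []
        d_in = V
        for layer in range(cfg.enc_layers):
            fwd = _LSTM(rng, d_in, E, f"enc{layer}_fwd")
            bwd = _LSTM(rng, d_in, E, f"enc{layer}_bwd")
            self.enc.append((fwd, bwd))
            d_in = 2 * E
        self.bottleneck = _Dense(rng, 2 * E * cfg.enc_layers, Z, "bottleneck")
        self.dec_init = _Dense(rng, Z, 2 * D * cfg.dec_layers, "dec_init")
        self.dec = []
        d_in = V + Z
        for layer in range(cfg.dec_layers):
            self.dec.append(_LSTM(rng, d_in, D, f"dec{layer}"))
            d_in = D
        self.out = _Dense(rng, D, V, "out")
        self._adam = None

    # -- bookkeeping ------------------------------------------------------

    def _modules(self):
        mods = []
        for fwd, bwd in self.enc:
            mods += [fwd, bwd]
        mods += [self.bottleneck, self.dec_init] + self.dec + [self.out]
        return mods

    def parameters(self):
        for mod in self._modules():
            for name, p, g in mod.params():
                yield f"{mod.name}.{name}", p, g

    def num_params(self) -> int:
        return sum(p.size for _n, p, _g in self.parameters())

    def layer_report(self):
        """(name, shape, parameter count) for every weight tensor."""
        return [(n, p.shape, p.size) for n, p, _g in self.parameters()]

    def zero_grad(self):
        for _n, _p, g in self.parameters():
            g[...] = 0.0

    # -- data preparation -------------------------------------------------

    def _ids(self, strings):
        T = self.cfg.max_len
        pad = self.vocab.index[PAD]
        eos = self.vocab.index[EOS]
        ids = np.full((len(strings), T), pad, dtype=np.int64)
        for n, s in enumerate(strings):
            toks = self.vocab.encode(tokenize(s))
            if len(toks) + 1 > T:
                raise VocabularyError(
                    f"string of {len(toks)} tokens exceeds max_len={T}"
                )
            ids[n, : len(toks)] = toks
            ids[n, len(toks)] = eos
        return ids

    def _one_hot(self, ids):
        V = len(self.vocab)
        out = np.zeros((*ids.shape, V), dtype=F32)
        np.put_along_axis(out, ids[..., None], 1.0, axis=-1)
        return out

    # -- forward / backward ----------------------------------------------

    def _encode_ids(self, ids, with_cache=False):
        pad = self.vocab.index[PAD]
        mask = ids != pad
        X = self._one_hot(ids)
        finals = []
        inp = X
        for fwd, bwd in self.enc:
            Hf, hf, _ = fwd.forward(inp, mask)
            rev = inp[:, ::-1]
            Hb, hb, _ = bwd.forward(np.ascontiguousarray(rev), mask[:, ::-1])
            finals += [hf, hb]
            inp = np.concatenate([Hf, Hb[:, ::-1]], axis=2)
        concat = np.concatenate(finals, axis=1)
        z = np.tanh(self.bottleneck.forward(concat))
        if with_cache:
            self._enc_cache = (mask, z)
        return z, mask

    def _decoder_states(self, z):
        D = self.cfg.dec_units
        init = np.tanh(self.dec_init.forward(z))
        self._init_act = init
        states = []
        for layer in range(self.cfg.dec_layers):
            h0 = init[:, 2 * layer * D:(2 * layer + 1) * D]
            c0 = init[:, (2 * layer + 1) * D:(2 * layer + 2) * D]
            states.append((np.ascontiguousarray(h0), np.ascontiguousarray(c0)))
        return states

    def _forward_batch(self, ids):
        """Teacher-forced forward pass; returns (loss, dlogits hook data)."""
        B, T = ids.shape
        sos = self.vocab.index[SOS]
        pad = self.vocab.index[PAD]
        z, _mask = self._encode_ids(ids, with_cache=True)
        dec_in_ids = np.concatenate(
            [np.full((B, 1), sos, dtype=np.int64), ids[:, :-1]], axis=1
        )
        tgt_mask = ids != pad
        Xd = self._one_hot(dec_in_ids)
        zrep = np.repeat(z[:, None, :], T, axis=1)
        inp = np.concatenate([Xd, zrep], axis=2)
        states = self._decoder_states(z)
        dec_mask = np.ones_like(tgt_mask)
        H = inp
        for lstm, (h0, c0) in zip(self.dec, states):
            H, _h, _c = lstm.forward(H, dec_mask, h0, c0)
        logits = self.out.forward(H)
        # softmax cross-entropy over non-pad targets
        logits64 = logits.astype(np.float64)
        logits64 -= logits64.max(axis=2, keepdims=True)
        expz = np.exp(logits64)
        probs = expz / expz.sum(axis=2, keepdims=True)
        n_tok = tgt_mask.sum()
        idx = (np.arange(B)[:, None], np.arange(T)[None, :], ids)
        loss = -(np.log(probs[idx] + 1e-12) * tgt_mask).sum() / n_tok
        self._fwd = (ids, tgt_mask, probs, n_tok, z)
        return loss

    def _backward_batch(self):
        ids, tgt_mask, probs, n_tok, z = self._fwd
        B, T = ids.shape
        dlogits = probs.astype(F32)
        idx = (np.arange(B)[:, None], np.arange(T)[None, :], ids)
        dlogits[idx] -= 1.0
        dlogits *= (tgt_mask[..., None] / n_tok).astype(F32)
        dH = self.out.backward(dlogits)
        dh0c0 = []
        for lstm in reversed(self.dec):
            dH, dh0, dc0 = lstm.backward(dH)
            dh0c0.append((dh0, dc0))
        dh0c0.reverse()
        D = self.cfg.dec_units
        dinit = np.concatenate(
            [np.concatenate(pair, axis=1) for pair in dh0c0], axis=1
        )
        dinit *= 1 - self._init_act ** 2
        dz = self.dec_init.backward(dinit)
        # gradient from the per-step latent concatenation
        V = len(self.vocab)
        dz = dz + dH[:, :, V:].sum(axis=1)
        self._backward_encoder(dz)

    def _backward_encoder(self, dz):
        mask, z = self._enc_cache
        dpre = dz * (1 - z * z)
        dconcat = self.bottleneck.backward(dpre)
        E = self.cfg.enc_units
        n = self.cfg.enc_layers
        pieces = [dconcat[:, k * E:(k + 1) * E] for k in range(2 * n)]
        dinp = None
        for layer in reversed(range(n)):
            fwd, bwd = self.enc[layer]
            if dinp is None:
                dHf = None
                dHb = None
            else:
                dHf = np.ascontiguousarray(dinp[:, :, :E])
                dHb = np.ascontiguousarray(dinp[:, ::-1, E:])
            dXf, _dh, _dc = fwd.backward(dHf, dh_last=pieces[2 * layer])
            dXb_rev, _dh, _dc = bwd.backward(dHb, dh_last=pieces[2 * layer + 1])
            dinp = dXf + dXb_rev[:, ::-1]
        # gradient w.r.t. the one-hot input is discarded

    # -- optimization -----------------------------------------------------

    def _global_grad_norm(self):
        total = 0.0
        for _n, _p, g in self.parameters():
            total += float((g.astype(np.float64) ** 2).sum())
        return np.sqrt(total)

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam is None:
            self._adam = {
                "t": 0,
                "m": [np.zeros_like(p) for _n, p, _g in self.parameters()],
                "v": [np.zeros_like(p) for _n, p, _g in self.parameters()],
            }
        st = self._adam
        st["t"] += 1
        t = st["t"]
        for k, (_n, p, g) in enumerate(self.parameters()):
            st["m"][k] = beta1 * st["m"][k] + (1 - beta1) * g
            st["v"][k] = beta2 * st["v"][k] + (1 - beta2) * g * g
            mhat = st["m"][k] / (1 - beta1 ** t)
            vhat = st["v"][k] / (1 - beta2 ** t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(F32)

    def evaluate_loss(self, strings, batch_size=256):
        ids = self._ids(strings)
        total, n = 0.0, 0
        for b in range(0, len(ids), batch_size):
            batch = ids[b:b + batch_size]
            loss = self._forward_batch(batch)
            ntok = (batch != self.vocab.index[PAD]).sum()
            total += loss * ntok
            n += ntok
        return total / max(n, 1)

    def train(self, corpus, tcfg: TrainConfig):
        """Teacher-forced training with Adam and plateau LR reduction.

        Returns a history list of per-epoch dicts (losses, lr, events).
        """
        tcfg.validate()
        corpus = list(corpus)
        if not corpus:
            raise DataError("empty training corpus")
        rng = np.random.default_rng(tcfg.seed)
        order = rng.permutation(len(corpus))
        n_val = int(len(corpus) * tcfg.val_fraction)
        val = [corpus[i] for i in order[:n_val]]
        train = [corpus[i] for i in order[n_val:]] or list(val)
        ids = self._ids(train)
        lr = tcfg.lr
        best_val = np.inf
        stall = 0
        history = []
        for epoch in range(tcfg.max_epochs):
            perm = rng.permutation(len(ids))
            epoch_loss, n_batches = 0.0, 0
            for b in range(0, len(ids), tcfg.batch_size):
                batch = ids[perm[b:b + tcfg.batch_size]]
                self.zero_grad()
                loss = self._forward_batch(batch)
                self._backward_batch()
                norm = self._global_grad_norm()
                if norm > tcfg.clip_norm:
                    scale = F32(tcfg.clip_norm / (norm + 1e-12))
                    for _n, _p, g in self.parameters():
                        g *= scale
                self._adam_step(lr)
                epoch_loss += loss
                n_batches += 1
            val_loss = self.evaluate_loss(val) if val else epoch_loss / n_batches
            events = []
            if val_loss < best_val - tcfg.min_delta:
                best_val = val_loss
                stall = 0
            else:
                stall += 1
                if stall >= tcfg.patience:
                    new_lr = max(lr * tcfg.lr_factor, tcfg.min_lr)
                    if new_lr < lr:
                        lr = new_lr
                        events.append(f"lr_reduced_to_{lr:.2e}")
                    stall = 0
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": float(epoch_loss / n_batches),
                    "val_loss": float(val_loss),
                    "lr": float(lr),
                    "events": events,
                }
            )
        self.history = history
        return history

    # -- inference --------------------------------------------------------

    def encode(self, strings) -> np.ndarray:
        """Latent vectors, shape (n, latent_dim)."""
        ids = self._ids(strings)
        out = []
        for b in range(0, len(ids), 512):
            z, _ = self._encode_ids(ids[b:b + 512])
            out.append(z)
        return np.concatenate(out, axis=0)

    def decode(self, vectors, greedy: bool = True, temperature: float = 1.0,
               seed: int = 0) -> list[str]:
        """Decode latent vectors to strings (greedy argmax by default)."""
        z = np.asarray(vectors, dtype=F32)
        if z.ndim == 1:
            z = z[None, :]
        B = z.shape[0]
        V = len(self.vocab)
        T = self.cfg.max_len
        sos = self.vocab.index[SOS]
        eos = self.vocab.index[EOS]
        pad = self.vocab.index[PAD]
        rng = np.random.default_rng(seed)
        states = self._decoder_states(z)
        tok = np.full(B, sos, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        out_tokens = [[] for _ in range(B)]
        for _t in range(T):
            x = np.zeros((B, V), dtype=F32)
            x[np.arange(B), tok] = 1.0
            h = np.concatenate([x, z], axis=1)
            new_states = []
            for lstm, (hs, cs) in zip(self.dec, states):
                hs, cs = lstm.step(h, hs, cs)
                new_states.append((hs, cs))
                h = hs
            states = new_states
            logits = self.out.forward(h)
            if greedy:
                tok = logits.argmax(axis=1)
            else:
                logits64 = logits.astype(np.float64) / max(temperature, 1e-6)
                logits64 -= logits64.max(axis=1, keepdims=True)
                p = np.exp(logits64)
                p /= p.sum(axis=1, keepdims=True)
                tok = np.array([rng.choice(V, p=row) for row in p])
            for n in range(B):
                if done[n]:
                    continue
                if tok[n] in (eos, pad):
                    done[n] = True
                else:
                    out_tokens[n].append(self.vocab.tokens[tok[n]])
            if done.all():
                break
        return [detokenize(toks) for toks in out_tokens]

    def reconstruction_rate(self, strings) -> tuple[float, int]:
        """Fraction of strings reproduced exactly by encode-then-decode."""
        if not strings:
            return 0.0, 0
        decoded = self.decode(self.encode(strings))
        hits = sum(d == s for d, s in zip(decoded, strings))
        return hits / len(strings), hits

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {name.replace(".", "__"): p for name, p, _g in self.parameters()}
        arrays["__cfg"] = np.array(
            [self.cfg.max_len, self.cfg.latent_dim, self.cfg.enc_layers,
             self.cfg.enc_units, self.cfg.dec_layers, self.cfg.dec_units]
        )
        arrays["__vocab"] = np.array(json.dumps(self.vocab.index))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Seq2SeqAutoencoder":
        data = np.load(path, allow_pickle=False)
        dims = data["__cfg"].astype(int)
        cfg = AEConfig(*dims)
        index = json.loads(str(data["__vocab"]))
        vocab = Vocabulary.__new__(Vocabulary)
        vocab.tokens = [t for t, _ in sorted(index.items(), key=lambda kv: kv[1])]
        vocab.index = dict(index)
        model = cls(cfg, vocab)
        for name, p, _g in model.parameters():
            p[...] = data[name.replace(".", "__")]
        return model


def build_model(cfg: AEConfig, vocab: Vocabulary, seed: int = 0) -> Seq2SeqAutoencoder:
    """Construct an autoencoder with deterministic initialization."""
    return Seq2SeqAutoencoder(cfg, vocab, seed=seed)


def lstm_param_count(d_in: int, units: int) -> int:
    """Closed-form LSTM parameter count: 4*units*(d_in + units + 1)."""
    return 4 * units * (d_in + units + 1)
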