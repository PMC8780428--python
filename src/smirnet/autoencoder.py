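"""Character-level LSTM sequence autoencoder in pure numpy.

One autoencoder is trained per entity type (miRNA sequences, compound
SMILES).  The encoder LSTM reads the one-hot string and its final hidden
and cell states are linearly projected to a fixed-length latent vector
(64-d or 128-d by convention); the decoder LSTM is initialised from that
vector and reproduces the string character by character.  Training uses
teacher forcing with a pad-masked cross-entropy loss and the Adam
optimiser; evaluation uses greedy free-running decoding, and the
reconstruction accuracy of the decoder is the diagnostic for how much
information the latent vector retains.

The implementation is deliberately compact: a single-layer LSTM each way,
full manual backpropagation through time, and deterministic seeded
initialisation, so that identical (corpus, seed) pairs give bitwise
identical latent vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .encoding import (
    END,
    PAD,
    START,
    LengthError,
    UnknownCharacterError,
    Vocabulary,
    build_vocabulary,
    encode_indices,
)
from .io import SequenceRecord


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class ReconstructionReport:
    """Greedy-decoding agreement between inputs and reconstructions.

    ``per_char_accuracy`` counts character matches at non-pad target
    positions (including the end symbol); ``exact_match_rate`` counts
    whole strings reproduced verbatim.  The two are different metrics and
    neither bounds the other.
    """

    per_char_accuracy: float
    exact_match_rate: float
    n_sequences: int


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class _LSTMParams:
    """Weights of one LSTM layer (gate order: input, forget, cell, output)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int) -> None:
        s_x = np.sqrt(6.0 / (n_in + 4 * n_hidden))
        s_h = np.sqrt(6.0 / (n_hidden + 4 * n_hidden))
        self.Wx = rng.uniform(-s_x, s_x, size=(n_in, 4 * n_hidden))
        self.Wh = rng.uniform(-s_h, s_h, size=(n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        # forget-gate bias starts at 1 to keep early memory open
        self.b[n_hidden : 2 * n_hidden] = 1.0


def _lstm_step(p: _LSTMParams, x, h, c, H):
    z = x @ p.Wx + h @ p.Wh + p.b
    i = _sigmoid(z[:, :H])
    f = _sigmoid(z[:, H : 2 * H])
    g = np.tanh(z[:, 2 * H : 3 * H])
    o = _sigmoid(z[:, 3 * H :])
    c_new = f * c + i * g
    tc = np.tanh(c_new)
    h_new = o * tc
    return h_new, c_new, (x, h, c, i, f, g, o, c_new, tc)


def _lstm_step_back(p: _LSTMParams, cache, dh, dc, grads, H):
    x, h_prev, c_prev, i, f, g, o, c_new, tc = cache
    do = dh * tc
    dc_total = dc + dh * o * (1.0 - tc * tc)
    di = dc_total * g
    df = dc_total * c_prev
    dg = dc_total * i
    dc_prev = dc_total * f
    dz = np.concatenate(
        [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
        axis=1,
    )
    grads["Wx"] += x.T @ dz
    grads["Wh"] += h_prev.T @ dz
    grads["b"] += dz.sum(axis=0)
    dx = dz @ p.Wx.T
    dh_prev = dz @ p.Wh.T
    return dx, dh_prev, dc_prev


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SequenceAutoencoder(BaseEstimator, TransformerMixin):
    """Seq2seq autoencoder exposing the encoder as a string->vector transform.

    Parameters
    ----------
    latent_dim : int
        Dimension of the latent representation; 64 and 128 are the two
        standard encoding versions.
    hidden_units : int
        LSTM hidden-state size of both encoder and decoder.
    epochs, batch_size, learning_rate : training-loop controls.
    max_len : int or None
        Maximum string length; required unless ``vocab`` is given.
    fixed_alphabet : sequence of characters or None
        Use this domain alphabet (e.g. the six nucleotide characters)
        instead of the characters observed in the training corpus.
    vocab : Vocabulary or None
        Pre-built vocabulary; overrides max_len/fixed_alphabet.
    teacher_forcing : bool
        Feed the true previous character to the decoder during training
        (standard); when off, the decoder free-runs on its own argmax.
    truncate_overlength : bool
        At transform time, truncate over-length strings to max_len with a
        warning instead of raising; training always requires conforming
        lengths.
    random_state : int
        Seed for initialisation and batch shuffling.

    Attributes
    ----------
    vocab_ : Vocabulary used by the fitted model.
    params_ : dict of weight arrays.
    loss_curve_ : per-epoch mean training loss.
    training_report_ : ReconstructionReport on the training corpus,
        computed with greedy (non-teacher-forced) decoding.
    """

    def __init__(
        self,
        latent_dim: int = 64,
        hidden_units: int = 128,
        epochs: int = 200,
        batch_size: int = 128,
        learning_rate: float = 5e-3,
        max_len: int | None = None,
        fixed_alphabet: Sequence[str] | None = None,
        vocab: Vocabulary | None = None,
        teacher_forcing: bool = True,
        truncate_overlength: bool = True,
        random_state: int = 0,
    ) -> None:
        self.latent_dim = latent_dim
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_len = max_len
        self.fixed_alphabet = fixed_alphabet
        self.vocab = vocab
        self.teacher_forcing = teacher_forcing
        self.truncate_overlength = truncate_overlength
        self.random_state = random_state

    # ------------------------------------------------------------------ utils

    @staticmethod
    def _texts(X: Sequence[SequenceRecord | str]) -> list[str]:
        return [x.text if isinstance(x, SequenceRecord) else x for x in X]

    def _prepare(self, texts: list[str], truncate: bool) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays for the encoder input and the decoder target."""
        V = self.vocab_
        enc = np.stack([encode_indices(t, V, truncate=truncate) for t in texts])
        lengths = np.array([min(len(t), V.max_len) for t in texts])
        return enc, lengths

    def _one_hot(self, idx: np.ndarray) -> np.ndarray:
        V = len(self.vocab_)
        out = np.zeros(idx.shape + (V,), dtype=np.float64)
        np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
        return out

    # ---------------------------------------------------------------- forward

    def _encode_states(self, enc_idx: np.ndarray, lengths: np.ndarray, cache=None):
        """Run the encoder; state updates are masked past each string's end."""
        H = self.hidden_units
        B, T = enc_idx.shape
        X = self._one_hot(enc_idx)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        enc_p = self._p_enc
        for t in range(T):
            m = (lengths > t).astype(float)[:, None]
            h_new, c_new, cch = _lstm_step(enc_p, X[:, t], h, c, H)
            if cache is not None:
                cache.append((cch, m, h, c))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        return h, c

    def _latent_from_states(self, h: np.ndarray, c: np.ndarray) -> np.ndarray:
        hc = np.concatenate([h, c], axis=1)
        return hc @ self.params_["Wp"] + self.params_["bp"]

    def _decoder_init(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = self.hidden_units
        s = np.tanh(z @ self.params_["Wd"] + self.params_["bd"])
        return s[:, :H], s[:, H:]

    # --------------------------------------------------------------- training

    def fit(self, X: Sequence[SequenceRecord | str], y=None) -> "SequenceAutoencoder":
        texts = self._texts(X)
        if len(texts) == 0:
            raise ValueError("cannot train on an empty corpus")
        if len(texts) < 2:
            raise ValueError("training requires at least 2 sequences")

        if self.vocab is not None:
            self.vocab_ = self.vocab
        else:
            if self.max_len is None:
                raise ValueError("max_len is required when no vocabulary is given")
            corpus = [
                x if isinstance(x, SequenceRecord) else SequenceRecord(f"s{i}", x, "smiles")
                for i, x in enumerate(X)
            ]
            self.vocab_ = build_vocabulary(corpus, self.max_len, self.fixed_alphabet)

        over = [t for t in texts if len(t) > self.vocab_.max_len]
        if over:
            raise LengthError(
                f"{len(over)} training sequences exceed max_len {self.vocab_.max_len}"
            )

        rng = np.random.default_rng(self.random_state)
        H, L, V = self.hidden_units, self.latent_dim, len(self.vocab_)
        enc_p = _LSTMParams(rng, V, H)
        # decoder input = previous-character one-hot concatenated with the
        # latent vector, so the encoding conditions every decoding step
        dec_p = _LSTMParams(rng, V + L, H)
        s_p = np.sqrt(6.0 / (2 * H + L))
        s_d = np.sqrt(6.0 / (L + 2 * H))
        s_o = np.sqrt(6.0 / (H + V))
        self.params_ = {
            "enc_Wx": enc_p.Wx, "enc_Wh": enc_p.Wh, "enc_b": enc_p.b,
            "dec_Wx": dec_p.Wx, "dec_Wh": dec_p.Wh, "dec_b": dec_p.b,
            "Wp": rng.uniform(-s_p, s_p, size=(2 * H, L)), "bp": np.zeros(L),
            "Wd": rng.uniform(-s_d, s_d, size=(L, 2 * H)), "bd": np.zeros(2 * H),
            "Wo": rng.uniform(-s_o, s_o, size=(H, V)), "bo": np.zeros(V),
        }
        self._p_enc, self._p_dec = enc_p, dec_p

        enc_idx, lengths = self._prepare(texts, truncate=False)
        opt = _Adam(self.params_, self.learning_rate)
        n = len(texts)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                loss, m = self._train_batch(enc_idx[sel], lengths[sel], opt)
                total += loss * m
                count += m
            mean_loss = total / max(count, 1)
            if not np.isfinite(mean_loss):
                raise DivergenceError(f"training loss diverged at epoch {epoch}")
            self.loss_curve_.append(mean_loss)

        self.training_report_ = self._report(texts)
        return self

    def _train_batch(self, enc_idx, lengths, opt) -> tuple[float, int]:
        H = self.hidden_units
        P = self.params_
        B, T = enc_idx.shape
        Td = T + 1  # decoder predicts every char plus the end symbol
        V = len(self.vocab_)
        vb = self.vocab_
        pad_i, start_i, end_i = vb.index[PAD], vb.index[START], vb.index[END]

        # --- forward: encoder -> latent -> decoder init
        enc_cache: list = []
        h_T, c_T = self._encode_states(enc_idx, lengths, cache=enc_cache)
        hc = np.concatenate([h_T, c_T], axis=1)
        z = hc @ P["Wp"] + P["bp"]
        pre = z @ P["Wd"] + P["bd"]
        s0 = np.tanh(pre)
        h, c = s0[:, :H], s0[:, H:]

        # decoder teacher inputs [START, c1..cn, pad...] and targets
        # [c1..cn, END, pad...]
        dec_in = np.full((B, Td), pad_i, dtype=np.int64)
        dec_in[:, 0] = start_i
        dec_in[:, 1:] = enc_idx
        target = np.full((B, Td), pad_i, dtype=np.int64)
        target[:, :T] = enc_idx
        target[np.arange(B), lengths] = end_i
        mask = np.zeros((B, Td))
        mask[np.arange(Td)[None, :] <= lengths[:, None]] = 1.0

        dec_cache = []
        probs = np.zeros((B, Td, V))
        x_t = np.concatenate([self._one_hot(dec_in[:, 0]), z], axis=1)
        for t in range(Td):
            h_new, c_new, cch = _lstm_step(self._p_dec, x_t, h, c, H)
            dec_cache.append(cch)
            h, c = h_new, c_new
            logits = h @ P["Wo"] + P["bo"]
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            probs[:, t] = e / e.sum(axis=1, keepdims=True)
            if t + 1 < Td:
                if self.teacher_forcing:
                    nxt = self._one_hot(dec_in[:, t + 1])
                else:
                    nxt = self._one_hot(np.argmax(probs[:, t], axis=1))
                x_t = np.concatenate([nxt, z], axis=1)

        n_pos = mask.sum()
        eps = 1e-12
        ll = -np.log(probs[np.arange(B)[:, None], np.arange(Td)[None, :], target] + eps)
        loss = float((ll * mask).sum() / n_pos)

        # --- backward
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        g_dec = {"Wx": grads["dec_Wx"], "Wh": grads["dec_Wh"], "b": grads["dec_b"]}
        g_enc = {"Wx": grads["enc_Wx"], "Wh": grads["enc_Wh"], "b": grads["enc_b"]}

        dprobs = probs.copy()
        dprobs[np.arange(B)[:, None], np.arange(Td)[None, :], target] -= 1.0
        dprobs *= mask[:, :, None] / n_pos

        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dz_steps = np.zeros_like(z)
        for t in range(Td - 1, -1, -1):
            dlogits = dprobs[:, t]
            # h after step t is o * tanh(c_new), both held in the cache
            _, _, _, _, _, _, o_t, _, tc_t = dec_cache[t]
            h_t = o_t * tc_t
            grads["Wo"] += h_t.T @ dlogits
            grads["bo"] += dlogits.sum(axis=0)
            dh = dh_next + dlogits @ P["Wo"].T
            dx, dh_prev, dc_prev = _lstm_step_back(
                self._p_dec, dec_cache[t], dh, dc_next, g_dec, H
            )
            dh_next, dc_next = dh_prev, dc_prev
            # the character part of the input is a one-hot constant; the
            # latent part receives gradient from every step
            dz_steps += dx[:, V:]

        ds0 = np.concatenate([dh_next, dc_next], axis=1)
        dpre = ds0 * (1.0 - s0 * s0)
        grads["Wd"] += z.T @ dpre
        grads["bd"] += dpre.sum(axis=0)
        dz = dpre @ P["Wd"].T + dz_steps
        grads["Wp"] += hc.T @ dz
        grads["bp"] += dz.sum(axis=0)
        dhc = dz @ P["Wp"].T
        dh_e, dc_e = dhc[:, :H], dhc[:, H:]
        for t in range(T - 1, -1, -1):
            cch, m, h_prev, c_prev = enc_cache[t]
            dh_upd = m * dh_e
            dc_upd = m * dc_e
            dh_skip = (1 - m) * dh_e
            dc_skip = (1 - m) * dc_e
            _, dh_prev, dc_prev = _lstm_step_back(
                self._p_enc, cch, dh_upd, dc_upd, g_enc, H
            )
            dh_e = dh_prev + dh_skip
            dc_e = dc_prev + dc_skip

        opt.step(P, grads)
        return loss, int(B)

    # -------------------------------------------------------------- inference

    def transform(self, X: Sequence[SequenceRecord | str]) -> np.ndarray:
        """Encode strings into (n, latent_dim) latent vectors."""
        self._check_fitted()
        texts = self._texts(X)
        if not texts:
            return np.zeros((0, self.latent_dim))
        enc_idx, lengths = self._prepare(texts, truncate=self.truncate_overlength)
        h, c = self._encode_states(enc_idx, lengths)
        return self._latent_from_states(h, c)

    def reconstruct(self, X: Sequence[SequenceRecord | str]) -> list[str]:
        """Greedy free-running decode of each string's latent vector."""
        self._check_fitted()
        texts = self._texts(X)
        enc_idx, lengths = self._prepare(texts, truncate=self.truncate_overlength)
        h_T, c_T = self._encode_states(enc_idx, lengths)
        z = self._latent_from_states(h_T, c_T)
        return self._greedy_decode(z)

    def _greedy_decode(self, z: np.ndarray) -> list[str]:
        H = self.hidden_units
        P = self.params_
        vb = self.vocab_
        B = z.shape[0]
        h, c = self._decoder_init(z)
        token = np.full(B, vb.index[START], dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        out: list[list[str]] = [[] for _ in range(B)]
        for _ in range(vb.max_len + 1):
            x = np.concatenate([self._one_hot(token), z], axis=1)
            h, c, _ = _lstm_step(self._p_dec, x, h, c, H)
            logits = h @ P["Wo"] + P["bo"]
            token = np.argmax(logits, axis=1)
            for b in range(B):
                if done[b]:
                    continue
                ch = vb.chars[int(token[b])]
                if ch in (END, PAD) or len(out[b]) >= vb.max_len:
                    done[b] = True
                else:
                    out[b].append(ch)
            if done.all():
                break
        return ["".join(chs) for chs in out]

    def _report(self, texts: list[str]) -> ReconstructionReport:
        recon = self.reconstruct(texts)
        exact = sum(r == t for r, t in zip(recon, texts))
        match, total = 0, 0
        for r, t in zip(recon, texts):
            tgt = t + END
            rec = r + END
            for i, ch in enumerate(tgt):
                total += 1
                if i < len(rec) and rec[i] == ch:
                    match += 1
        return ReconstructionReport(
            per_char_accuracy=match / max(total, 1),
            exact_match_rate=exact / max(len(texts), 1),
            n_sequences=len(texts),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("autoencoder is not fitted; call fit first")


def train_autoencoder(
    corpus: Sequence[SequenceRecord],
    vocab: Vocabulary,
    **config,
) -> SequenceAutoencoder:
    """Thin functional wrapper: train an autoencoder on a corpus."""
    model = SequenceAutoencoder(vocab=vocab, **config)
    return model.fit(corpus)


def encode(model: SequenceAutoencoder, record: SequenceRecord | str) -> np.ndarray:
    """Latent vector of a single record (function of its text only)."""
    return model.transform([record])[0]
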