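"""A small GRU sequence-to-sequence autoencoder for SMILES fingerprints.

Encoder GRU stack -> fixed-length bottleneck (the fingerprint) -> decoder
GRU stack reconstructing the token sequence with teacher forcing.  Written
directly in numpy with manual backprop-through-time and Adam, trained one
sequence at a time (corpora here are small).  Deterministic given the seed.

Hyperparameter fields mirror the usual search space for this architecture:
fingerprint length in {128, 256, 512, 1024}, learning rate in
{0.1, 0.01, 0.001}, 2-4 layers, dropout in {0, 0.1, 0.2, 0.3}.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GruSeq2Seq"]

_SOS, _EOS = "<s>", "</s>"


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _GRUCell:
    """Single GRU layer; parameters stored in a flat dict for Adam."""

    def __init__(self, in_dim: int, hid: int, rng: np.random.Generator, prefix: str):
        s = 1.0 / np.sqrt(hid)
        self.prefix = prefix
        self.in_dim, self.hid = in_dim, hid
        self.p = {}
        for gate in ("z", "r", "h"):
            self.p[f"W{gate}"] = rng.uniform(-s, s, (hid, in_dim))
            self.p[f"U{gate}"] = rng.uniform(-s, s, (hid, hid))
            self.p[f"b{gate}"] = np.zeros(hid)

    def forward(self, x, h_prev):
        p = self.p
        z = _sigmoid(p["Wz"] @ x + p["Uz"] @ h_prev + p["bz"])
        r = _sigmoid(p["Wr"] @ x + p["Ur"] @ h_prev + p["br"])
        hbar = np.tanh(p["Wh"] @ x + p["Uh"] @ (r * h_prev) + p["bh"])
        h = (1 - z) * h_prev + z * hbar
        cache = (x, h_prev, z, r, hbar)
        return h, cache

    def backward(self, dh, cache, grads):
        x, h_prev, z, r, hbar = cache
        p = self.p
        dz = dh * (hbar - h_prev) * z * (1 - z)
        dhbar_pre = dh * z * (1 - hbar**2)
        dh_prev = dh * (1 - z)
        grads[f"{self.prefix}Wh"] += np.outer(dhbar_pre, x)
        grads[f"{self.prefix}Uh"] += np.outer(dhbar_pre, r * h_prev)
        grads[f"{self.prefix}bh"] += dhbar_pre
        drh = p["Uh"].T @ dhbar_pre
        dr = drh * h_prev
        dh_prev += drh * r
        dr_pre = dr * r * (1 - r)
        grads[f"{self.prefix}Wz"] += np.outer(dz, x)
        grads[f"{self.prefix}Uz"] += np.outer(dz, h_prev)
        grads[f"{self.prefix}bz"] += dz
        grads[f"{self.prefix}Wr"] += np.outer(dr_pre, x)
        grads[f"{self.prefix}Ur"] += np.outer(dr_pre, h_prev)
        grads[f"{self.prefix}br"] += dr_pre
        dh_prev += p["Uz"].T @ dz + p["Ur"].T @ dr_pre
        dx = p["Wz"].T @ dz + p["Wr"].T @ dr_pre + p["Wh"].T @ dhbar_pre
        return dx, dh_prev


class GruSeq2Seq:
    """GRU encoder-decoder whose bottleneck is a drug fingerprint.

    Parameters
    ----------
    fv_length : bottleneck (= hidden) dimension; this is the fingerprint size.
    n_layers : GRU layers in both encoder and decoder.
    learning_rate, dropout : Adam step size and inter-layer dropout rate.
    epochs : full passes over the training corpus.
    seed : controls init, shuffling, and dropout masks.
    """

    def __init__(
        self,
        fv_length: int = 128,
        n_layers: int = 2,
        learning_rate: float = 0.01,
        dropout: float = 0.1,
        embed_dim: int = 32,
        epochs: int = 100,
        seed: int = 0,
    ):
        self.fv_length = fv_length
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.embed_dim = embed_dim
        self.epochs = epochs
        self.seed = seed
        self._fitted = False

    # -- construction -----------------------------------------------------
    def _build(self, tokens: set[str]):
        rng = np.random.default_rng(self.seed)
        self.vocab_ = {t: i for i, t in enumerate([_SOS, _EOS] + sorted(tokens))}
        self.inv_vocab_ = {i: t for t, i in self.vocab_.items()}
        V, E, H = len(self.vocab_), self.embed_dim, self.fv_length
        self.params_ = {"emb": rng.uniform(-0.1, 0.1, (V, E))}
        self.enc_ = []
        self.dec_ = []
        for layer in range(self.n_layers):
            in_dim = E if layer == 0 else H
            for stack, name in ((self.enc_, "enc"), (self.dec_, "dec")):
                cell = _GRUCell(in_dim, H, rng, f"{name}{layer}_")
                for k, v in cell.p.items():
                    self.params_[f"{cell.prefix}{k}"] = v
                    cell.p[k] = self.params_[f"{cell.prefix}{k}"]
                stack.append(cell)
        s = 1.0 / np.sqrt(H)
        self.params_["Wo"] = rng.uniform(-s, s, (V, H))
        self.params_["bo"] = np.zeros(V)
        self._rng = rng
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        self._adam_t = 0

    def _encode_ids(self, ids, train=False, drop_masks=None):
        """Run the encoder stack; returns final hiddens per layer + caches."""
        H = self.fv_length
        hs = [np.zeros(H) for _ in range(self.n_layers)]
        caches = [[] for _ in range(self.n_layers)]
        inputs_per_layer = [[] for _ in range(self.n_layers)]
        for t, tok in enumerate(ids):
            x = self.params_["emb"][tok]
            for layer, cell in enumerate(self.enc_):
                inputs_per_layer[layer].append(x)
                hs[layer], cache = cell.forward(x, hs[layer])
                caches[layer].append(cache)
                x = hs[layer]
                if train and drop_masks is not None and layer < self.n_layers - 1:
                    x = x * drop_masks[layer]
        return hs, caches

    # -- training ---------------------------------------------------------
    def _step(self, ids):
        """One forward/backward pass on a single token-id sequence."""
        params = self.params_
        keep = 1.0 - self.dropout
        drop_e = [
            (self._rng.random(self.fv_length) < keep) / keep if keep < 1.0 else None
            for _ in range(max(0, self.n_layers - 1))
        ]
        drop_d = [
            (self._rng.random(self.fv_length) < keep) / keep if keep < 1.0 else None
            for _ in range(max(0, self.n_layers - 1))
        ]
        if self.dropout == 0.0:
            drop_e = drop_d = None
        enc_h, enc_caches = self._encode_ids(ids, train=True, drop_masks=drop_e)

        sos, eos = self.vocab_[_SOS], self.vocab_[_EOS]
        dec_in = [sos] + list(ids)
        dec_target = list(ids) + [eos]
        hs = [h.copy() for h in enc_h]
        dec_caches = [[] for _ in range(self.n_layers)]
        logits_list, probs_list = [], []
        loss = 0.0
        for t, tok in enumerate(dec_in):
            x = params["emb"][tok]
            for layer, cell in enumerate(self.dec_):
                hs[layer], cache = cell.forward(x, hs[layer])
                dec_caches[layer].append(cache)
                x = hs[layer]
                if drop_d is not None and layer < self.n_layers - 1:
                    x = x * drop_d[layer]
            logits = params["Wo"] @ x + params["bo"]
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            probs_list.append(p)
            loss -= np.log(max(p[dec_target[t]], 1e-12))

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        T = len(dec_in)
        dh_next = [np.zeros(self.fv_length) for _ in range(self.n_layers)]
        for t in reversed(range(T)):
            p = probs_list[t].copy()
            p[dec_target[t]] -= 1.0
            # top-layer hidden after dropout was fed to the output layer only
            # when it is the last layer (no dropout on the top layer output)
            h_top = dec_caches[-1][t]
            h_top_val = (1 - h_top[2]) * h_top[1] + h_top[2] * h_top[4]
            grads["Wo"] += np.outer(p, h_top_val)
            grads["bo"] += p
            dh = params["Wo"].T @ p
            dh_layer = dh + dh_next[-1]
            for layer in reversed(range(self.n_layers)):
                cell = self.dec_[layer]
                dx, dh_prev = cell.backward(dh_layer, dec_caches[layer][t], grads)
                dh_next[layer] = dh_prev
                if layer > 0:
                    if drop_d is not None and layer - 1 < self.n_layers - 1:
                        dx = dx * drop_d[layer - 1]
                    dh_layer = dx + dh_next[layer - 1]
                else:
                    grads["emb"][dec_in[t]] += dx
        # gradient w.r.t. encoder final hiddens = dh_next at decoder t=0
        denc_h = dh_next
        dh_next = [denc_h[l] for l in range(self.n_layers)]
        for t in reversed(range(len(ids))):
            dh_layer = dh_next[-1]
            for layer in reversed(range(self.n_layers)):
                cell = self.enc_[layer]
                dx, dh_prev = cell.backward(dh_layer, enc_caches[layer][t], grads)
                dh_next[layer] = dh_prev
                if layer > 0:
                    if drop_e is not None:
                        dx = dx * drop_e[layer - 1]
                    dh_layer = dx + dh_next[layer - 1]
                else:
                    grads["emb"][ids[t]] += dx

        # clip and Adam update
        for g in grads.values():
            np.clip(g, -5.0, 5.0, out=g)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._adam_t)
            vhat = v / (1 - b2**self._adam_t)
            self.params_[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss / T

    def fit(self, token_seqs: list[list[str]]):
        """Train the autoencoder on tokenized SMILES sequences."""
        if not token_seqs:
            raise ValueError("empty training corpus")
        self._build({t for s in token_seqs for t in s})
        encoded = [np.array([self.vocab_[t] for t in s], dtype=np.int64) for s in token_seqs]
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = self._rng.permutation(len(encoded))
            epoch_loss = 0.0
            for i in order:
                epoch_loss += self._step(encoded[i])
            self.loss_history_.append(epoch_loss / len(encoded))
        self._fitted = True
        return self

    # -- inference --------------------------------------------------------
    def encode(self, tokens: list[str]) -> np.ndarray:
        """Fingerprint = final top-layer encoder hidden state."""
        if not self._fitted:
            raise RuntimeError("model not fitted")
        ids = [self.vocab_[t] for t in tokens if t in self.vocab_]
        if not ids:
            return np.zeros(self.fv_length)
        hs, _ = self._encode_ids(np.array(ids, dtype=np.int64))
        return hs[-1].copy()

    def reconstruct(self, tokens: list[str]) -> list[str]:
        """Greedy teacher-forced reconstruction (for accuracy reporting)."""
        ids = np.array([self.vocab_[t] for t in tokens if t in self.vocab_], dtype=np.int64)
        hs, _ = self._encode_ids(ids)
        hs = [h.copy() for h in hs]
        out = []
        dec_in = [self.vocab_[_SOS]] + list(ids)
        for tok in dec_in:
            x = self.params_["emb"][tok]
            for layer, cell in enumerate(self.dec_):
                hs[layer], _ = cell.forward(x, hs[layer])
                x = hs[layer]
            logits = self.params_["Wo"] @ x + self.params_["bo"]
            out.append(self.inv_vocab_[int(np.argmax(logits))])
        return out[:-1]  # drop the predicted end-of-sequence position

    def reconstruction_accuracy(self, token_seqs: list[list[str]]) -> float:
        """Fraction of input tokens reproduced under teacher forcing."""
        correct = total = 0
        for s in token_seqs:
            pred = self.reconstruct(s)
            correct += sum(p == t for p, t in zip(pred, s))
            total += len(s)
        return correct / max(total, 1)
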