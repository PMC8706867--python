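"""NumPy implementation of a stacked-GRU autoregressive sequence model.

One embedding layer, a stack of GRU layers, and a linear softmax head over
the vocabulary.  Training is plain backpropagation through time with Adam
and a PAD-masked mean negative-log-likelihood loss; everything is float32,
kept in time-major (T, B, ...) layout so per-timestep slices are
contiguous, and the heavy lifting is BLAS matmuls.

Gate convention (the common framework layout), gate blocks ordered
``[reset, update, candidate]`` inside the fused weight matrices::

    r_t = sigmoid(x_t Wx_r + h_{t-1} Wh_r + bx_r + bh_r)
    z_t = sigmoid(x_t Wx_z + h_{t-1} Wh_z + bx_z + bh_z)
    n_t = tanh(x_t Wx_n + bx_n + r_t * (h_{t-1} Wh_n + bh_n))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}
"""

from __future__ import annotations

import numpy as np

__all__ = ["GRUStack"]

_F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # exp overflow for very negative inputs saturates to inf and the ratio
    # correctly becomes 0, so the one-branch form is safe in float32
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


class GRUStack:
    """Embedding + stacked GRU + softmax head with Adam training state."""

    def __init__(self, vocab_size: int, embedding_dim: int, hidden_units: int,
                 n_layers: int, rng: np.random.Generator):
        self.vocab_size = vocab_size
        self.embedding_dim = embedding_dim
        self.hidden_units = hidden_units
        self.n_layers = n_layers
        V, E, H = vocab_size, embedding_dim, hidden_units
        k = 1.0 / np.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        self.params["emb"] = rng.uniform(-0.1, 0.1, (V, E)).astype(_F32)
        for layer in range(n_layers):
            d_in = E if layer == 0 else H
            self.params[f"Wx{layer}"] = rng.uniform(-k, k, (d_in, 3 * H)).astype(_F32)
            self.params[f"Wh{layer}"] = rng.uniform(-k, k, (H, 3 * H)).astype(_F32)
            self.params[f"bx{layer}"] = np.zeros(3 * H, dtype=_F32)
            self.params[f"bh{layer}"] = np.zeros(3 * H, dtype=_F32)
        self.params["Wo"] = rng.uniform(-k, k, (H, V)).astype(_F32)
        self.params["bo"] = np.zeros(V, dtype=_F32)
        # Adam state
        self._m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------
    # forward (time-major internally)
    # ------------------------------------------------------------------
    def _forward_rnn(self, inputs: np.ndarray, want_cache: bool = False):
        """Run the stack over a (B, T) int batch.

        Returns the top hidden states in time-major (T, B, H) layout and,
        optionally, the cache needed for BPTT.
        """
        B, T = inputs.shape
        H = self.hidden_units
        dtype = self.params["emb"].dtype
        # (T, B, E): time-major so x[t] is contiguous
        x = np.ascontiguousarray(self.params["emb"][inputs].transpose(1, 0, 2))
        cache = {"inputs": inputs} if want_cache else None
        for layer in range(self.n_layers):
            Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
            bx, bh = self.params[f"bx{layer}"], self.params[f"bh{layer}"]
            gx = (x.reshape(T * B, -1) @ Wx + bx).reshape(T, B, 3 * H)
            Hs = np.empty((T, B, H), dtype=dtype)
            if want_cache:
                R = np.empty_like(Hs); Z = np.empty_like(Hs)
                N = np.empty_like(Hs); HN = np.empty_like(Hs)
            h = np.zeros((B, H), dtype=dtype)
            for t in range(T):
                gh = h @ Wh + bh
                gxt = gx[t]
                r = _sigmoid(gxt[:, :H] + gh[:, :H])
                z = _sigmoid(gxt[:, H:2 * H] + gh[:, H:2 * H])
                hn_lin = gh[:, 2 * H:]
                n = np.tanh(gxt[:, 2 * H:] + r * hn_lin)
                h = (1.0 - z) * n + z * h
                Hs[t] = h
                if want_cache:
                    R[t] = r; Z[t] = z; N[t] = n; HN[t] = hn_lin
            if want_cache:
                cache[f"x{layer}"] = x
                cache[f"H{layer}"] = Hs
                cache[f"R{layer}"] = R; cache[f"Z{layer}"] = Z
                cache[f"N{layer}"] = N; cache[f"HN{layer}"] = HN
            x = Hs
        return x, cache

    def token_log_probs(self, inputs: np.ndarray) -> np.ndarray:
        """Log next-token distributions for every position, (B, T, V)."""
        h_top, _ = self._forward_rnn(inputs)
        T, B, H = h_top.shape
        logits = h_top.reshape(T * B, H) @ self.params["Wo"] + self.params["bo"]
        logp = _log_softmax(logits).reshape(T, B, self.vocab_size)
        return np.ascontiguousarray(logp.transpose(1, 0, 2))

    def loss(self, inputs: np.ndarray, targets: np.ndarray,
             mask: np.ndarray) -> float:
        """Mean NLL of next-token prediction over unmasked positions."""
        logp = self.token_log_probs(inputs)
        picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
        return float(-(picked * mask).sum() / mask.sum())

    # ------------------------------------------------------------------
    # backward + Adam
    # ------------------------------------------------------------------
    def train_step(self, inputs: np.ndarray, targets: np.ndarray,
                   mask: np.ndarray, lr: float,
                   betas: tuple[float, float] = (0.9, 0.999),
                   eps: float = 1e-8, clip_norm: float = 5.0) -> float:
        """One fused forward/backward/Adam update; returns the batch loss."""
        B, T = inputs.shape
        H, V = self.hidden_units, self.vocab_size
        h_top, cache = self._forward_rnn(inputs, want_cache=True)

        logits = h_top.reshape(T * B, H) @ self.params["Wo"] + self.params["bo"]
        logp = _log_softmax(logits)
        flat_t = targets.T.reshape(-1)           # time-major flattening
        flat_m = mask.T.reshape(-1).astype(logp.dtype)
        n_tok = flat_m.sum()
        rows = np.arange(T * B)
        loss = float(-(logp[rows, flat_t] * flat_m).sum() / n_tok)

        dlogits = np.exp(logp)
        dlogits[rows, flat_t] -= 1.0
        dlogits *= (flat_m / n_tok)[:, None]

        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = h_top.reshape(T * B, H).T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        d_out = (dlogits @ self.params["Wo"].T).reshape(T, B, H)

        for layer in range(self.n_layers - 1, -1, -1):
            Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
            x = cache[f"x{layer}"]
            Hs = cache[f"H{layer}"]
            R, Z = cache[f"R{layer}"], cache[f"Z{layer}"]
            N, HN = cache[f"N{layer}"], cache[f"HN{layer}"]
            dGx = np.empty((T, B, 3 * H), dtype=x.dtype)
            dGh = np.empty((T, B, 3 * H), dtype=x.dtype)
            dh_carry = np.zeros((B, H), dtype=x.dtype)
            WhT = np.ascontiguousarray(Wh.T)
            zero_h = np.zeros((B, H), dtype=x.dtype)
            for t in range(T - 1, -1, -1):
                dh = d_out[t] + dh_carry
                h_prev = Hs[t - 1] if t > 0 else zero_h
                r, z, n, hn = R[t], Z[t], N[t], HN[t]
                dn_pre = dh * (1.0 - z) * (1.0 - n * n)
                dz_pre = dh * (h_prev - n) * z * (1.0 - z)
                dr_pre = dn_pre * hn * r * (1.0 - r)
                dgx_t = dGx[t]
                dgx_t[:, :H] = dr_pre
                dgx_t[:, H:2 * H] = dz_pre
                dgx_t[:, 2 * H:] = dn_pre
                dgh_t = dGh[t]
                dgh_t[:, :H] = dr_pre
                dgh_t[:, H:2 * H] = dz_pre
                np.multiply(dn_pre, r, out=dgh_t[:, 2 * H:])
                dh_carry = dh * z + dgh_t @ WhT
            h_prev_all = np.concatenate([zero_h[None], Hs[:-1]], axis=0)
            d_in = x.shape[-1]
            grads[f"Wx{layer}"] = x.reshape(T * B, d_in).T @ dGx.reshape(T * B, 3 * H)
            grads[f"Wh{layer}"] = h_prev_all.reshape(T * B, H).T @ dGh.reshape(T * B, 3 * H)
            grads[f"bx{layer}"] = dGx.sum(axis=(0, 1))
            grads[f"bh{layer}"] = dGh.sum(axis=(0, 1))
            d_out = (dGx.reshape(T * B, 3 * H) @ Wx.T).reshape(T, B, d_in)

        demb = np.zeros_like(self.params["emb"])
        np.add.at(demb, inputs.T.reshape(-1), d_out.reshape(T * B, -1))
        grads["emb"] = demb

        # global-norm clip, then Adam
        gnorm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                            for g in grads.values()))
        if clip_norm and gnorm > clip_norm:
            scale = x.dtype.type(clip_norm / (gnorm + 1e-12))
            for g in grads.values():
                g *= scale
        b1, b2 = betas
        self._adam_t += 1
        t_ = self._adam_t
        corr = np.sqrt(1.0 - b2 ** t_) / (1.0 - b1 ** t_)
        for k_, g in grads.items():
            m, v = self._m[k_], self._v[k_]
            m *= b1; m += (1.0 - b1) * g
            v *= b2; v += (1.0 - b2) * g * g
            self.params[k_] -= (lr * corr) * m / (np.sqrt(v) + eps)
        return loss

    # ------------------------------------------------------------------
    # sampling
    # ------------------------------------------------------------------
    def sample_tokens(self, n: int, bos: int, eos: int, max_length: int,
                      rng: np.random.Generator, temperature: float = 1.0,
                      batch_size: int = 1024) -> list[list[int]]:
        """Ancestral sampling: start at BOS, draw until EOS or max_length.

        Returns the token bodies (without BOS/EOS) for ``n`` sequences.
        """
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        out: list[list[int]] = []
        remaining = n
        Hd = self.hidden_units
        while remaining > 0:
            B = min(batch_size, remaining)
            remaining -= B
            h = [np.zeros((B, Hd), dtype=_F32) for _ in range(self.n_layers)]
            tok = np.full(B, bos, dtype=np.int64)
            done = np.zeros(B, dtype=bool)
            drawn = np.empty((max_length, B), dtype=np.int64)
            steps = 0
            for _ in range(max_length):
                x = self.params["emb"][tok]  # (B, E)
                for layer in range(self.n_layers):
                    Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
                    bx, bh = self.params[f"bx{layer}"], self.params[f"bh{layer}"]
                    gx = x @ Wx + bx
                    gh = h[layer] @ Wh + bh
                    r = _sigmoid(gx[:, :Hd] + gh[:, :Hd])
                    z = _sigmoid(gx[:, Hd:2 * Hd] + gh[:, Hd:2 * Hd])
                    ncand = np.tanh(gx[:, 2 * Hd:] + r * gh[:, 2 * Hd:])
                    h[layer] = np.where(done[:, None], h[layer],
                                        (1.0 - z) * ncand + z * h[layer])
                    x = h[layer]
                logits = x @ self.params["Wo"] + self.params["bo"]
                probs = np.exp(_log_softmax(logits / temperature))
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random(B)
                tok = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
                tok = np.minimum(tok, self.vocab_size - 1)
                tok = np.where(done, eos, tok)
                done |= tok == eos
                drawn[steps] = tok
                steps += 1
                if done.all():
                    break
            for i in range(B):
                body = []
                for t in range(steps):
                    ti = int(drawn[t, i])
                    if ti == eos:
                        break
                    body.append(ti)
                out.append(body)
        return out

    # ------------------------------------------------------------------
    # state
    # ------------------------------------------------------------------
    def copy(self) -> "GRUStack":
        dup = GRUStack.__new__(GRUStack)
        dup.vocab_size = self.vocab_size
        dup.embedding_dim = self.embedding_dim
        dup.hidden_units = self.hidden_units
        dup.n_layers = self.n_layers
        dup.params = {k: v.copy() for k, v in self.params.items()}
        dup._m = {k: v.copy() for k, v in self._m.items()}
        dup._v = {k: v.copy() for k, v in self._v.items()}
        dup._adam_t = self._adam_t
        return dup
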