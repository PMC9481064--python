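"""Minimal fully-connected residual network (numpy forward/backward/Adam).

Architecture: an input projection, ``n_hidden`` equal-width hidden layers
with leaky-ReLU activations and identity residual skips every
``skip_period`` layers, and a linear output layer.  The softmax is masked:
structurally impossible classes get a large negative logit so they receive
zero probability and zero gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ResidualMLP"]

_NEG = -1e30


def _leaky(z, slope):
    return np.where(z > 0, z, slope * z)


def _leaky_grad(z, slope):
    return np.where(z > 0, 1.0, slope)


def masked_log_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    z = np.where(mask, logits, _NEG)
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


class ResidualMLP:
    """Plain-numpy residual MLP trained with Adam on masked cross-entropy."""

    def __init__(self, n_in, n_out, width=64, n_hidden=10, leaky_slope=0.01,
                 skip_period=2, rng=None):
        rng = np.random.default_rng(rng)
        self.n_hidden = int(n_hidden)
        self.leaky_slope = float(leaky_slope)
        self.skip_period = int(skip_period)

        def he(n1, n2):
            return rng.normal(0.0, np.sqrt(2.0 / n1), size=(n1, n2))

        self.params = {"W_in": he(n_in, width), "b_in": np.zeros(width),
                       "W_out": he(width, n_out) * 0.1, "b_out": np.zeros(n_out)}
        for i in range(self.n_hidden):
            self.params[f"W{i}"] = he(width, width)
            self.params[f"b{i}"] = np.zeros(width)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---- forward ---------------------------------------------------------
    def forward(self, X, want_cache=False):
        p = self.params
        acts = [_leaky(X @ p["W_in"] + p["b_in"], self.leaky_slope)]
        zs = []
        h = acts[0]
        for i in range(self.n_hidden):
            z = h @ p[f"W{i}"] + p[f"b{i}"]
            a = _leaky(z, self.leaky_slope)
            if (i + 1) % self.skip_period == 0 and (i + 1) >= self.skip_period:
                a = a + acts[i + 1 - self.skip_period]
            zs.append(z)
            acts.append(a)
            h = a
        logits = h @ p["W_out"] + p["b_out"]
        if want_cache:
            return logits, (X, acts, zs)
        return logits

    # ---- loss + gradients ------------------------------------------------
    def loss_and_grads(self, X, y, mask):
        logits, (X0, acts, zs) = self.forward(X, want_cache=True)
        B = X.shape[0]
        logp = masked_log_softmax(logits, mask)
        loss = -logp[np.arange(B), y].mean()

        probs = np.exp(logp)
        dlogits = probs
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        p = self.params
        g = {k: None for k in p}
        h_top = acts[-1]
        g["W_out"] = h_top.T @ dlogits
        g["b_out"] = dlogits.sum(axis=0)

        # gradient wrt each activation, filled in reverse
        ga = [None] * (self.n_hidden + 1)
        ga[self.n_hidden] = dlogits @ p["W_out"].T
        for i in range(self.n_hidden - 1, -1, -1):
            gout = ga[i + 1]
            if (i + 1) % self.skip_period == 0 and (i + 1) >= self.skip_period:
                j = i + 1 - self.skip_period
                ga[j] = gout.copy() if ga[j] is None else ga[j] + gout
            dz = gout * _leaky_grad(zs[i], self.leaky_slope)
            g[f"W{i}"] = acts[i].T @ dz
            g[f"b{i}"] = dz.sum(axis=0)
            gin = dz @ p[f"W{i}"].T
            ga[i] = gin if ga[i] is None else ga[i] + gin
        dz0 = ga[0] * _leaky_grad(X0 @ p["W_in"] + p["b_in"], self.leaky_slope)
        g["W_in"] = X0.T @ dz0
        g["b_in"] = dz0.sum(axis=0)
        return loss, g

    # ---- optimizer -------------------------------------------------------
    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ---- (de)serialization ----------------------------------------------
    def state_dict(self):
        meta = {"n_hidden": self.n_hidden, "leaky_slope": self.leaky_slope,
                "skip_period": self.skip_period}
        return meta, dict(self.params)

    @classmethod
    def from_state(cls, meta, params):
        n_in, width = params["W_in"].shape
        n_out = params["W_out"].shape[1]
        net = cls(n_in, n_out, width=width, n_hidden=meta["n_hidden"],
                  leaky_slope=meta["leaky_slope"], skip_period=meta["skip_period"])
        for k in net.params:
            net.params[k] = np.asarray(params[k])
        return net
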