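"""A small map-to-map convolutional network in pure NumPy.

Treats the processed L*H attention channels of a molecule as an image
and emits a per-pixel contact probability map.  Two 3x3 'same'
convolutions (C -> hidden ReLU -> 1), logits symmetrized as
(Z + Z^T)/2 before the sigmoid so predictions are symmetric by
construction, binary cross-entropy evaluated on eligible (off-band,
unpadded) pixels only, optimized with Adam.

The network is deliberately tiny: on planted synthetic corpora the
contact signal is (near-)linear in the aware channels, so a shallow
model suffices, and training stays fast on one CPU.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(C, N, N) -> (N*N, C*9) patches for a 3x3 'same' convolution."""
    c, n, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    cols = [xp[:, di : di + n, dj : dj + n] for di in range(3) for dj in range(3)]
    return np.stack(cols, axis=1).reshape(c * 9, n * n).T


def _col2im3(dcol: np.ndarray, c: int, n: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    d = dcol.T.reshape(c, 9, n, n)
    out = np.zeros((c, n + 2, n + 2))
    k = 0
    for di in range(3):
        for dj in range(3):
            out[:, di : di + n, dj : dj + n] += d[:, k]
            k += 1
    return out[:, 1:-1, 1:-1]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ContactCNN:
    """Two-layer convolutional contact-map predictor."""

    def __init__(self, n_channels: int, hidden: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_channels = n_channels
        self.hidden = hidden
        s1 = np.sqrt(2.0 / (n_channels * 9))
        s2 = np.sqrt(2.0 / (hidden * 9))
        self.params = {
            "W1": rng.normal(0, s1, size=(n_channels * 9, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0, s2, size=(hidden * 9, 1)),
            "b2": np.zeros(1),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------- forward

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """(C, N, N) channels -> (N, N) symmetric probability map."""
        if x.ndim != 3 or x.shape[0] != self.n_channels:
            raise ShapeError(
                f"expected ({self.n_channels}, N, N) input, got {x.shape}"
            )
        n = x.shape[1]
        col1 = _im2col3(x)
        pre1 = col1 @ self.params["W1"] + self.params["b1"]
        act1 = np.maximum(pre1, 0.0)
        hmap = act1.T.reshape(self.hidden, n, n)
        col2 = _im2col3(hmap)
        z = (col2 @ self.params["W2"] + self.params["b2"]).reshape(n, n)
        z_sym = (z + z.T) / 2.0
        prob = _sigmoid(z_sym)
        if cache is not None:
            cache.update(col1=col1, pre1=pre1, act1=act1, col2=col2, prob=prob, n=n)
        return prob

    # ------------------------------------------------------------ training

    def _step(self, x: np.ndarray, y: np.ndarray, mask: np.ndarray, lr: float) -> float:
        cache: dict = {}
        prob = self.forward(x, cache)
        m = mask.astype(float)
        msum = m.sum()
        if msum == 0:
            return 0.0
        eps = 1e-12
        loss = -(
            m * (y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        ).sum() / msum

        g_sym = (prob - y) * m / msum  # dL/dz_sym
        g_z = (g_sym + g_sym.T) / 2.0  # through the symmetrization
        n = cache["n"]
        g_flat = g_z.reshape(n * n, 1)
        grads = {
            "W2": cache["col2"].T @ g_flat,
            "b2": g_flat.sum(axis=0),
        }
        dcol2 = g_flat @ self.params["W2"].T
        dh = _col2im3(dcol2, self.hidden, n)
        dact1 = dh.reshape(self.hidden, n * n).T
        dpre1 = dact1 * (cache["pre1"] > 0)
        grads["W1"] = cache["col1"].T @ dpre1
        grads["b1"] = dpre1.sum(axis=0)
        dummy = _col2im3(dpre1 @ self.params["W1"].T, self.n_channels, n)
        _ = dummy  # input gradient unused; kept for adjoint testing

        self._adam_t += 1
        b1, b2 = 0.9, 0.999
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[k] / (1 - b2 ** self._adam_t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
        return float(loss)

    def fit(
        self,
        xs: list[np.ndarray],
        ys: list[np.ndarray],
        masks: list[np.ndarray],
        epochs: int = 30,
        lr: float = 0.02,
        seed: int = 0,
    ) -> list[float]:
        """Per-molecule stochastic training; returns the epoch loss curve."""
        rng = np.random.default_rng(seed)
        curve = []
        for _ in range(epochs):
            order = rng.permutation(len(xs))
            losses = [self._step(xs[k], ys[k], masks[k], lr) for k in order]
            curve.append(float(np.mean(losses)))
        return curve

    # -------------------------------------------------------- persistence

    def state_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "hidden": self.hidden,
            "params": {k: v.copy() for k, v in self.params.items()},
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "ContactCNN":
        net = cls(state["n_channels"], hidden=state["hidden"])
        net.params = {k: np.asarray(v) for k, v in state["params"].items()}
        return net
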