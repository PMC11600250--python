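"""Minimal deterministic dense-network engine used by the sorters.

A small fully-connected MLP with ReLU hidden units, trained with Adam on
mini-batches drawn from a seeded NumPy generator.  All state is plain
ndarrays, so identical seeds give bit-identical training trajectories on
a given platform — the determinism contract the sorters rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "SGDMomentum", "Autoencoder"]


class Dense:
    """One affine layer, Glorot-uniform initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)


class MLP:
    """Stack of Dense layers with per-layer activations ('relu' | 'linear')."""

    def __init__(self, sizes: list[int], activations: list[str], rng: np.random.Generator):
        assert len(activations) == len(sizes) - 1
        self.layers = [Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.activations = activations

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.append(layer.W)
            out.append(layer.b)
        return out

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = x
        if cache is not None:
            cache.append(a)
        for layer, act in zip(self.layers, self.activations):
            z = a @ layer.W + layer.b
            a = np.maximum(z, 0.0) if act == "relu" else z
            if cache is not None:
                cache.append(a)
        return a

    def backward(
        self, cache: list, grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of every parameter plus the gradient at the input.

        ``cache`` is the activation list recorded by :meth:`forward`.
        """
        grads: list[np.ndarray] = [None] * (2 * len(self.layers))
        g = grad_out
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            a_in, a_out = cache[li], cache[li + 1]
            if self.activations[li] == "relu":
                g = g * (a_out > 0)
            grads[2 * li] = a_in.T @ g
            grads[2 * li + 1] = g.sum(axis=0)
            g = g @ layer.W.T
        return grads, g


class Adam:
    """Adam optimizer over an explicit parameter list (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class SGDMomentum:
    """Plain SGD with classical momentum (updates in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.momentum
            v += g
            p -= self.lr * v


class Autoencoder:
    """Symmetric encoder/decoder MLP with linear latent and output layers.

    ``sizes`` runs from the input dimension to the latent dimension; the
    decoder mirrors it.  Hidden layers are ReLU.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        enc_act = ["relu"] * (len(sizes) - 2) + ["linear"]
        dec_sizes = sizes[::-1]
        dec_act = ["relu"] * (len(sizes) - 2) + ["linear"]
        self.encoder = MLP(sizes, enc_act, rng)
        self.decoder = MLP(dec_sizes, dec_act, rng)
        self.sizes = list(sizes)

    @property
    def params(self) -> list[np.ndarray]:
        return self.encoder.params + self.decoder.params

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(x)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x))

    def reconstruction_error(self, x: np.ndarray) -> float:
        return float(np.mean((self.reconstruct(x) - x) ** 2))

    def train(
        self,
        x: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float,
        rng: np.random.Generator,
        optimizer: Adam | None = None,
    ) -> list[float]:
        """Mini-batch MSE training; returns the per-epoch mean loss."""
        opt = optimizer if optimizer is not None else Adam(self.params, lr=lr)
        n = len(x)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                batch = x[order[start : start + batch_size]]
                cache_e: list = []
                cache_d: list = []
                z = self.encoder.forward(batch, cache_e)
                xhat = self.decoder.forward(z, cache_d)
                diff = xhat - batch
                losses.append(float(np.mean(diff**2)))
                g = 2.0 * diff / diff.size
                dec_grads, gz = self.decoder.backward(cache_d, g)
                enc_grads, _ = self.encoder.backward(cache_e, gz)
                opt.step(enc_grads + dec_grads)
            history.append(float(np.mean(losses)))
        return history
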