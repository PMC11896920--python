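"""Minimal sinusoidal coordinate network (SIREN) with hand-written backprop.

A SIREN is a multilayer perceptron with sine activations whose weight
initialisation keeps pre-activations distributed so that the network
represents smooth continuous functions of its (normalised) input
coordinates.  Here it parameterises a displacement field; training
needs gradients of a composite loss with respect to the weights *and*
with respect to the input points (for the cycle-consistency term, where
one network is evaluated at points produced by the other), so the
backward pass returns both.
"""

from __future__ import annotations

import numpy as np


class SirenNet:
    """Sine-activated MLP mapping R^in -> R^out."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_dim: int = 3,
        out_dim: int = 3,
        width: int = 64,
        hidden_layers: int = 3,
        w0: float = 30.0,
        final_scale: float = 1e-2,
    ):
        self.w0 = w0
        dims = [in_dim] + [width] * hidden_layers + [out_dim]
        self.params: list[list[np.ndarray]] = []
        for li, (n_in, n_out) in enumerate(zip(dims[:-1], dims[1:])):
            if li == 0:
                bound = 1.0 / n_in
            else:
                bound = np.sqrt(6.0 / n_in) / w0
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
            b = rng.uniform(-bound, bound, size=n_out)
            if li == len(dims) - 2:  # final linear layer: start near the zero field
                w *= final_scale
                b[:] = 0.0
            self.params.append([w, b])

    def zero_grads(self) -> list[list[np.ndarray]]:
        return [[np.zeros_like(w), np.zeros_like(b)] for w, b in self.params]

    def forward(self, x: np.ndarray):
        """Returns (y, cache); cache holds per-layer inputs and pre-activations."""
        cache = []
        a = x
        last = len(self.params) - 1
        for li, (w, b) in enumerate(self.params):
            z = a @ w + b
            cache.append((a, z))
            a = z if li == last else np.sin(self.w0 * z)
        return a, cache

    def backward(self, cache, grad_y: np.ndarray, grads) -> np.ndarray:
        """Accumulates dL/dparams into ``grads``; returns dL/dx.

        ``grad_y`` is dL/d(output); at each layer ``g`` holds dL/dz for
        that layer's pre-activation (the output layer has no sine).
        """
        g = grad_y
        last = len(self.params) - 1
        for li in range(last, -1, -1):
            a_prev, _ = cache[li]
            w, _b = self.params[li]
            grads[li][0] += a_prev.T @ g
            grads[li][1] += g.sum(axis=0)
            g = g @ w.T
            if li > 0:
                _, z_prev = cache[li - 1]
                g = g * (self.w0 * np.cos(self.w0 * z_prev))
        return g


class Adam:
    """Adam optimiser over a SirenNet's parameter list."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [[np.zeros_like(p) for p in group] for group in params]
        self.v = [[np.zeros_like(p) for p in group] for group in params]
        self.t = 0

    def step(self, grads, lr: float) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for group, gg, mm, vv in zip(self.params, grads, self.m, self.v):
            for p, g, m, v in zip(group, gg, mm, vv):
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def one_cycle_lr(
    iteration: int,
    total: int,
    max_lr: float,
    warmup_frac: float = 0.1,
    div_start: float = 25.0,
    div_final: float = 1e4,
) -> float:
    """One-cycle schedule: linear warm-up to ``max_lr``, cosine anneal down."""
    warm = max(1, int(round(warmup_frac * total)))
    if iteration < warm:
        frac = iteration / warm
        return max_lr / div_start + frac * (max_lr - max_lr / div_start)
    frac = (iteration - warm) / max(1, total - warm)
    lo = max_lr / div_final
    return lo + 0.5 * (max_lr - lo) * (1 + np.cos(np.pi * frac))
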