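"""Layer objects over the autograd engine.

Weight initialization follows the pix2pix convention: Gaussian with mean 0
and standard deviation 0.02, biases zero.  Normalization layers are
parameter-free (instance-style), so they contribute nothing to parameter
counts.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d, instance_norm

INIT_STD = 0.02


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        """All parameter tensors, regardless of the requires_grad flag
        (the flag is toggled to freeze/unfreeze, not to deregister)."""
        params: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Tensor):
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
                elif isinstance(value, dict):
                    stack.extend(v for v in value.values() if isinstance(v, Module))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=p.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Tensor(
            rng.normal(0.0, INIT_STD, (c_out, c_in, kernel, kernel)).astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Tensor(
            rng.normal(0.0, INIT_STD, (c_in, c_out, kernel, kernel)).astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class InstanceNorm(Module):
    """Parameter-free normalization; safe at any batch size."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        return instance_norm(x, self.eps)


def count_parameters(model: Module) -> int:
    """Number of trainable scalars in a model."""
    return int(sum(p.data.size for p in model.parameters()))
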