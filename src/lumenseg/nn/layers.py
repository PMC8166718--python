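"""Layer modules and the Adam optimizer for the autodiff engine.

Modules hold named :class:`~lumenseg.nn.tensor.Tensor` parameters and
recursively expose them for optimization and checkpointing.  Weight
initialization is He-normal and always driven by an explicit
``numpy.random.Generator`` so model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm2d, conv2d, conv_transpose2d_2x2

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "Adam"]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        out = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    out.append(v)
        return out

    def num_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def state_dict(self):
        state = {}
        for i, m in enumerate(self.modules()):
            for name, v in vars(m).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{i}.{name}"] = v.data.copy()
                elif isinstance(v, np.ndarray):  # running stats
                    state[f"{i}.{name}"] = v.copy()
        return state

    def load_state_dict(self, state):
        for i, m in enumerate(self.modules()):
            for name, v in vars(m).items():
                key = f"{i}.{name}"
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = state[key].astype(np.float32).reshape(v.data.shape)
                elif isinstance(v, np.ndarray):
                    v[...] = state[key]


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, pad=0):
        super().__init__()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0, scale, (cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    """2x2 stride-2 up-convolution."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (cin * 4))
        self.weight = Tensor(rng.normal(0, scale, (cin, cout, 2, 2)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x):
        return conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x):
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class Adam:
    """Adam with bias correction; a zero learning rate leaves weights intact."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
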