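"""Layer abstractions over the autodiff tensor ops.

Modules follow the familiar container pattern: parameters are discovered
recursively through attributes, ``train()``/``eval()`` toggle dropout and
batch-norm behaviour, and weight initialisation draws from an explicit
``numpy.random.Generator`` so identical seeds build identical networks.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d, max_pool2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def __call__(self, x):
        return self.forward(x)

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                yield v
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    yield v

    def train(self, mode=True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def buffers(self):
        """Non-trainable state (batch-norm running statistics)."""
        for m in [self, *self.modules()]:
            if isinstance(m, BatchNorm2d):
                yield m, "running_mean"
                yield m, "running_var"

    def state_dict(self):
        state = [p.data.copy() for p in self.parameters()]
        state += [getattr(m, name).copy() for m, name in self.buffers()]
        return state

    def load_state_dict(self, state):
        params = list(self.parameters())
        buffers = list(self.buffers())
        if len(params) + len(buffers) != len(state):
            raise ValueError("state size mismatch")
        for p, d in zip(params, state):
            p.data = np.asarray(d, dtype=np.float32).reshape(p.data.shape)
        for (m, name), d in zip(buffers, state[len(params):]):
            setattr(m, name, np.asarray(d, dtype=np.float32).copy())


def n_parameters(module):
    """Total count of trainable scalars in a module."""
    return sum(p.data.size for p in module.parameters())


def _he_init(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=0, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, cin, cout, k, rng, stride=2, padding=0,
                 output_padding=0, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.output_padding = output_padding
        self.weight = Parameter(_he_init(rng, (cin, cout, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride,
                                self.padding, self.output_padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        g, b = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mu, var = self.running_mean, self.running_var

        inv = 1.0 / np.sqrt(var + self.eps)
        mu4 = mu.reshape(1, -1, 1, 1)
        inv4 = inv.reshape(1, -1, 1, 1)
        xhat = (x.data - mu4) * inv4
        out_data = (g.data.reshape(1, -1, 1, 1) * xhat
                    + b.data.reshape(1, -1, 1, 1))
        training = self.training
        n_elem = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def bwd(grad):
            if g.requires_grad:
                g._accum((grad * xhat).sum(axis=(0, 2, 3)))
            if b.requires_grad:
                b._accum(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gx = grad * g.data.reshape(1, -1, 1, 1)
                if training:
                    # full batch-norm backward: mean/var depend on x
                    m = n_elem
                    s1 = gx.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = (gx - s1 / m - xhat * s2 / m) * inv4
                else:
                    dx = gx * inv4
                x._accum(dx.astype(np.float32))

        return Tensor(out_data, True, (x, g, b), bwd)


class Dropout(Module):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape) < keep) / keep
        mask = mask.astype(np.float32)
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class MaxPool2d(Module):
    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return max_pool2d(x, self.k)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
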