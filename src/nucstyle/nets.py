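"""Network building blocks for the disentangled style-transfer model.

Architectures follow the two-encoder translation family: a content encoder
producing a spatial, domain-invariant code; a variational attribute encoder
producing a low-dimensional style vector; a single shared generator
conditioned on a one-hot domain code; a patch-level domain discriminator and
a small classifier that plays adversary on the content code.  Channel widths
are configurable so the same shapes run as a fast test profile or a larger
full profile.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, upsample2x

__all__ = [
    "Conv2d",
    "Linear",
    "InstanceNorm",
    "ResBlock",
    "ContentEncoder",
    "AttributeEncoder",
    "Generator",
    "DomainDiscriminator",
    "ContentDiscriminator",
    "Adam",
]


class Module:
    """Base: tracks child modules / parameters by attribute name."""

    def parameters(self):
        params = []
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append((name, value))
            elif isinstance(value, Module):
                params.extend(
                    (f"{name}.{sub}", p) for sub, p in value.parameters()
                )
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.extend(
                            (f"{name}.{i}.{sub}", p)
                            for sub, p in item.parameters()
                        )
        return params

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state):
        for name, p in self.parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(
            rng.normal(0, std, size=(cout, cin, k, k)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, fin, fout, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / fin)
        self.weight = Tensor(rng.normal(0, std, size=(fin, fout)), requires_grad=True)
        self.bias = Tensor(np.zeros(fout), requires_grad=True)

    def __call__(self, x):
        return x @ self.weight + self.bias


class InstanceNorm(Module):
    """Per-sample, per-channel normalization with affine parameters."""

    def __init__(self, c, eps=1e-5):
        self.gamma = Tensor(np.ones((1, c, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        m = x.mean(axis=(2, 3), keepdims=True)
        v = ((x - m) ** 2).mean(axis=(2, 3), keepdims=True)
        return (x - m) / (v + self.eps).sqrt() * self.gamma + self.beta


class ResBlock(Module):
    def __init__(self, c, rng=None):
        self.conv1 = Conv2d(c, c, rng=rng)
        self.norm1 = InstanceNorm(c)
        self.conv2 = Conv2d(c, c, rng=rng)
        self.norm2 = InstanceNorm(c)

    def __call__(self, x):
        h = self.norm1(self.conv1(x)).leaky_relu()
        h = self.norm2(self.conv2(h))
        return x + h


def _broadcast_vec(vec: Tensor, h: int, w: int) -> Tensor:
    """Tile an (n, d) vector tensor into an (n, d, h, w) map."""
    n, d = vec.shape
    ones = Tensor(np.ones((1, 1, h, w)))
    return vec.reshape(n, d, 1, 1) * ones


class ContentEncoder(Module):
    """Two stride-2 conv blocks then residual blocks; output C_c x H/4 x W/4."""

    def __init__(self, c_content=64, rng=None):
        self.c_content = c_content
        self.conv1 = Conv2d(3, c_content // 2, stride=2, rng=rng)
        self.norm1 = InstanceNorm(c_content // 2)
        self.conv2 = Conv2d(c_content // 2, c_content, stride=2, rng=rng)
        self.norm2 = InstanceNorm(c_content)
        self.blocks = [ResBlock(c_content, rng=rng) for _ in range(3)]

    def __call__(self, x):
        h = self.norm1(self.conv1(x)).leaky_relu()
        h = self.norm2(self.conv2(h)).leaky_relu()
        for b in self.blocks:
            h = b(h)
        return h


class AttributeEncoder(Module):
    """Conv stack + global average pool + (mu, logvar) heads."""

    def __init__(self, n_domains, n_attr=8, base=16, rng=None):
        self.n_domains = n_domains
        self.n_attr = n_attr
        self.conv1 = Conv2d(3 + n_domains, base, stride=2, rng=rng)
        self.conv2 = Conv2d(base, base * 2, stride=2, rng=rng)
        self.conv3 = Conv2d(base * 2, base * 4, stride=2, rng=rng)
        self.conv4 = Conv2d(base * 4, base * 4, stride=2, rng=rng)
        self.head_mu = Linear(base * 4, n_attr, rng=rng)
        self.head_logvar = Linear(base * 4, n_attr, rng=rng)

    def __call__(self, x, domain_map):
        h = concat([x, domain_map], axis=1)
        h = self.conv1(h).leaky_relu()
        h = self.conv2(h).leaky_relu()
        h = self.conv3(h).leaky_relu()
        h = self.conv4(h).leaky_relu()
        pooled = h.mean(axis=(2, 3))
        mu = self.head_mu(pooled)
        logvar = self.head_logvar(pooled).clamp(-10.0, 10.0)
        return mu, logvar


def _adain(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Adaptive instance norm: normalize spatially, re-scale by style."""
    m = x.mean(axis=(2, 3), keepdims=True)
    v = ((x - m) ** 2).mean(axis=(2, 3), keepdims=True)
    c = x.shape[1]
    return (x - m) / (v + eps).sqrt() * (gamma.reshape(1, c, 1, 1) + 1.0) + (
        beta.reshape(1, c, 1, 1)
    )


class AdaResBlock(Module):
    """Residual block whose normalizations are style-modulated (AdaIN)."""

    def __init__(self, c, rng=None):
        self.conv1 = Conv2d(c, c, rng=rng)
        self.conv2 = Conv2d(c, c, rng=rng)
        self.c = c

    def __call__(self, x, g1, b1, g2, b2):
        h = _adain(self.conv1(x), g1, b1).leaky_relu()
        h = _adain(self.conv2(h), g2, b2)
        return x + h


class Generator(Module):
    """Residual decoder with style injected through AdaIN.

    The attribute vector and one-hot domain code are mapped by a small MLP
    to per-channel (gamma, beta) pairs that modulate every normalization in
    the decoder.  A plain InstanceNorm would subtract exactly the constant
    shifts that carry global style (background colour, brightness), so the
    style signal must enter through the normalization parameters instead of
    as concatenated channels.
    """

    def __init__(self, c_content=64, n_attr=8, n_domains=5, rng=None):
        cc = c_content
        self.c4 = max(cc // 4, 8)
        self.mix = Conv2d(cc + n_attr + n_domains, cc, k=1, pad=0, rng=rng)
        self.blocks = [AdaResBlock(cc, rng=rng) for _ in range(3)]
        self.up1 = Conv2d(cc, cc // 2, rng=rng)
        self.up2 = Conv2d(cc // 2, self.c4, rng=rng)
        self.out = Conv2d(self.c4, 3, rng=rng)
        # style MLP -> (gamma, beta) for 6 block norms + 2 upsample norms
        self._sites = [cc] * 6 + [cc // 2, self.c4]
        n_style = 2 * sum(self._sites)
        hidden = max(32, 2 * n_attr)
        self.style1 = Linear(n_attr + n_domains, hidden, rng=rng)
        self.style2 = Linear(hidden, n_style, rng=rng)

    def _style_params(self, z_a: Tensor, domain_vec: Tensor):
        s = self.style1(concat([z_a, domain_vec], axis=1)).leaky_relu()
        flat = (self.style2(s) * 0.5).reshape(-1)
        out, off = [], 0
        for c in self._sites:
            gamma = flat.narrow(0, off, c)
            beta = flat.narrow(0, off + c, c)
            out.append((gamma, beta))
            off += 2 * c
        return out

    def __call__(self, z_c, z_a, domain_vec):
        n, _, h, w = z_c.shape
        styles = self._style_params(z_a, domain_vec)
        cond = concat([z_c, _broadcast_vec(z_a, h, w),
                       _broadcast_vec(domain_vec, h, w)], axis=1)
        x = self.mix(cond).leaky_relu()
        for i, blk in enumerate(self.blocks):
            (g1, b1), (g2, b2) = styles[2 * i], styles[2 * i + 1]
            x = blk(x, g1, b1, g2, b2)
        g, b = styles[6]
        x = _adain(self.up1(upsample2x(x)), g, b).leaky_relu()
        g, b = styles[7]
        x = _adain(self.up2(upsample2x(x)), g, b).leaky_relu()
        return self.out(x).tanh()


class DomainDiscriminator(Module):
    """Domain-conditional least-squares discriminator.

    Two heads over a shared conv trunk: a patch-level real/fake map (input
    conditioned on the one-hot domain as constant channels) and an auxiliary
    per-image domain classifier, which gives the generator a direct,
    non-saturating gradient toward the target domain's appearance.
    """

    def __init__(self, n_domains, base=16, rng=None):
        self.conv1 = Conv2d(3 + n_domains, base, stride=2, rng=rng)
        self.conv2 = Conv2d(base, base * 2, stride=2, rng=rng)
        self.conv3 = Conv2d(base * 2, base * 4, stride=2, rng=rng)
        self.out = Conv2d(base * 4, 1, k=1, pad=0, rng=rng)
        self.cls = Conv2d(base * 4, n_domains, k=1, pad=0, rng=rng)

    def __call__(self, x, domain_map):
        h = concat([x, domain_map], axis=1)
        h = self.conv1(h).leaky_relu()
        h = self.conv2(h).leaky_relu()
        h = self.conv3(h).leaky_relu()
        return self.out(h)

    def classify(self, x):
        """Domain logits for an image (domain channels zeroed: unconditioned)."""
        n, _, hh, ww = x.shape
        zeros = Tensor(np.zeros((n, self.cls.weight.shape[0], hh, ww),
                                dtype=np.float32))
        h = concat([x, zeros], axis=1)
        h = self.conv1(h).leaky_relu()
        h = self.conv2(h).leaky_relu()
        h = self.conv3(h).leaky_relu()
        return self.cls(h).mean(axis=(2, 3))


class ContentDiscriminator(Module):
    """Domain classifier on the content code (adversary for E_c)."""

    def __init__(self, c_content, n_domains, rng=None):
        self.conv1 = Conv2d(c_content, c_content, stride=2, rng=rng)
        self.conv2 = Conv2d(c_content, c_content, stride=2, rng=rng)
        self.head = Linear(c_content, n_domains, rng=rng)

    def __call__(self, z_c):
        h = self.conv1(z_c).leaky_relu()
        h = self.conv2(h).leaky_relu()
        return self.head(h.mean(axis=(2, 3)))


class Adam:
    """Adam with classic (L2-coupled) weight decay."""

    def __init__(self, params, lr=1e-4, betas=(0.5, 0.999), weight_decay=1e-4):
        self.params = [p for _, p in params]
        self.lr, self.b1, self.b2 = lr, betas[0], betas[1]
        self.wd = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)
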