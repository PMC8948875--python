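"""Disentangled multi-domain style transfer for microscopy images.

The model decomposes an image into a spatial, domain-invariant *content*
code (nuclei locations and shapes) and a low-dimensional, domain-specific
*attribute* code (stain colour, background, contrast), plus a one-hot domain
label.  A single shared generator re-assembles any (content, attribute,
domain) triple into an image.  Training on unpaired images from several
modalities uses six loss terms:

* cross-cycle consistency — swap content codes between two domains,
  translate, re-encode, swap back; the second translation must recover the
  originals (L1),
* image self-reconstruction (L1),
* a least-squares adversarial loss on generated images, conditioned on the
  target domain,
* an adversarial domain classifier on the content code, pushing the content
  encoder toward domain-uniform codes,
* latent regression — a style vector drawn from the prior must be
  recoverable from the image generated with it (L1 on the posterior mean),
* a KL term tying the attribute posterior to a standard Gaussian.

Because augmentation resamples only the attribute code and domain while the
content code stays fixed, an augmented image inherits the source image's
instance mask bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .autograd import Tensor, no_grad
from .nets import (
    Adam,
    AttributeEncoder,
    ContentDiscriminator,
    ContentEncoder,
    DomainDiscriminator,
    Generator,
)
from .synthetic import LabeledImage

__all__ = [
    "LossWeights",
    "StyleConfig",
    "StyleModel",
    "kl_loss",
    "recon_loss",
    "total_loss",
    "one_hot",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the six training loss terms."""

    w_cc: float = 10.0
    w_c: float = 1.0
    w_d: float = 1.0
    w_recon: float = 10.0
    w_latent: float = 10.0
    w_KL: float = 0.01

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class StyleConfig:
    """Model size and optimisation settings.

    The full profile mirrors common practice for this model family
    (content channels 64, Adam at 1e-4 with betas (0.5, 0.999), weight decay
    1e-4, batch size two); the test profile shrinks channel widths four-fold
    so smoke training runs on a single CPU.
    """

    n_domains: int = 5
    n_attr: int = 8
    c_content: int = 64
    attr_base: int = 32
    disc_base: int = 32
    lr: float = 1e-4
    betas: tuple = (0.5, 0.999)
    weight_decay: float = 1e-4
    batch_size: int = 2
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)

    @classmethod
    def test_profile(cls, n_domains: int = 2, seed: int = 0, lr: float = 1e-3):
        """Small widths and a faster learning rate for CPU smoke runs."""
        return cls(
            n_domains=n_domains, c_content=16, attr_base=8, disc_base=8,
            lr=lr, seed=seed,
        )


def one_hot(domain: int, n_domains: int) -> np.ndarray:
    if not 0 <= domain < n_domains:
        raise ValueError(f"domain {domain} outside [0, {n_domains})")
    v = np.zeros(n_domains, dtype=np.float32)
    v[domain] = 1.0
    return v


def _check_one_hot(vec: np.ndarray, n_domains: int) -> np.ndarray:
    vec = np.asarray(vec, dtype=np.float32).ravel()
    if vec.shape != (n_domains,) or not (
        (vec == 1).sum() == 1 and ((vec == 0) | (vec == 1)).all()
    ):
        raise ValueError("domain code must be one-hot of length n_domains")
    return vec


def _to_tensor(image: np.ndarray) -> Tensor:
    """H x W x 3 in [0,1] -> 1 x 3 x H x W in [-1,1]."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    if image.shape[0] % 4 or image.shape[1] % 4:
        raise ValueError("image sides must be divisible by 4")
    return Tensor((image * 2.0 - 1.0).transpose(2, 0, 1)[None])


def _to_image(t: Tensor) -> np.ndarray:
    out = (t.data[0].transpose(1, 2, 0) + 1.0) / 2.0
    return np.clip(out.astype(np.float64), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Loss terms.  Each accepts Tensors or arrays and returns a Tensor so the
# same code serves training and the brute-force comparisons in the tests.
# ---------------------------------------------------------------------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def kl_loss(mu, logvar) -> Tensor:
    """KL(N(mu, diag exp(logvar)) || N(0, I)), closed form, mean over batch.

    0.5 * sum(mu^2 + exp(logvar) - 1 - logvar) per sample.  Tensor inputs
    stay on the differentiable float32 path; plain arrays are evaluated at
    float64 precision.
    """
    if isinstance(mu, Tensor) or isinstance(logvar, Tensor):
        mu, logvar = _as_tensor(mu), _as_tensor(logvar)
        if np.isnan(mu.data).any() or np.isnan(logvar.data).any():
            raise FloatingPointError("NaN in attribute posterior")
        if mu.shape != logvar.shape:
            raise ValueError("mu and logvar must have equal shape")
        per_sample = (mu**2 + logvar.exp() - 1.0 - logvar).sum(axis=-1) * 0.5
        return per_sample.mean()
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=np.float64))
    if np.isnan(mu).any() or np.isnan(logvar).any():
        raise FloatingPointError("NaN in attribute posterior")
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar must have equal shape")
    per_sample = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=-1)
    return Tensor(per_sample.mean(), dtype=np.float64)


def recon_loss(x, x_hat) -> Tensor:
    """Mean absolute difference between two images/batches."""
    if isinstance(x, Tensor) or isinstance(x_hat, Tensor):
        x, x_hat = _as_tensor(x), _as_tensor(x_hat)
        if x.shape != x_hat.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
        return (x - x_hat).abs().mean()
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return Tensor(np.abs(x - x_hat).mean(), dtype=np.float64)


def total_loss(losses: dict, weights: LossWeights) -> Tensor:
    """Weighted sum of the six named loss terms."""
    required = ("cc", "c", "d", "recon", "latent", "KL")
    missing = [k for k in required if k not in losses]
    if missing:
        raise ValueError(f"missing loss terms: {missing}")
    if any(isinstance(losses[k], Tensor) for k in required):
        vals = {k: _as_tensor(losses[k]) for k in required}
        return (
            weights.w_cc * vals["cc"]
            + weights.w_c * vals["c"]
            + weights.w_d * vals["d"]
            + weights.w_recon * vals["recon"]
            + weights.w_latent * vals["latent"]
            + weights.w_KL * vals["KL"]
        )
    w = (weights.w_cc, weights.w_c, weights.w_d, weights.w_recon,
         weights.w_latent, weights.w_KL)
    vals = [float(losses[k]) for k in required]
    if not all(np.isfinite(vals)):
        raise ValueError("loss terms must be finite")
    return Tensor(float(np.dot(w, vals)), dtype=np.float64)


def _lsgan(pred: Tensor, target: float) -> Tensor:
    return ((pred - target) ** 2).mean()


def _ce_to_label(logits: Tensor, label: int) -> Tensor:
    logp = logits - logits.logsumexp(axis=1)
    onehot = np.zeros(logits.shape, dtype=np.float32)
    onehot[:, label] = 1.0
    return -((logp * Tensor(onehot)).sum(axis=1).mean())


def _ce_to_uniform(logits: Tensor) -> Tensor:
    d = logits.shape[1]
    logp = logits - logits.logsumexp(axis=1)
    return -(logp.mean(axis=1).mean())  # mean over classes = uniform CE / ln-base


@dataclass
class AttributeCode:
    mu: np.ndarray
    logvar: np.ndarray
    z_a: np.ndarray


class StyleModel:
    """Disentangled multi-domain style-transfer model."""

    def __init__(self, config: Optional[StyleConfig] = None):
        self.config = config or StyleConfig()
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.Ec = ContentEncoder(cfg.c_content, rng=rng)
        self.Ea = AttributeEncoder(cfg.n_domains, cfg.n_attr, cfg.attr_base, rng=rng)
        self.G = Generator(cfg.c_content, cfg.n_attr, cfg.n_domains, rng=rng)
        self.D_dom = DomainDiscriminator(cfg.n_domains, cfg.disc_base, rng=rng)
        self.D_con = ContentDiscriminator(cfg.c_content, cfg.n_domains, rng=rng)
        self.is_trained = False
        self.loss_history: List[dict] = []

    # -- encoding / generation -------------------------------------------
    def _domain_map(self, vec: np.ndarray, h: int, w: int) -> Tensor:
        return Tensor(np.broadcast_to(vec[None, :, None, None], (1, len(vec), h, w)).copy())

    def encode_content(self, image: np.ndarray) -> Tensor:
        """Spatial content code, C_c x H/4 x W/4 (deterministic)."""
        with no_grad():
            return self.Ec(_to_tensor(image))

    def encode_attribute(
        self, image: np.ndarray, domain, rng: np.random.Generator
    ) -> AttributeCode:
        """Variational attribute code; z_a = mu + exp(logvar/2) * eps."""
        vec = _check_one_hot(
            one_hot(domain, self.config.n_domains) if np.isscalar(domain) else domain,
            self.config.n_domains,
        )
        with no_grad():
            x = _to_tensor(image)
            mu, logvar = self.Ea(x, self._domain_map(vec, *x.shape[2:]))
        eps = rng.standard_normal(self.config.n_attr).astype(np.float32)
        z_a = mu.data[0] + np.exp(logvar.data[0] / 2.0) * eps
        return AttributeCode(mu=mu.data[0], logvar=logvar.data[0], z_a=z_a)

    def generate(self, z_c, z_a, domain) -> np.ndarray:
        """Decode (content, attribute, domain) into an image in [0, 1]."""
        z_c = z_c if isinstance(z_c, Tensor) else Tensor(z_c)
        vec = _check_one_hot(
            one_hot(domain, self.config.n_domains) if np.isscalar(domain) else domain,
            self.config.n_domains,
        )
        z_a = np.asarray(z_a, dtype=np.float32).reshape(1, -1)
        if z_a.shape[1] != self.config.n_attr:
            raise ValueError("z_a has wrong length")
        with no_grad():
            out = self.G(z_c, Tensor(z_a), Tensor(vec[None]))
        return _to_image(out)

    # -- loss graph pieces (training-side, gradient-carrying) -------------
    def _encode_pair(self, x: Tensor, vec: np.ndarray, rng):
        z_c = self.Ec(x)
        mu, logvar = self.Ea(x, self._domain_map(vec, *x.shape[2:]))
        eps = Tensor(rng.standard_normal(mu.shape).astype(np.float32))
        z_a = mu + (logvar * 0.5).exp() * eps
        return z_c, mu, logvar, z_a

    def cross_cycle_loss(self, x_i, x_j, domain_i: int, domain_j: int, rng) -> Tensor:
        """Two-step swapped-content translation loss, L1 against the originals."""
        if domain_i == domain_j:
            raise ValueError("cross-cycle requires two distinct domains")
        vi = one_hot(domain_i, self.config.n_domains)
        vj = one_hot(domain_j, self.config.n_domains)
        xi = x_i if isinstance(x_i, Tensor) else _to_tensor(x_i)
        xj = x_j if isinstance(x_j, Tensor) else _to_tensor(x_j)
        z_ci, _, _, z_ai = self._encode_pair(xi, vi, rng)
        z_cj, _, _, z_aj = self._encode_pair(xj, vj, rng)
        # first translation: swap content
        u = self.G(z_cj, z_ai, Tensor(vi[None]))  # domain i look, content j
        v = self.G(z_ci, z_aj, Tensor(vj[None]))  # domain j look, content i
        # re-encode and swap back
        z_cu, _, _, z_au = self._encode_pair(u, vi, rng)
        z_cv, _, _, z_av = self._encode_pair(v, vj, rng)
        x_i2 = self.G(z_cv, z_au, Tensor(vi[None]))
        x_j2 = self.G(z_cu, z_av, Tensor(vj[None]))
        return recon_loss(xi, x_i2) + recon_loss(xj, x_j2)

    def adversarial_losses(self, real, fake, domain: int):
        """(L_D on discriminator, L_D generator side, L_c encoder side, L_c classifier).

        Least-squares GAN on the domain-conditional discriminator; on the
        content side, the classifier is trained with cross-entropy to the
        true domain while the encoder is pushed toward the uniform
        distribution over domains.
        """
        vec = one_hot(domain, self.config.n_domains)
        x_r = real if isinstance(real, Tensor) else _to_tensor(real)
        x_f = fake if isinstance(fake, Tensor) else _to_tensor(fake)
        dm = self._domain_map(vec, *x_r.shape[2:])
        d_real = self.D_dom(x_r, dm)
        d_fake_det = self.D_dom(x_f.detach(), dm)
        loss_d_disc = _lsgan(d_real, 1.0) + _lsgan(d_fake_det, 0.0)
        loss_d_gen = _lsgan(self.D_dom(x_f, dm), 1.0)
        z_c = self.Ec(x_r)
        logits_enc = self.D_con(z_c)
        loss_c_enc = _ce_to_uniform(logits_enc)
        logits_cls = self.D_con(z_c.detach())
        loss_c_cls = _ce_to_label(logits_cls, domain)
        return loss_d_disc, loss_d_gen, loss_c_enc, loss_c_cls

    def latent_regression_loss(self, z_c, domain: int, rng) -> Tensor:
        """L1 between a prior-drawn style vector and its recovery from the image."""
        vec = one_hot(domain, self.config.n_domains)
        z_r = Tensor(rng.standard_normal((1, self.config.n_attr)).astype(np.float32))
        x_r = self.G(z_c, z_r, Tensor(vec[None]))
        mu, _ = self.Ea(x_r, self._domain_map(vec, *x_r.shape[2:]))
        return recon_loss(z_r, mu)

    # -- training ----------------------------------------------------------
    def train(
        self,
        dataset: Sequence[LabeledImage],
        iterations: int = 500,
        checkpoint_dir=None,
        checkpoint_every: int = 0,
        log_every: int = 0,
    ) -> List[dict]:
        """Alternating discriminator/generator optimisation.

        Each iteration draws one image from each of two distinct domains
        (the configured batch size of two), updates the two discriminators
        on detached codes/fakes, then updates encoders and generator on the
        full weighted objective.  Returns the per-iteration loss history.
        """
        cfg = self.config
        by_domain = {}
        for lab in dataset:
            if lab.domain_id is None:
                raise ValueError("all training images need a domain_id")
            by_domain.setdefault(lab.domain_id, []).append(lab)
        domains = sorted(by_domain)
        if len(domains) < 2:
            raise ValueError("training needs at least two domains")
        if max(domains) >= cfg.n_domains:
            raise ValueError("domain_id outside configured n_domains")
        # include the iteration offset so resumed training continues the
        # stream instead of replaying the first call's draws
        ss = np.random.SeedSequence([cfg.seed, 0xA06, len(self.loss_history)])
        rng = np.random.default_rng(ss)
        opt_d = Adam(self.D_dom.parameters(), cfg.lr, cfg.betas, cfg.weight_decay)
        opt_c = Adam(self.D_con.parameters(), cfg.lr, cfg.betas, cfg.weight_decay)
        gen_params = (
            self.Ec.parameters() + self.Ea.parameters() + self.G.parameters()
        )
        opt_g = Adam(gen_params, cfg.lr, cfg.betas, cfg.weight_decay)
        history: List[dict] = []
        for it in range(iterations):
            di, dj = rng.choice(domains, size=2, replace=False)
            di, dj = int(di), int(dj)
            lab_i = by_domain[di][rng.integers(len(by_domain[di]))]
            lab_j = by_domain[dj][rng.integers(len(by_domain[dj]))]
            xi, xj = _to_tensor(lab_i.pixels), _to_tensor(lab_j.pixels)
            vi, vj = one_hot(di, cfg.n_domains), one_hot(dj, cfg.n_domains)
            dm_i = self._domain_map(vi, *xi.shape[2:])
            dm_j = self._domain_map(vj, *xj.shape[2:])

            # ---- generator/encoder pass (graph reused for D updates) ----
            z_ci, mu_i, lv_i, z_ai = self._encode_pair(xi, vi, rng)
            z_cj, mu_j, lv_j, z_aj = self._encode_pair(xj, vj, rng)
            x_ii = self.G(z_ci, z_ai, Tensor(vi[None]))
            x_jj = self.G(z_cj, z_aj, Tensor(vj[None]))
            l_recon = recon_loss(xi, x_ii) + recon_loss(xj, x_jj)
            u = self.G(z_cj, z_ai, Tensor(vi[None]))
            v = self.G(z_ci, z_aj, Tensor(vj[None]))
            z_cu, _, _, z_au = self._encode_pair(u, vi, rng)
            z_cv, _, _, z_av = self._encode_pair(v, vj, rng)
            x_i2 = self.G(z_cv, z_au, Tensor(vi[None]))
            x_j2 = self.G(z_cu, z_av, Tensor(vj[None]))
            l_cc = recon_loss(xi, x_i2) + recon_loss(xj, x_j2)
            l_c_enc = _ce_to_uniform(self.D_con(z_ci)) + _ce_to_uniform(
                self.D_con(z_cj)
            )
            # latent branch: generate from prior-sampled attributes so the
            # generator is adversarially constrained in exactly the regime
            # used for augmentation (z_a ~ N(0, I) + target domain)
            z_r1 = Tensor(rng.standard_normal((1, cfg.n_attr)).astype(np.float32))
            z_r2 = Tensor(rng.standard_normal((1, cfg.n_attr)).astype(np.float32))
            x_qj = self.G(Tensor(z_ci.data), z_r1, Tensor(vj[None]))
            x_qi = self.G(Tensor(z_cj.data), z_r2, Tensor(vi[None]))
            mu_qj, _ = self.Ea(x_qj, dm_j)
            mu_qi, _ = self.Ea(x_qi, dm_i)
            l_latent = recon_loss(z_r1, mu_qj) + recon_loss(z_r2, mu_qi)
            l_kl = kl_loss(mu_i, lv_i) + kl_loss(mu_j, lv_j)
            l_adv_g = (
                _lsgan(self.D_dom(u, dm_i), 1.0)
                + _lsgan(self.D_dom(v, dm_j), 1.0)
                + _lsgan(self.D_dom(x_qi, dm_i), 1.0)
                + _lsgan(self.D_dom(x_qj, dm_j), 1.0)
                # auxiliary head: fakes must classify as their target domain
                + _ce_to_label(self.D_dom.classify(u), di)
                + _ce_to_label(self.D_dom.classify(v), dj)
                + _ce_to_label(self.D_dom.classify(x_qi), di)
                + _ce_to_label(self.D_dom.classify(x_qj), dj)
            )
            w = cfg.weights
            l_total = (
                w.w_cc * l_cc
                + w.w_recon * l_recon
                + w.w_d * l_adv_g
                + w.w_c * l_c_enc
                + w.w_latent * l_latent
                + w.w_KL * l_kl
            )
            opt_g.zero_grad()
            l_total.backward()
            opt_g.step()

            # ---- discriminator updates on detached fakes/codes ----------
            with no_grad():
                z_ci_d = self.Ec(xi).detach()
                z_cj_d = self.Ec(xj).detach()
            l_d_disc = (
                _lsgan(self.D_dom(xi, dm_i), 1.0)
                + _lsgan(self.D_dom(Tensor(u.data), dm_i), 0.0)
                + _lsgan(self.D_dom(Tensor(x_qi.data), dm_i), 0.0) * 0.5
                + _lsgan(self.D_dom(xj, dm_j), 1.0)
                + _lsgan(self.D_dom(Tensor(v.data), dm_j), 0.0)
                + _lsgan(self.D_dom(Tensor(x_qj.data), dm_j), 0.0) * 0.5
                # auxiliary head learns domains from real images only
                + _ce_to_label(self.D_dom.classify(xi), di)
                + _ce_to_label(self.D_dom.classify(xj), dj)
            )
            opt_d.zero_grad()
            l_d_disc.backward()
            opt_d.step()
            l_c_cls = _ce_to_label(self.D_con(z_ci_d), di) + _ce_to_label(
                self.D_con(z_cj_d), dj
            )
            opt_c.zero_grad()
            l_c_cls.backward()
            opt_c.step()

            history.append(
                {
                    "iteration": it,
                    "recon": float(l_recon.data) / 2.0,
                    "cc": float(l_cc.data) / 2.0,
                    "adv_g": float(l_adv_g.data),
                    "adv_d": float(l_d_disc.data),
                    "content_enc": float(l_c_enc.data),
                    "content_cls": float(l_c_cls.data),
                    "latent": float(l_latent.data),
                    "kl": float(l_kl.data),
                    "total": float(l_total.data),
                }
            )
            if log_every and (it + 1) % log_every == 0:
                print(
                    f"iter {it + 1}/{iterations}  recon={history[-1]['recon']:.4f}"
                    f"  cc={history[-1]['cc']:.4f}  adv_d={history[-1]['adv_d']:.4f}"
                )
            if (
                checkpoint_dir
                and checkpoint_every
                and (it + 1) % checkpoint_every == 0
            ):
                self.is_trained = True
                self.save(Path(checkpoint_dir) / f"iter_{it + 1:06d}")
        if iterations > 0:
            self.is_trained = True
        self.loss_history.extend(history)
        return history

    # -- augmentation ------------------------------------------------------
    def sample_augmentation(
        self,
        labeled: LabeledImage,
        rng: np.random.Generator,
        target_domain: Optional[int] = None,
        exclude_source: bool = False,
    ) -> LabeledImage:
        """Resample style and domain while keeping content (and mask) fixed.

        The content code of the input is preserved; the attribute code is
        drawn from the prior N(0, I) and the target domain uniformly (unless
        given).  The returned image carries a bit-identical copy of the
        input's instance mask.
        """
        if not self.is_trained:
            raise RuntimeError("style model is untrained; call train() first")
        z_c = self.encode_content(labeled.pixels)
        z_a = rng.standard_normal(self.config.n_attr)
        if target_domain is None:
            choices = list(range(self.config.n_domains))
            if exclude_source and labeled.domain_id in choices and len(choices) > 1:
                choices.remove(labeled.domain_id)
            target_domain = int(rng.choice(choices))
        pixels = self.generate(z_c, z_a, target_domain)
        return LabeledImage(
            pixels=pixels,
            instance_mask=labeled.instance_mask.copy(),
            domain_id=target_domain,
            image_id=f"{labeled.image_id}_aug",
        )

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["weights"] = asdict(self.config.weights)
        cfg["is_trained"] = self.is_trained
        with open(directory / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1)
        state = {}
        for prefix, net in self._nets().items():
            for name, arr in net.state_dict().items():
                state[f"{prefix}.{name}"] = arr
        np.savez(directory / "weights.npz", **state)

    def _nets(self):
        return {
            "Ec": self.Ec, "Ea": self.Ea, "G": self.G,
            "D_dom": self.D_dom, "D_con": self.D_con,
        }

    @classmethod
    def load(cls, directory, n_domains: Optional[int] = None) -> "StyleModel":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            cfg = json.load(fh)
        trained = cfg.pop("is_trained", False)
        cfg["weights"] = LossWeights(**cfg["weights"])
        cfg["betas"] = tuple(cfg["betas"])
        config = StyleConfig(**cfg)
        if n_domains is not None and n_domains != config.n_domains:
            raise ValueError(
                f"checkpoint has {config.n_domains} domains, expected {n_domains}"
            )
        model = cls(config)
        state = np.load(directory / "weights.npz")
        for prefix, net in model._nets().items():
            sub = {
                k[len(prefix) + 1 :]: state[k]
                for k in state.files
                if k.startswith(prefix + ".")
            }
            net.load_state_dict(sub)
        model.is_trained = trained
        return model
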