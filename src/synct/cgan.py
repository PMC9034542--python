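"""Conditional-GAN image translation: densely connected encoder-decoder
generator, patch discriminator, adversarial + L1 objective, training loop.

The generator is a 2-D fully convolutional DenseNet: a stem convolution,
five dense-block / transition-down stages whose dense-block outputs are
kept as skip paths, a bottleneck dense block, and five transition-up /
dense-block stages that concatenate the skips back in, ending in a
1 x 1 convolution with a tanh onto the normalized intensity range.  The
discriminator is a PatchGAN judging (input, candidate) channel pairs
through four strided down-transitions into a sigmoid patch map.

The objective is the pix2pix form: the generator minimizes a
non-saturating adversarial term plus ``lambda_l1`` (default 100) times
the mean absolute error against the real target, making training close
to supervised regression with an adversarial regularizer.  Default
schedule: batch 4, Adam for G at 2e-4, SGD for D at 2e-5, 200 epochs
with the checkpoint chosen by lowest validation L1.

``CGANTranslator`` wraps all of this as a scikit-learn estimator
(``fit(X, y)`` / ``predict(X)`` on stacks of normalized 2-D slices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .core import CTVolume
from .preprocess import (
    PreprocessConfig,
    denormalize_array,
    normalize_array,
    pad_to_multiple,
    random_crop_pair,
)

_EPS = 1e-6


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class GeneratorConfig:
    """Depths and growth rate of the dense encoder-decoder.

    The default values are calibrated so the built network carries 5.4 M
    trainable parameters (see ``default_generator_config``).
    """

    n_transitions: int = 5
    layers_per_block: tuple[int, ...] = (4, 5, 7, 10, 12)
    bottleneck_layers: int = 15
    growth_rate: int = 12
    initial_features: int = 48
    dropout_rate: float = 0.2

    def __post_init__(self):
        if len(self.layers_per_block) != self.n_transitions:
            raise ValueError("layers_per_block must list one count per transition")
        if min(self.layers_per_block) < 1 or self.growth_rate < 1 \
                or self.initial_features < 1 or self.bottleneck_layers < 1:
            raise ValueError("all architecture counts must be positive")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """PatchGAN widths; defaults calibrated to 1.6 M trainable parameters."""

    n_transitions: int = 4
    base_features: int = 48
    patch_output: bool = True

    def __post_init__(self):
        if self.n_transitions < 1 or self.base_features < 1:
            raise ValueError("architecture counts must be positive")


@dataclass(frozen=True)
class TrainConfig:
    lambda_l1: float = 100.0
    batch_size: int = 4
    epochs: int = 200
    lr_g: float = 2e-4
    lr_d: float = 2e-5
    adam_betas: tuple[float, float] = (0.5, 0.999)
    lr_decay: bool = True     # linear decay to 0 over the last half of training
    train_crop: int | None = 352
    seed: int = 0

    def __post_init__(self):
        for name in ("lambda_l1", "batch_size", "epochs", "lr_g", "lr_d"):
            if getattr(self, name) < 0 or (name != "lambda_l1" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


def default_generator_config() -> GeneratorConfig:
    return GeneratorConfig()


def default_discriminator_config() -> DiscriminatorConfig:
    return DiscriminatorConfig()


def small_generator_config() -> GeneratorConfig:
    """Desk-scale config for CPU training runs on phantoms."""
    return GeneratorConfig(layers_per_block=(2, 2, 2, 2, 2),
                           bottleneck_layers=2, growth_rate=8,
                           initial_features=16, dropout_rate=0.0)


def small_discriminator_config() -> DiscriminatorConfig:
    return DiscriminatorConfig(base_features=8)


def desk_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    """Training schedule for desk-scale phantom runs.

    A smaller network tolerates (and needs) a larger step size than the
    clinical schedule; the linear decay over the second half keeps the
    adversarial game from destabilising late epochs.  Full slices are
    used (no random crop) since phantom ROIs are already small.
    """
    return TrainConfig(epochs=epochs, lr_g=2e-3, adam_betas=(0.9, 0.999),
                       lr_decay=True, train_crop=None, seed=seed)


# ------------------------------------------------------------------- networks
class _DenseLayer(nn.Module):
    def __init__(self, cin, growth, dropout, rng):
        super().__init__()
        self.bn = nn.BatchNorm2d(cin)
        self.conv = nn.Conv2d(cin, growth, 3, rng, padding=1)
        self.drop = nn.Dropout(dropout, rng) if dropout > 0 else None

    def forward(self, x):
        h = self.conv(self.bn(x).relu())
        return self.drop(h) if self.drop is not None else h


class _DenseBlock(nn.Module):
    """Each layer sees the concatenation of the block input and all
    previous layers' outputs; produces ``n_layers * growth`` new maps."""

    def __init__(self, cin, n_layers, growth, dropout, rng):
        super().__init__()
        self.layers = [
            _DenseLayer(cin + i * growth, growth, dropout, rng)
            for i in range(n_layers)
        ]
        self.out_new = n_layers * growth
        self.out_full = cin + self.out_new

    def forward(self, x):
        feats = [x]
        new = []
        for layer in self.layers:
            h = layer(nn.concat(feats) if len(feats) > 1 else feats[0])
            feats.append(h)
            new.append(h)
        return nn.concat(feats), (nn.concat(new) if len(new) > 1 else new[0])


class _TransitionDown(nn.Module):
    def __init__(self, channels, dropout, rng):
        super().__init__()
        self.bn = nn.BatchNorm2d(channels)
        self.conv = nn.Conv2d(channels, channels, 1, rng)
        self.drop = nn.Dropout(dropout, rng) if dropout > 0 else None
        self.pool = nn.MaxPool2d(2)

    def forward(self, x):
        h = self.conv(self.bn(x).relu())
        if self.drop is not None:
            h = self.drop(h)
        return self.pool(h)


class FCDenseNetGenerator(nn.Module):
    """Fully convolutional dense encoder-decoder, 1 channel in/out."""

    def __init__(self, config: GeneratorConfig, rng):
        super().__init__()
        self.config = config
        g, drop = config.growth_rate, config.dropout_rate
        self.stem = nn.Conv2d(1, config.initial_features, 3, rng, padding=1)

        c = config.initial_features
        self.down_blocks, self.downs, self.skip_channels = [], [], []
        for n_layers in config.layers_per_block:
            block = _DenseBlock(c, n_layers, g, drop, rng)
            self.down_blocks.append(block)
            c = block.out_full
            self.skip_channels.append(c)
            self.downs.append(_TransitionDown(c, drop, rng))

        self.bottleneck = _DenseBlock(c, config.bottleneck_layers, g, drop, rng)
        m = self.bottleneck.out_new

        self.ups, self.up_blocks = [], []
        for i, n_layers in enumerate(reversed(config.layers_per_block)):
            self.ups.append(nn.ConvTranspose2d(m, m, 3, rng, stride=2,
                                               padding=1, output_padding=1))
            cin = m + self.skip_channels[-(i + 1)]
            block = _DenseBlock(cin, n_layers, g, drop, rng)
            self.up_blocks.append(block)
            m = block.out_new
            last_full = block.out_full
        self.head = nn.Conv2d(last_full, 1, 1, rng)

    def forward(self, x):
        self._check_input(x)
        h = self.stem(x)
        skips = []
        for block, down in zip(self.down_blocks, self.downs):
            full, _ = block(h)
            skips.append(full)
            h = down(full)
        _, h = self.bottleneck(h)
        for i, (up, block) in enumerate(zip(self.ups, self.up_blocks)):
            h = up(h)
            full, new = block(nn.concat([h, skips[-(i + 1)]]))
            h = full if i == len(self.ups) - 1 else new
        return self.head(h).tanh()

    def _check_input(self, x):
        div = 2 ** self.config.n_transitions
        _, c, hh, ww = x.data.shape
        if c != 1:
            raise ValueError(f"generator expects 1-channel input, got {c}")
        if hh % div or ww % div:
            raise ValueError(
                f"input spatial size {(hh, ww)} must be divisible by {div} "
                f"(= 2^{self.config.n_transitions} down/up transitions); "
                f"pad the slice symmetrically to the next multiple")


class PatchDiscriminator(nn.Module):
    """Two-channel (input, candidate) PatchGAN with a sigmoid patch map."""

    def __init__(self, config: DiscriminatorConfig, rng):
        super().__init__()
        self.config = config
        f = config.base_features
        layers = [nn.Conv2d(2, f, 4, rng, stride=2, padding=1),
                  nn.LeakyReLU(0.2)]
        c = f
        for _ in range(config.n_transitions - 1):
            layers += [nn.Conv2d(c, 2 * c, 4, rng, stride=2, padding=1),
                       nn.BatchNorm2d(2 * c), nn.LeakyReLU(0.2)]
            c *= 2
        layers += [nn.Conv2d(c, 1, 4, rng, stride=1, padding=1)]
        self.body = nn.Sequential(*layers)

    def forward(self, x):
        if x.data.shape[1] != 2:
            raise ValueError(
                f"discriminator expects 2-channel (input, candidate) pairs, "
                f"got {x.data.shape[1]} channels")
        return self.body(x).sigmoid()


def build_generator(config: GeneratorConfig | None = None, seed: int = 0):
    rng = np.random.default_rng(seed)
    return FCDenseNetGenerator(config or default_generator_config(), rng)


def build_discriminator(config: DiscriminatorConfig | None = None, seed: int = 0):
    rng = np.random.default_rng(seed)
    return PatchDiscriminator(config or default_discriminator_config(), rng)


def count_parameters(network) -> int:
    """Number of trainable scalars (frozen parameters excluded)."""
    return sum(p.data.size for p in network.parameters() if p.requires_grad)


# --------------------------------------------------------------------- losses
def _bce(prob, label: float):
    """Binary cross-entropy of a probability map against a constant label."""
    p = prob.clip(_EPS, 1.0 - _EPS)
    if label == 1.0:
        return -(p.log().mean())
    if label == 0.0:
        return -((1.0 - p).log().mean())
    return -((label * p.log()) + ((1.0 - label) * (1.0 - p).log())).mean()


def generator_loss(d_fake, pred, target, lambda_l1: float = 100.0):
    """Non-saturating adversarial term + lambda * L1, with components.

    Returns ``(total, components)`` where components maps ``adversarial``
    and ``l1`` to their scalar values; ``total = adversarial +
    lambda_l1 * l1`` exactly.
    """
    if pred.data.shape != target.data.shape:
        raise ValueError("pred/target shape mismatch")
    adv = _bce(d_fake, 1.0)
    l1 = (pred - target).abs().mean()
    total = adv + nn.Tensor(np.float32(lambda_l1)) * l1
    return total, {"adversarial": float(adv.data), "l1": float(l1.data)}


def discriminator_loss(d_real, d_fake):
    """BCE(d_real, 1) + BCE(d_fake, 0), patch-averaged."""
    return _bce(d_real, 1.0) + _bce(d_fake, 0.0)


# ------------------------------------------------------------------ estimator
class CGANTranslator(BaseEstimator):
    """Conditional-GAN slice translator with the scikit-learn interface.

    Parameters mirror the training schedule; ``fit`` expects stacks of
    normalized axial slices ``X`` (input modality) and ``y`` (target
    modality) of shape ``(n_slices, H, W)`` with values in the model
    range.  ``predict`` translates slices deterministically (dropout
    off, batch-norm in inference mode, best-validation weights).
    """

    def __init__(self, g_config=None, d_config=None, lambda_l1=100.0,
                 batch_size=4, epochs=200, lr_g=2e-4, lr_d=2e-5,
                 adam_betas=(0.5, 0.999), lr_decay=True, train_crop=None,
                 seed=0, verbose=False):
        self.g_config = g_config
        self.d_config = d_config
        self.lambda_l1 = lambda_l1
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_g = lr_g
        self.lr_d = lr_d
        self.adam_betas = adam_betas
        self.lr_decay = lr_decay
        self.train_crop = train_crop
        self.seed = seed
        self.verbose = verbose

    # ---------------------------------------------------------------- fitting
    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must be (n_slices, H, W) and match")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if validation_data is not None:
            Xv = np.asarray(validation_data[0], dtype=np.float32)
            yv = np.asarray(validation_data[1], dtype=np.float32)
            if Xv.shape[0] == 0:
                raise ValueError("empty validation set")
        else:
            Xv = yv = None

        rng = np.random.default_rng(self.seed)
        g_cfg = self.g_config or small_generator_config()
        d_cfg = self.d_config or small_discriminator_config()
        gen = FCDenseNetGenerator(g_cfg, rng)
        disc = PatchDiscriminator(d_cfg, rng)
        opt_g = nn.Adam(gen.parameters(), self.lr_g, betas=tuple(self.adam_betas))
        opt_d = nn.SGD(disc.parameters(), self.lr_d)

        n = X.shape[0]
        hist = {"epoch": [], "g_loss": [], "g_adv": [], "g_l1": [],
                "d_loss": [], "val_l1": []}
        best = (np.inf, None, -1)

        for epoch in range(1, self.epochs + 1):
            if self.lr_decay:
                half = self.epochs // 2
                frac = 1.0 if epoch <= half else \
                    max(0.05, (self.epochs - epoch + 1) / (self.epochs - half))
                opt_g.lr = self.lr_g * frac
                opt_d.lr = self.lr_d * frac
            gen.train(), disc.train()
            order = rng.permutation(n)
            ep = {"g": [], "adv": [], "l1": [], "d": []}
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = self._make_batch(X[idx], y[idx], rng)

                # --- discriminator step (detached fake)
                xt = nn.Tensor(xb)
                fake = gen(xt)
                fake_detached = nn.Tensor(fake.data.copy())
                d_real = disc(nn.concat([nn.Tensor(xb), nn.Tensor(yb)]))
                d_fake = disc(nn.concat([nn.Tensor(xb), fake_detached]))
                d_loss = discriminator_loss(d_real, d_fake)
                gen.zero_grad(), disc.zero_grad()
                d_loss.backward()
                opt_d.step()

                # --- generator step (reuses the forward graph; D freshly applied)
                d_fake = disc(nn.concat([xt, fake]))
                g_loss, comp = generator_loss(d_fake, fake, nn.Tensor(yb),
                                              self.lambda_l1)
                gen.zero_grad(), disc.zero_grad()
                g_loss.backward()
                nn.clip_grad_norm(gen.parameters(), 1.0)
                opt_g.step()

                if not np.isfinite(float(g_loss.data)) or \
                        not np.isfinite(float(d_loss.data)):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch} "
                        f"(g_loss={float(g_loss.data)}, d_loss={float(d_loss.data)})")
                ep["g"].append(float(g_loss.data))
                ep["adv"].append(comp["adversarial"])
                ep["l1"].append(comp["l1"])
                ep["d"].append(float(d_loss.data))

            val_l1 = self._validation_l1(gen, Xv, yv) if Xv is not None else np.nan
            hist["epoch"].append(epoch)
            hist["g_loss"].append(float(np.mean(ep["g"])))
            hist["g_adv"].append(float(np.mean(ep["adv"])))
            hist["g_l1"].append(float(np.mean(ep["l1"])))
            hist["d_loss"].append(float(np.mean(ep["d"])))
            hist["val_l1"].append(float(val_l1))
            if self.verbose:
                print(f"epoch {epoch:3d}  g={hist['g_loss'][-1]:.4f} "
                      f"d={hist['d_loss'][-1]:.4f} val_l1={val_l1:.4f}")
            if Xv is not None and val_l1 < best[0]:
                best = (val_l1, gen.state_dict(), epoch)

        if best[1] is not None:
            gen.load_state_dict(best[1])
            self.best_epoch_ = best[2]
            self.best_val_l1_ = best[0]
        else:
            self.best_epoch_ = self.epochs
            self.best_val_l1_ = np.nan
        self.generator_ = gen.eval()
        self.discriminator_ = disc.eval()
        self.history_ = hist
        self.n_epochs_ = self.epochs
        return self

    def _make_batch(self, xb, yb, rng):
        crop = self.train_crop
        if crop is None or crop >= min(xb.shape[1:]):
            return xb[:, None], yb[:, None]
        xs, ys = [], []
        for i in range(xb.shape[0]):
            xc, yc, _ = random_crop_pair(xb[i], yb[i], crop, rng)
            xs.append(xc)
            ys.append(yc)
        return np.stack(xs)[:, None], np.stack(ys)[:, None]

    def _validation_l1(self, gen, Xv, yv):
        gen.eval()
        errs = []
        for i in range(Xv.shape[0]):
            pred = self._predict_slice(gen, Xv[i])
            errs.append(float(np.abs(pred - yv[i]).mean()))
        gen.train()
        return float(np.mean(errs))

    # -------------------------------------------------------------- inference
    def _predict_slice(self, gen, slice2d):
        padded, undo = pad_to_multiple(slice2d, 2 ** gen.config.n_transitions,
                                       value=float(slice2d.min()))
        out = gen(nn.Tensor(padded[None, None]))
        return out.data[0, 0][undo]

    def predict(self, X):
        if not hasattr(self, "generator_"):
            raise RuntimeError("CGANTranslator is not fitted; call fit() first")
        X = np.asarray(X, dtype=np.float32)
        self.generator_.eval()
        return np.stack([self._predict_slice(self.generator_, X[i])
                         for i in range(X.shape[0])])


# -------------------------------------------------------- module-level facade
@dataclass
class TrainedModel:
    """Fitted translator plus its configuration and training history."""

    estimator: CGANTranslator
    g_config: GeneratorConfig
    d_config: DiscriminatorConfig
    t_config: TrainConfig

    @property
    def history(self):
        return self.estimator.history_

    def save(self, prefix: str):
        np.savez_compressed(prefix + ".npz",
                            *self.estimator.generator_.state_dict())
        sidecar = {
            "g_config": asdict(self.g_config),
            "d_config": asdict(self.d_config),
            "t_config": asdict(self.t_config),
            "best_epoch": int(self.estimator.best_epoch_),
            "best_val_l1": float(self.estimator.best_val_l1_),
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, prefix: str):
        with open(prefix + ".json") as fh:
            sidecar = json.load(fh)
        g_cfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in sidecar["g_config"].items()})
        d_cfg = DiscriminatorConfig(**sidecar["d_config"])
        t_cfg = TrainConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in sidecar["t_config"].items()})
        est = CGANTranslator(g_config=g_cfg, d_config=d_cfg,
                             lambda_l1=t_cfg.lambda_l1, seed=t_cfg.seed)
        gen = build_generator(g_cfg, seed=t_cfg.seed)
        with np.load(prefix + ".npz") as zf:
            gen.load_state_dict([zf[k] for k in zf.files])
        est.generator_ = gen.eval()
        est.history_ = {}
        est.best_epoch_ = sidecar["best_epoch"]
        est.best_val_l1_ = sidecar["best_val_l1"]
        return cls(est, g_cfg, d_cfg, t_cfg)


def train(train_slices, val_slices, g_cfg: GeneratorConfig | None = None,
          d_cfg: DiscriminatorConfig | None = None,
          t_cfg: TrainConfig | None = None, verbose=False) -> TrainedModel:
    """Fit the translator on (input, target) normalized slice stacks.

    ``train_slices`` / ``val_slices`` are ``(X, y)`` tuples of arrays
    shaped (n_slices, H, W).
    """
    g_cfg = g_cfg or default_generator_config()
    d_cfg = d_cfg or default_discriminator_config()
    t_cfg = t_cfg or TrainConfig()
    est = CGANTranslator(
        g_config=g_cfg, d_config=d_cfg, lambda_l1=t_cfg.lambda_l1,
        batch_size=t_cfg.batch_size, epochs=t_cfg.epochs, lr_g=t_cfg.lr_g,
        lr_d=t_cfg.lr_d, adam_betas=t_cfg.adam_betas,
        lr_decay=t_cfg.lr_decay, train_crop=t_cfg.train_crop, seed=t_cfg.seed,
        verbose=verbose)
    est.fit(train_slices[0], train_slices[1], validation_data=val_slices)
    return TrainedModel(est, g_cfg, d_cfg, t_cfg)


def infer_volume(model: TrainedModel, nct: CTVolume,
                 preprocess_cfg: PreprocessConfig,
                 center=None, heart_mask=None) -> CTVolume:
    """Translate a full NCT volume into SCECT.

    Axial slices inside the heart ROI are windowed, normalized,
    translated and denormalized back to HU; the result is embedded into
    a copy of the NCT, so voxels outside the ROI stay bit-identical.
    """
    from .ct_io import embed_roi
    from .preprocess import heart_roi_center

    if center is None:
        center = heart_roi_center(nct, heart_mask)
    shape = nct.voxels.shape
    size = tuple(min(r, s) for r, s in zip(preprocess_cfg.roi_size, shape))
    start = tuple(int(np.clip(c - sz // 2, 0, sh - sz))
                  for c, sz, sh in zip(center, size, shape))
    box = tuple(slice(o, o + s) for o, s in zip(start, size))
    roi_hu = nct.voxels[box]
    roi_norm = normalize_array(roi_hu, preprocess_cfg)

    est = model.estimator
    slices = np.moveaxis(roi_norm, 2, 0)  # (nz, nx, ny)
    pred = est.predict(slices)
    pred_hu = denormalize_array(np.moveaxis(pred, 0, 2), preprocess_cfg)

    from .core import CTVolume as _CTV, Grid as _Grid
    patch_grid = _Grid(size, nct.grid.spacing,
                       tuple(nct.grid.origin[a] + start[a] * nct.grid.spacing[a]
                             for a in range(3)))
    return embed_roi(nct, _CTV(pred_hu, patch_grid), start)
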