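"""Classifier-regularized convolutional VAE.

The network maps a triplet of binary silhouette projections (3 channels of one
square image) through a strided convolutional encoder to a low-dimensional
Gaussian posterior (mu, log sigma^2), samples a latent vector by
reparameterization, and feeds it to (a) a transposed-convolution decoder that
emits a logistic-activated image of the same geometry and (b) a single affine
softmax layer for class prediction.  The training objective is

    e_total = (1 - alpha) * (e_rec + e_reg) + alpha * e_c

with binary cross-entropy reconstruction, closed-form diagonal-Gaussian KL
against N(0, I), and label cross-entropy scaled by 1/n_classes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ShapeError

EPS_CLIP = 1e-7

__all__ = [
    "ModelConfig",
    "LatentCode",
    "LabelVector",
    "LossBreakdown",
    "MorphoVAE",
    "compute_losses",
    "kl_standard_normal",
    "binary_cross_entropy",
    "one_hot",
]


@dataclass
class ModelConfig:
    n_classes: int
    alpha: float = 0.1
    latent_dim: int = 3
    encoder_filters: list[int] = field(default_factory=lambda: [128, 128, 32, 32, 64])
    decoder_filters: list[int] = field(default_factory=lambda: [64, 32, 32, 128, 128])
    activation: str = "relu"
    optimizer: str = "rmsprop"
    epochs: int = 100
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    image_size: int = 128
    kernel_size: int = 3
    n_channels: int = 3
    # Training-time balance of the objective's terms.  The printed loss
    # (mean-per-pixel BCE plus an unweighted latent KL) makes encoding any
    # information cost more regularization than it can recover in
    # reconstruction, which collapses the posterior; the weights below rescale
    # the KL and classification *gradients* so training behaves, while every
    # reported LossBreakdown keeps the stated formulas untouched.
    reg_weight: float = 0.01
    class_weight: float | None = None  # None -> n_classes (cancels the 1/K)

    def validate(self) -> "ModelConfig":
        if self.reg_weight <= 0:
            raise ValueError("reg_weight must be positive")
        if self.class_weight is not None and self.class_weight <= 0:
            raise ValueError("class_weight must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.encoder_filters) != len(self.decoder_filters):
            raise ValueError("encoder and decoder must have the same number of layers")
        if not 1 <= len(self.encoder_filters) <= 6:
            raise ValueError("number of layers must be in 1..6")
        if any(f <= 0 for f in self.encoder_filters + self.decoder_filters):
            raise ValueError("filter counts must be positive")
        if self.activation not in ("relu", "sigmoid", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.optimizer.lower() not in ("sgd", "adam", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        n_layers = len(self.encoder_filters)
        if self.image_size % (2**n_layers) != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by 2^{n_layers}"
            )
        return self

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d).validate()


@dataclass
class LatentCode:
    """Encoder output: posterior mean, log-variance and a sampled latent."""

    mu: np.ndarray
    log_var: np.ndarray
    zeta: np.ndarray


@dataclass
class LabelVector:
    y: np.ndarray
    y_prime: np.ndarray


@dataclass
class LossBreakdown:
    e_rec: float
    e_reg: float
    e_c: float
    e_vae: float
    e_total: float

    @classmethod
    def from_components(cls, e_rec: float, e_reg: float, e_c: float, alpha: float):
        e_vae = e_rec + e_reg
        return cls(
            e_rec=float(e_rec),
            e_reg=float(e_reg),
            e_c=float(e_c),
            e_vae=float(e_vae),
            e_total=float((1.0 - alpha) * e_vae + alpha * e_c),
        )

    def check(self, alpha: float, atol: float = 1e-9) -> None:
        assert abs(self.e_vae - (self.e_rec + self.e_reg)) <= atol * max(1.0, abs(self.e_vae))
        expected = (1.0 - alpha) * self.e_vae + alpha * self.e_c
        assert abs(self.e_total - expected) <= atol * max(1.0, abs(expected))
        assert self.e_rec >= 0 and self.e_reg >= -1e-12 and self.e_c >= 0


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float64)
    out[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    return out


def binary_cross_entropy(p: np.ndarray, q: np.ndarray) -> float:
    """Mean-per-pixel BCE between target ``p`` and prediction ``q``.

    ``q`` is clipped to [EPS_CLIP, 1 - EPS_CLIP] before the logs.  For batched
    input the per-sample losses are averaged.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.clip(np.asarray(q, dtype=np.float64), EPS_CLIP, 1.0 - EPS_CLIP)
    if p.shape != q.shape:
        raise ShapeError(f"p {p.shape} vs q {q.shape}")
    per_elem = -(p * np.log(q) + (1.0 - p) * np.log(1.0 - q))
    return float(per_elem.mean())


def kl_standard_normal(mu: np.ndarray, log_var: np.ndarray) -> float:
    """Closed-form D_KL(N(mu, sigma^2) || N(0, 1)), summed over latent dims.

    For batched input the per-sample divergences are averaged.
    """
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    if mu.shape != log_var.shape:
        raise ShapeError(f"mu {mu.shape} vs log_var {log_var.shape}")
    per = 0.5 * (mu**2 + np.exp(log_var) - log_var - 1.0)
    if per.ndim == 1:
        return float(per.sum())
    return float(per.sum(axis=-1).mean())


def compute_losses(
    p: np.ndarray,
    q: np.ndarray,
    code: LatentCode,
    labels: LabelVector,
    alpha: float,
) -> LossBreakdown:
    """Assemble the full loss breakdown from raw tensors (no network needed)."""
    e_rec = binary_cross_entropy(p, q)
    e_reg = kl_standard_normal(code.mu, code.log_var)
    y = np.asarray(labels.y, dtype=np.float64)
    yp = np.clip(np.asarray(labels.y_prime, dtype=np.float64), EPS_CLIP, 1.0)
    if y.shape != yp.shape:
        raise ShapeError(f"y {y.shape} vs y_prime {yp.shape}")
    n_classes = y.shape[-1]
    per = -(y * np.log(yp)).sum(axis=-1) / n_classes
    e_c = float(np.mean(per))
    return LossBreakdown.from_components(e_rec, e_reg, e_c, alpha)


class MorphoVAE:
    """The network plus its manual backward pass.

    Parameters live in float32; the public ``encode``/``decode``/``classify``
    API returns float64 so downstream metrics are well conditioned.
    """

    def __init__(self, config: ModelConfig):
        self.config = config.validate()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
        c = config
        self.n_layers = len(c.encoder_filters)
        self.base_size = c.image_size // (2**self.n_layers)
        act = c.activation

        enc_layers: list[nn.Layer] = []
        self._conv_names: list[str] = []
        prev = c.n_channels
        spatial = c.image_size
        self._conv_spatial: list[int] = []
        for i, f in enumerate(c.encoder_filters):
            enc_layers.append(nn.Conv2d(prev, f, rng, k=c.kernel_size))
            enc_layers.append(nn.make_activation(act))
            spatial //= 2
            self._conv_names.append(f"enc_conv_{i}")
            self._conv_spatial.append(spatial)
            prev = f
        enc_layers.append(nn.Flatten())
        feat = prev * self.base_size * self.base_size
        enc_layers.append(nn.Dense(feat, 2 * c.latent_dim, rng, gain=1.0))
        self.encoder = nn.Sequential(enc_layers)

        dec_layers: list[nn.Layer] = []
        d0 = c.decoder_filters[0]
        dec_layers.append(nn.Dense(c.latent_dim, d0 * self.base_size * self.base_size, rng))
        dec_layers.append(nn.make_activation(act))
        dec_layers.append(nn.Reshape((d0, self.base_size, self.base_size)))
        prev = d0
        for f in c.decoder_filters[1:]:
            dec_layers.append(nn.ConvTranspose2d(prev, f, rng, k=c.kernel_size))
            dec_layers.append(nn.make_activation(act))
            prev = f
        # final upsample straight to image channels; logistic applied downstream
        dec_layers.append(nn.ConvTranspose2d(prev, c.n_channels, rng, k=c.kernel_size, gain=1.0))
        self.decoder = nn.Sequential(dec_layers)

        self.classifier = nn.Sequential([nn.Dense(c.latent_dim, c.n_classes, rng, gain=1.0)])

    # ------------------------------------------------------------------ utils
    @property
    def scorecam_layer_name(self) -> str:
        """Name of the conv layer whose activation feeds Score-CAM (8x8 map
        when the geometry allows, otherwise the last conv layer)."""
        for name, s in zip(self._conv_names, self._conv_spatial):
            if s == 8:
                candidate = name
        try:
            return candidate  # last one with spatial size 8
        except UnboundLocalError:
            return self._conv_names[-1]

    def _check_images(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        c, s = self.config.n_channels, self.config.image_size
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != (c, s, s):
            raise ShapeError(f"expected (*, {c}, {s}, {s}) images, got {x.shape}")
        return np.ascontiguousarray(x, dtype=np.float32)

    def param_items(self):
        for prefix, net in (("enc", self.encoder), ("dec", self.decoder), ("cls", self.classifier)):
            for key, p, g in net.param_items():
                yield f"{prefix}/{key}", p, g

    def get_weights(self) -> dict[str, np.ndarray]:
        return {key: p.copy() for key, p, _ in self.param_items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, p, _ in self.param_items():
            p[...] = weights[key]

    def save(self, path) -> None:
        arrays = {f"param:{k}": v for k, v in self.get_weights().items()}
        arrays["config_json"] = np.frombuffer(self.config.to_json().encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MorphoVAE":
        with np.load(path) as data:
            cfg = ModelConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg)
            model.set_weights(
                {k[len("param:") :]: data[k] for k in data.files if k.startswith("param:")}
            )
        return model

    # ------------------------------------------------------------------ API
    def encode(
        self,
        x: np.ndarray,
        mode: str = "deterministic",
        seed: int | None = None,
        n_draws: int = 1,
    ) -> LatentCode:
        """Map images to a :class:`LatentCode`.

        Deterministic mode sets zeta = mu; stochastic mode draws
        zeta ~ N(mu, sigma) with the given seed.  With ``n_draws > 1`` the
        zeta array gains a leading draw axis.
        """
        single = np.asarray(x).ndim == 3
        xb = self._check_images(x)
        out = self.encoder.forward(xb).astype(np.float64)
        L = self.config.latent_dim
        mu, log_var = out[:, :L], out[:, L:]
        if mode == "deterministic":
            zeta = np.repeat(mu[None], n_draws, axis=0) if n_draws > 1 else mu.copy()
        elif mode == "stochastic":
            rng = np.random.default_rng(seed)
            eps = rng.standard_normal((n_draws,) + mu.shape)
            zeta = mu[None] + np.exp(0.5 * log_var)[None] * eps
            if n_draws == 1:
                zeta = zeta[0]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if single:
            mu, log_var = mu[0], log_var[0]
            zeta = zeta[..., 0, :] if n_draws > 1 else zeta[0]
        return LatentCode(mu=mu, log_var=log_var, zeta=zeta)

    def decode(self, zeta: np.ndarray) -> np.ndarray:
        """Decode latent vector(s) to images with values strictly inside (0, 1)."""
        zeta = np.asarray(zeta, dtype=np.float64)
        if not np.all(np.isfinite(zeta)):
            raise ValueError("zeta must be finite")
        single = zeta.ndim == 1
        zb = np.atleast_2d(zeta).astype(np.float32)
        if zb.shape[1] != self.config.latent_dim:
            raise ShapeError(f"expected latent dim {self.config.latent_dim}, got {zb.shape[1]}")
        logits = self.decoder.forward(zb).astype(np.float64)
        q = np.clip(nn.sigmoid(logits), EPS_CLIP, 1.0 - EPS_CLIP)
        return q[0] if single else q

    def classifier_logits(self, zeta: np.ndarray) -> np.ndarray:
        zeta = np.asarray(zeta, dtype=np.float64)
        if not np.all(np.isfinite(zeta)):
            raise ValueError("zeta must be finite")
        single = zeta.ndim == 1
        zb = np.atleast_2d(zeta).astype(np.float32)
        logits = self.classifier.forward(zb).astype(np.float64)
        return logits[0] if single else logits

    def classify(self, zeta: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for latent vector(s)."""
        return nn.softmax(self.classifier_logits(zeta), axis=-1)

    def predict_probs(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic encode -> classify over a batch of images."""
        xb = self._check_images(x)
        chunks = [
            self.classify(self.encode(xb[i : i + batch_size]).mu)
            for i in range(0, len(xb), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def reconstruct(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """decode(encode(x, deterministic)) over a batch of images."""
        xb = self._check_images(x)
        chunks = [
            self.decode(self.encode(xb[i : i + batch_size]).mu)
            for i in range(0, len(xb), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def conv_activations(self, x: np.ndarray, layer_name: str | None = None) -> np.ndarray:
        """Post-activation feature maps of the named encoder conv layer."""
        name = layer_name or self.scorecam_layer_name
        idx = self._conv_names.index(name)
        xb = self._check_images(x)
        out = xb
        # encoder layers alternate conv/activation until the flatten
        for i in range(idx + 1):
            out = self.encoder.layers[2 * i].forward(out)
            out = self.encoder.layers[2 * i + 1].forward(out)
        return out.astype(np.float64)

    # ------------------------------------------------------------- training
    def objective(self, losses: LossBreakdown, alpha: float | None = None) -> float:
        """Value of the surrogate actually minimized by training."""
        alpha = self.config.alpha if alpha is None else float(alpha)
        beta = self.config.reg_weight
        gamma = (
            self.config.class_weight
            if self.config.class_weight is not None
            else float(self.config.n_classes)
        )
        return (1.0 - alpha) * (losses.e_rec + beta * losses.e_reg) + alpha * gamma * losses.e_c

    def train_step(
        self,
        x: np.ndarray,
        y_onehot: np.ndarray,
        optimizer: "nn.optim.Optimizer",
        rng: np.random.Generator,
        alpha: float | None = None,
    ) -> LossBreakdown:
        """One minibatch forward/backward/update; returns the batch losses."""
        alpha = self.config.alpha if alpha is None else float(alpha)
        xb = self._check_images(x)
        yb = np.asarray(y_onehot, dtype=np.float32)
        n = xb.shape[0]
        L = self.config.latent_dim
        dim = float(np.prod(xb.shape[1:]))
        K = float(self.config.n_classes)

        enc_out = self.encoder.forward(xb)
        mu, lv = enc_out[:, :L], enc_out[:, L:]
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        sig = np.exp(0.5 * lv)
        zeta = mu + sig * eps

        dec_logits = self.decoder.forward(zeta)
        q32 = nn.sigmoid(dec_logits)
        cls_logits = self.classifier.forward(zeta)
        probs32 = nn.softmax(cls_logits, axis=-1)

        losses = compute_losses(
            xb.astype(np.float64),
            q32.astype(np.float64),
            LatentCode(mu.astype(np.float64), lv.astype(np.float64), zeta.astype(np.float64)),
            LabelVector(yb.astype(np.float64), probs32.astype(np.float64)),
            alpha,
        )
        losses.check(alpha)

        # gradients of the batch-mean surrogate objective (see ModelConfig)
        beta = self.config.reg_weight
        gamma = self.config.class_weight if self.config.class_weight is not None else K
        d_dec = ((1.0 - alpha) / (dim * n)) * (q32 - xb)
        dzeta = self.decoder.backward(d_dec.astype(np.float32))
        d_cls = (alpha * gamma / (K * n)) * (probs32 - yb)
        dzeta = dzeta + self.classifier.backward(d_cls.astype(np.float32))
        dmu = dzeta + (beta * (1.0 - alpha) / n) * mu
        dlv = dzeta * eps * 0.5 * sig + (beta * (1.0 - alpha) / n) * 0.5 * (np.exp(lv) - 1.0)
        self.encoder.backward(np.concatenate([dmu, dlv], axis=1).astype(np.float32))

        optimizer.step(self.param_items())
        return losses

    def evaluate(
        self, x: np.ndarray, y_onehot: np.ndarray, alpha: float | None = None, batch_size: int = 64
    ) -> LossBreakdown:
        """Deterministic-mode losses (zeta = mu) averaged over the dataset."""
        alpha = self.config.alpha if alpha is None else float(alpha)
        xb = self._check_images(x)
        yb = np.asarray(y_onehot, dtype=np.float64)
        n = len(xb)
        sums = np.zeros(3)
        for i in range(0, n, batch_size):
            xs = xb[i : i + batch_size]
            code = self.encode(xs)
            q = self.decode(code.mu)
            probs = self.classify(code.mu)
            b = compute_losses(
                xs.astype(np.float64), q, code, LabelVector(yb[i : i + batch_size], probs), alpha
            )
            w = len(xs)
            sums += w * np.array([b.e_rec, b.e_reg, b.e_c])
        e_rec, e_reg, e_c = sums / n
        return LossBreakdown.from_components(e_rec, e_reg, e_c, alpha)
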