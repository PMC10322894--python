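"""Model contracts: encoding, decoding, classification and the loss forms."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from morphovae import (
    LabelVector,
    LatentCode,
    ModelConfig,
    MorphoVAE,
    compute_losses,
    kl_standard_normal,
    one_hot,
)
from morphovae.errors import ShapeError
from morphovae.nn import make_optimizer


def tiny_config(**overrides):
    base = dict(
        n_classes=3,
        encoder_filters=[4, 4, 8],
        decoder_filters=[8, 4, 4],
        image_size=32,
        seed=1,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def tiny_model():
    return MorphoVAE(tiny_config())


@pytest.fixture(scope="module")
def tiny_input():
    rng = np.random.default_rng(0)
    return (rng.random((3, 32, 32)) > 0.6).astype(np.float32)


# ------------------------------------------------------------------ encoding
def test_deterministic_zeta_equals_mu(tiny_model, tiny_input):
    code = tiny_model.encode(tiny_input, mode="deterministic")
    np.testing.assert_array_equal(code.zeta, code.mu)


def test_stochastic_seeded_reproducibility(tiny_model, tiny_input):
    a = tiny_model.encode(tiny_input, mode="stochastic", seed=42)
    b = tiny_model.encode(tiny_input, mode="stochastic", seed=42)
    np.testing.assert_array_equal(a.zeta, b.zeta)
    c = tiny_model.encode(tiny_input, mode="stochastic", seed=43)
    assert not np.array_equal(a.zeta, c.zeta)


def test_monte_carlo_mean_matches_mu(tiny_model, tiny_input):
    n = 10_000
    code = tiny_model.encode(tiny_input, mode="stochastic", seed=0, n_draws=n)
    assert code.zeta.shape == (n, 3)
    sigma = np.exp(0.5 * code.log_var)
    se = sigma / np.sqrt(n)
    assert np.all(np.abs(code.zeta.mean(axis=0) - code.mu) < 3 * se)


def test_wrong_geometry_raises(tiny_model):
    with pytest.raises(ShapeError):
        tiny_model.encode(np.zeros((3, 16, 16), dtype=np.float32))


# ------------------------------------------------------------------ decoding
def test_decode_range_strictly_inside_unit_interval(tiny_model):
    img = tiny_model.decode(np.zeros(3))
    assert img.shape == (3, 32, 32)
    assert np.all(img > 0.0) and np.all(img < 1.0)


def test_decode_rejects_nonfinite(tiny_model):
    with pytest.raises(ValueError):
        tiny_model.decode(np.array([np.nan, 0.0, 0.0]))


def test_decode_continuity(tiny_model):
    rng = np.random.default_rng(7)
    z = rng.standard_normal(3)
    a = tiny_model.decode(z)
    b = tiny_model.decode(z + 1e-6)
    assert np.abs(a - b).max() < 1e-3


def test_overfit_single_sample_reconstruction():
    """decode(encode(x)) approximates x after training on that one sample."""
    rr, cc = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
    x = np.stack(
        [
            (rr - 16) ** 2 + (cc - 16) ** 2 <= 100,
            np.abs(rr - 10) + np.abs(cc - 20) <= 8,
            (rr > 8) & (rr < 26) & (cc > 5) & (cc < 15),
        ]
    ).astype(np.float32)
    cfg = tiny_config(
        encoder_filters=[8, 8, 16],
        decoder_filters=[16, 8, 8],
        optimizer="adam",
        learning_rate=1e-2,
        seed=2,
    )
    model = MorphoVAE(cfg)
    opt = make_optimizer(cfg.optimizer, cfg.learning_rate)
    rng = np.random.default_rng(0)
    y = one_hot([0], 3)
    for _ in range(800):
        model.train_step(x[None], y, opt, rng, alpha=0.0)
    recon = model.decode(model.encode(x).mu)
    frac_close = np.mean(np.abs(recon - x) < 0.1)
    assert frac_close >= 0.95, f"only {frac_close:.2%} of pixels close"


# -------------------------------------------------------------- classification
def test_classify_normalization(tiny_model):
    rng = np.random.default_rng(1)
    for _ in range(5):
        p = tiny_model.classify(rng.standard_normal(3))
        assert p.shape == (3,)
        assert abs(p.sum() - 1.0) < 1e-6
        assert np.all(p >= 0)


def test_classifier_is_affine(tiny_model):
    """Single-layer contract: logits(z1 + z2) = logits(z1) + logits(z2) - logits(0)."""
    rng = np.random.default_rng(2)
    for _ in range(5):
        z1, z2 = rng.standard_normal(3), rng.standard_normal(3)
        lhs = tiny_model.classifier_logits(z1 + z2)
        rhs = (
            tiny_model.classifier_logits(z1)
            + tiny_model.classifier_logits(z2)
            - tiny_model.classifier_logits(np.zeros(3))
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-4)


def test_classifier_learns_separable_latents():
    cfg = tiny_config(seed=4)
    model = MorphoVAE(cfg)
    rng = np.random.default_rng(0)
    centers = np.array([[4.0, 0, 0], [0, 4.0, 0], [0, 0, 4.0]])
    z = np.concatenate([c + 0.3 * rng.standard_normal((40, 3)) for c in centers])
    labels = np.repeat(np.arange(3), 40)
    y = one_hot(labels, 3).astype(np.float32)
    opt = make_optimizer("adam", 0.05)
    for _ in range(200):
        logits = model.classifier.forward(z.astype(np.float32))
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        model.classifier.backward(((probs - y) / (3 * len(z))).astype(np.float32))
        opt.step(model.classifier.param_items())
    acc = np.mean(model.classify(z).argmax(axis=1) == labels)
    assert acc >= 0.95


# ------------------------------------------------------------------ losses
def test_perfect_reconstruction_loss_negligible():
    rng = np.random.default_rng(3)
    p = (rng.random((3, 16, 16)) > 0.5).astype(float)
    code = LatentCode(np.zeros(3), np.zeros(3), np.zeros(3))
    labels = LabelVector(np.array([1.0, 0, 0]), np.array([0.5, 0.25, 0.25]))
    b = compute_losses(p, p, code, labels, alpha=0.1)
    assert b.e_rec <= 1e-6


def test_kl_zero_at_prior():
    code = LatentCode(np.zeros(3), np.zeros(3), np.zeros(3))
    labels = LabelVector(np.array([1.0, 0, 0]), np.array([1 / 3, 1 / 3, 1 / 3]))
    p = np.zeros((3, 4, 4))
    b = compute_losses(p, 0.5 * np.ones_like(p), code, labels, alpha=0.1)
    assert b.e_reg == 0.0


def brute_force_losses(p, q, mu, log_var, y, y_prime, alpha, eps=1e-7):
    """Independent elementwise-sum implementation."""
    q = np.minimum(np.maximum(q, eps), 1 - eps)
    e_rec = 0.0
    for pi, qi in zip(p.ravel(), q.ravel()):
        e_rec -= pi * np.log(qi) + (1 - pi) * np.log(1 - qi)
    e_rec /= p.size
    e_reg = 0.0
    for m, lv in zip(mu, log_var):
        e_reg += 0.5 * (m**2 + np.exp(lv) - lv - 1)
    e_c = 0.0
    for yi, ypi in zip(y, y_prime):
        if yi:
            e_c -= np.log(max(ypi, eps))
    e_c /= len(y)
    return e_rec, e_reg, e_c, (1 - alpha) * (e_rec + e_reg) + alpha * e_c


def test_losses_match_brute_force_oracle():
    rng = np.random.default_rng(11)
    p = (rng.random((3, 8, 8)) > 0.5).astype(float)
    q = rng.random((3, 8, 8))
    mu = rng.standard_normal(3)
    lv = rng.standard_normal(3) * 0.5
    y = np.array([0.0, 1.0, 0.0])
    yp = rng.dirichlet(np.ones(3))
    for alpha in (0.0, 0.1, 0.5, 1.0):
        b = compute_losses(p, q, LatentCode(mu, lv, mu), LabelVector(y, yp), alpha)
        e_rec, e_reg, e_c, e_total = brute_force_losses(p, q, mu, lv, y, yp, alpha)
        assert abs(b.e_rec - e_rec) < 1e-10
        assert abs(b.e_reg - e_reg) < 1e-10
        assert abs(b.e_c - e_c) < 1e-10
        assert abs(b.e_total - e_total) < 1e-10
    b0 = compute_losses(p, q, LatentCode(mu, lv, mu), LabelVector(y, yp), 0.0)
    b1 = compute_losses(p, q, LatentCode(mu, lv, mu), LabelVector(y, yp), 1.0)
    assert b0.e_total == pytest.approx(b0.e_vae)
    assert b1.e_total == pytest.approx(b1.e_c)


def test_default_alpha_matches_operating_point():
    assert ModelConfig(n_classes=7).alpha == 0.1


def test_kl_matches_numerical_integration():
    """Closed-form KL vs quadrature of q log(q/p) for scalar Gaussians."""
    for mu, sigma in [(0.0, 1.0), (0.7, 1.3), (-1.2, 0.6), (2.0, 2.0)]:
        closed = kl_standard_normal(np.array([mu]), np.array([2 * np.log(sigma)]))

        def integrand(x):
            qx = norm.pdf(x, mu, sigma)
            return qx * (norm.logpdf(x, mu, sigma) - norm.logpdf(x, 0, 1))

        numeric, _ = integrate.quad(integrand, mu - 12 * sigma, mu + 12 * sigma)
        assert abs(closed - numeric) < 1e-3


def test_loss_shape_mismatch_raises():
    code = LatentCode(np.zeros(3), np.zeros(3), np.zeros(3))
    labels = LabelVector(np.array([1.0, 0, 0]), np.array([1 / 3, 1 / 3, 1 / 3]))
    with pytest.raises(ShapeError):
        compute_losses(np.zeros((3, 4, 4)), np.zeros((3, 5, 5)), code, labels, 0.1)


# ------------------------------------------------------------------ misc
def test_checkpoint_roundtrip(tmp_path, tiny_model, tiny_input):
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = MorphoVAE.load(path)
    np.testing.assert_array_equal(
        loaded.encode(tiny_input).mu, tiny_model.encode(tiny_input).mu
    )
    assert loaded.config == tiny_model.config


def test_deterministic_pipeline_is_pure(tiny_model, tiny_input):
    code1 = tiny_model.encode(tiny_input)
    out1 = tiny_model.decode(code1.mu)
    p1 = tiny_model.classify(code1.mu)
    code2 = tiny_model.encode(tiny_input)
    out2 = tiny_model.decode(code2.mu)
    p2 = tiny_model.classify(code2.mu)
    np.testing.assert_array_equal(out1, out2)
    np.testing.assert_array_equal(p1, p2)


def test_scorecam_layer_has_8x8_map():
    model = MorphoVAE(ModelConfig(n_classes=3, encoder_filters=[4, 4, 4, 4, 8],
                                  decoder_filters=[8, 4, 4, 4, 4]))
    x = np.zeros((3, 128, 128), dtype=np.float32)
    acts = model.conv_activations(x)
    assert acts.shape[-2:] == (8, 8)
    assert model.scorecam_layer_name == "enc_conv_3"


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_classes=3, alpha=1.5).validate()
    with pytest.raises(ValueError):
        ModelConfig(n_classes=3, latent_dim=1).validate()
    with pytest.raises(ValueError):
        ModelConfig(n_classes=3, encoder_filters=[0, 4], decoder_filters=[4, 0]).validate()
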