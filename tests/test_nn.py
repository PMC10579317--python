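"""Tiny CNN backend: gradient correctness, training determinism, routing,
persistence, and Grad-CAM properties."""

import numpy as np
import pytest

from fundusqc import nn
from fundusqc.assessment import assess
from fundusqc.synthetic import (
    FundusSpec,
    Stratum,
    ValidationError,
    generate_clean_fundus,
    generate_dataset,
)


@pytest.fixture(scope="module")
def tiny_dataset():
    strata = [
        Stratum("post", 20, "posterior"),
        Stratum("peri", 10, "peripheral"),
        Stratum("peri_blur", 10, "peripheral", blur_sigma=(2.5, 4.0)),
        Stratum("peri_dark", 10, "peripheral",
                illumination_strength=(0.6, 0.9),
                illumination_region="whole"),
        Stratum("peri_cut", 10, "peripheral",
                integrity_missing_frac=(0.25, 0.5)),
    ]
    records, _ = generate_dataset(strata, seed=21, width=64, height=64)
    return records


@pytest.fixture(scope="module")
def trained_backend(tiny_dataset):
    cfg = nn.desk_scale_config(seed=3, epochs=4)
    return nn.train_cnn_backend(tiny_dataset, cfg)


def test_config_defaults_match_reference_recipe():
    cfg = nn.TrainConfig()
    assert (cfg.learning_rate, cfg.batch_size, cfg.epochs,
            cfg.input_size) == (0.001, 64, 50, 299)
    assert (cfg.lr_decay_factor, cfg.lr_patience_epochs) == (2.0, 3)


def test_unavailable_backbone_raises():
    x = np.zeros((4, 64, 64, 3))
    y = np.array([0.0, 1.0, 0.0, 1.0])
    with pytest.raises(ValidationError, match="not available"):
        nn.train_head(x, y, "t", nn.TrainConfig(backbone="inception_v3",
                                                input_size=64, epochs=1))


def test_backprop_matches_numerical_gradient():
    rng = np.random.default_rng(0)
    x = rng.random((2, 20, 20, 3))
    y = np.array([0.0, 1.0])
    params = nn._init_params(rng)
    logit, feat, gap, caches = nn._forward(params, x, want_cache=True)
    p = nn._sigmoid(logit)
    dlogit = (p - y) / len(y)
    grads = nn._backward(params, x, dlogit, feat, gap, caches)

    def loss(ps):
        lg, _ = nn._forward(ps, x)
        pp = nn._sigmoid(lg)
        return -np.mean(y * np.log(pp) + (1 - y) * np.log(1 - pp))

    eps = 1e-6
    for key in ("W0", "Wd", "b2"):
        flat_idx = 0  # check one representative entry per tensor
        ref = params[key].copy()
        pert = params[key].reshape(-1)
        pert[flat_idx] += eps
        up = loss(params)
        pert[flat_idx] -= 2 * eps
        down = loss(params)
        params[key] = ref
        numeric = (up - down) / (2 * eps)
        assert grads[key].reshape(-1)[flat_idx] == \
            pytest.approx(numeric, rel=1e-4, abs=1e-8)


def test_training_is_deterministic(tiny_dataset):
    cfg = nn.desk_scale_config(seed=5, epochs=2)
    x = nn._prepare([r.image for r in tiny_dataset[:20]], 64)
    y = np.array([1.0 if r.image.location == "posterior" else 0.0
                  for r in tiny_dataset[:20]])
    h1 = nn.train_head(x, y, "loc", cfg)
    h2 = nn.train_head(x, y, "loc", cfg)
    assert h1.history == h2.history
    for k in h1.params:
        assert np.array_equal(h1.params[k], h2.params[k])


def test_single_class_head_skipped_with_warning(tiny_dataset):
    posterior_only = [r for r in tiny_dataset
                      if r.image.location == "posterior"]
    cfg = nn.desk_scale_config(seed=1, epochs=1)
    with pytest.warns(UserWarning, match="single-class"):
        backend = nn.train_cnn_backend(posterior_only, cfg,
                                       tasks=["clarity_macula"])
    assert "clarity_macula" not in backend.heads


def test_assess_routes_aspects_by_location(trained_backend):
    img = generate_clean_fundus(FundusSpec(width=64, height=64,
                                           location="peripheral", seed=40))
    probs = assess(img, trained_backend, location_override="peripheral")
    assert tuple(probs.aspects) == ("integrity", "illumination", "clarity")
    assert all(0 <= p <= 1 for p in probs.aspects.values())


def test_backend_save_load_roundtrip(trained_backend, tmp_path):
    trained_backend.save(tmp_path / "ckpt")
    loaded = nn.CNNBackend.load(tmp_path / "ckpt")
    img = generate_clean_fundus(FundusSpec(width=64, height=64,
                                           location="peripheral", seed=41))
    a = assess(img, trained_backend, location_override="peripheral")
    b = assess(img, loaded, location_override="peripheral")
    assert a.aspects == b.aspects


class TestGradCAM:
    def test_values_normalised_and_shaped(self, trained_backend):
        img = generate_clean_fundus(FundusSpec(width=64, height=64,
                                               location="peripheral",
                                               seed=42))
        head = next(iter(trained_backend.heads))
        hm = nn.gradcam(img, trained_backend, head)
        assert hm.values.shape == img.shape
        assert hm.values.min() >= 0.0
        assert hm.values.max() <= 1.0
        if hm.values.max() > 0:
            assert hm.values.max() == pytest.approx(1.0)

    def test_classical_backend_unsupported(self, classical, clean_posterior):
        with pytest.raises(ValidationError, match="CNN"):
            nn.gradcam(clean_posterior, classical, "clarity")

    def test_unknown_head_rejected(self, trained_backend, clean_posterior):
        with pytest.raises(ValidationError):
            nn.gradcam(clean_posterior, trained_backend, "nonsense")

    def test_heatmap_localises_ridge_lesion(self):
        """A head trained to detect the bright peripheral ridge should put
        its heatmap mass on the ridge band of a fresh lesioned image (the
        defect region drives the prediction)."""
        from fundusqc.synthetic import add_rop_features

        strata = [Stratum("normal", 60, "peripheral"),
                  Stratum("ridge", 60, "peripheral", rop_stage="ridge")]
        recs, _ = generate_dataset(strata, seed=5, width=96, height=96)
        x = nn._prepare([r.image for r in recs], 64)
        y = np.array([1.0 if r.rop_label == "ROP" else 0.0 for r in recs])
        head = nn.train_head(x, y, "rop", nn.desk_scale_config(seed=1))
        backend = nn.CNNBackend({"rop": head}, 64)

        clean = generate_clean_fundus(FundusSpec(width=96, height=96,
                                                 location="peripheral",
                                                 seed=777))
        ridged = add_rop_features(clean, "ridge", seed=778)
        painted = (ridged.pixels.astype(float)
                   - clean.pixels.astype(float)).mean(-1) > 20
        v = nn.gradcam(ridged, backend, "rop").values
        retina = clean.masks["retina"]
        assert v[painted].mean() > 2 * v[retina & ~painted].mean()
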