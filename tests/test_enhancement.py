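"""Enhancement operators: gamma fixed points, bilateral oracle equivalence,
CLAHE channel selectivity, and the gating dispatcher."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusqc.assessment import AspectProbabilities, ClassicalBackend, assess
from fundusqc.enhancement import (
    BilateralParams,
    EnhancementParams,
    GammaParams,
    bilateral_filter,
    clahe_rg,
    enhance,
    gamma_transform,
)
from fundusqc.scoring import ThresholdPair
from fundusqc.synthetic import (
    DefectSpec,
    FundusImage,
    FundusSpec,
    ValidationError,
    apply_defects,
    generate_clean_fundus,
)


def flat_image(value, shape=(64, 64)):
    return FundusImage(np.full(shape + (3,), value, np.uint8), "peripheral")


class TestGammaTransform:
    @pytest.mark.parametrize("value", [0, 255])
    def test_fixed_points(self, value):
        out = gamma_transform(flat_image(value), GammaParams(0.7, 0.9))
        assert (out.pixels == value).all()

    def test_mid_gray_value_table(self):
        # (128/255)^0.7 * 255 = 157.39 -> 157 ; ^0.9 -> 137.46 -> 137
        out = gamma_transform(flat_image(128))
        assert out.pixels[0, 0, 0] == 157
        assert out.pixels[0, 0, 1] == 137
        assert out.pixels[0, 0, 2] == 128  # blue untouched

    def test_identity_exponent_is_identity(self, clean_posterior):
        out = gamma_transform(clean_posterior, GammaParams(1.0, 1.0))
        assert np.array_equal(out.pixels, clean_posterior.pixels)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValidationError):
            GammaParams(r_red=0.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.2, 0.99))
    def test_brightening_and_monotonicity(self, r):
        ramp = np.arange(256, dtype=np.uint8)
        img = FundusImage(np.stack([ramp] * 3, -1)[None, :, :], "peripheral")
        out = gamma_transform(img, GammaParams(r, r)).pixels[0]
        assert (out[:, 0].astype(int) >= ramp.astype(int)).all()  # r<1 brightens
        assert (np.diff(out[:, 0].astype(int)) >= 0).all()


def naive_bilateral(ch, b):
    """Independent per-pixel gather implementation of the bilateral filter."""
    h, w = ch.shape
    out = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            y0, y1 = max(0, y - b.radius), min(h, y + b.radius + 1)
            x0, x1 = max(0, x - b.radius), min(w, x + b.radius + 1)
            win = ch[y0:y1, x0:x1]
            yy, xx = np.mgrid[y0:y1, x0:x1]
            gs = np.exp(-((yy - y) ** 2 + (xx - x) ** 2)
                        / (2 * b.sigma_s**2))
            gr = np.exp(-((win - ch[y, x]) ** 2) / (2 * b.sigma_r**2))
            wgt = gs * gr
            out[y, x] = (wgt * win).sum() / wgt.sum()
    return out


class TestBilateralFilter:
    def test_constant_image_unchanged(self):
        out = bilateral_filter(flat_image(77, (16, 16)))
        assert (out.pixels == 77).all()

    def test_matches_naive_oracle_on_random_images(self):
        b = BilateralParams()  # radius 10, sigma_s 30, sigma_r 40
        rng = np.random.default_rng(0)
        for _ in range(20):
            px = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
            img = FundusImage(px, "peripheral")
            got = bilateral_filter(img, b, quantize=False)
            for c in range(3):
                want = naive_bilateral(px[..., c].astype(float), b)
                assert np.abs(got[..., c] - want).max() < 1e-9

    def test_step_edge_no_overshoot(self):
        px = np.zeros((16, 16, 3), np.uint8)
        px[:, 8:] = 200
        out = bilateral_filter(FundusImage(px, "peripheral"),
                               BilateralParams(radius=3))
        assert out.pixels.min() >= 0
        assert out.pixels.max() <= 200

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValidationError):
            BilateralParams(radius=0)


class TestClaheRG:
    def test_blue_channel_bit_identical(self, clean_posterior):
        out = clahe_rg(clean_posterior)
        assert np.array_equal(out.pixels[..., 2],
                              clean_posterior.pixels[..., 2])
        assert not np.array_equal(out.pixels[..., 1],
                                  clean_posterior.pixels[..., 1])

    def test_local_contrast_does_not_decrease(self, clean_peripheral):
        lowc = apply_defects(clean_peripheral, DefectSpec(
            illumination_strength=0.5, illumination_region="whole")).image
        out = clahe_rg(lowc)

        def tile_rms(ch):
            h, w = ch.shape
            t = h // 4
            vals = [ch[i:i + t, j:j + t].std()
                    for i in range(0, h - t, t) for j in range(0, w - t, t)]
            return np.mean(vals)

        assert tile_rms(out.pixels[..., 1].astype(float)) >= \
            tile_rms(lowc.pixels[..., 1].astype(float))


def _probs(integrity=0.0, illumination=0.0, clarity=0.0):
    return AspectProbabilities("peripheral", 0.1, {
        "integrity": integrity, "illumination": illumination,
        "clarity": clarity})


class TestEnhanceDispatcher:
    t = ThresholdPair(0.2, 0.8)

    def test_high_score_untouched(self, clean_peripheral):
        out, rep = enhance(clean_peripheral, _probs(0.1, 0.1, 0.1), self.t)
        assert rep.actions == ["none"]
        assert rep.iqcs_after is None
        assert np.array_equal(out.pixels, clean_peripheral.pixels)

    def test_low_score_discarded(self, black_peripheral, classical):
        probs = assess(black_peripheral, classical,
                       location_override="peripheral")
        out, rep = enhance(black_peripheral, probs, self.t)
        assert rep.actions == ["discard_flag"]
        assert rep.iqcs_before < 0.2

    def test_both_defects_ordered_gamma_bilateral_clahe(self,
                                                        clean_peripheral):
        probs = _probs(0.1, 0.9, 0.9)  # IQCS = 1-0.633 in eligible band
        out, rep = enhance(clean_peripheral, probs, self.t,
                           backend=ClassicalBackend())
        assert rep.actions == ["gamma", "bilateral", "clahe"]
        assert rep.iqcs_after is not None

    def test_integrity_only_rephotograph_advice(self, clean_peripheral):
        probs = _probs(integrity=0.95, illumination=0.2, clarity=0.2)
        out, rep = enhance(clean_peripheral, probs, self.t)
        assert rep.rephotograph_advised
        assert "gamma" not in rep.actions and "clahe" not in rep.actions

    def test_missing_thresholds_rejected(self, clean_peripheral):
        with pytest.raises(ValidationError):
            enhance(clean_peripheral, _probs(), None)


def test_enhancement_benefit_on_eligible_band_batch():
    """Desk-scale analog of the before/after IQCS comparison: over a seeded
    batch of eligible-band degraded images, the mean IQCS rises and the SD
    does not rise after enhancement."""
    backend = ClassicalBackend()
    t = ThresholdPair(0.2, 0.8)
    rng = np.random.default_rng(11)
    before, after = [], []
    for i in range(30):
        loc = "posterior" if i % 2 else "peripheral"
        region = "remaining" if loc == "posterior" else "whole"
        img = generate_clean_fundus(FundusSpec(width=96, height=96,
                                               location=loc, seed=i))
        kind = i % 3
        if kind == 0:
            d = DefectSpec(illumination_strength=rng.uniform(0.45, 0.65),
                           illumination_region=region)
        elif kind == 1:
            d = DefectSpec(blur_sigma=rng.uniform(1.6, 2.4))
        else:
            d = DefectSpec(illumination_strength=rng.uniform(0.45, 0.6),
                           illumination_region=region,
                           blur_sigma=rng.uniform(1.6, 2.2))
        rec = apply_defects(img, d)
        probs = assess(rec.image, backend, location_override=loc)
        _, rep = enhance(rec.image, probs, t, backend=backend)
        before.append(rep.iqcs_before)
        after.append(rep.iqcs_after if rep.iqcs_after is not None
                     else rep.iqcs_before)
    before, after = np.array(before), np.array(after)
    assert after.mean() > before.mean()
    assert after.std() <= before.std()
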