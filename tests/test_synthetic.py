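"""Generator invariants: determinism, structure, defect semantics, labels."""

import numpy as np
import pytest
from scipy import ndimage

from fundusqc.synthetic import (
    DefectSpec,
    FundusSpec,
    Stratum,
    ValidationError,
    add_rop_features,
    apply_defects,
    generate_clean_fundus,
    generate_dataset,
)


class TestGenerateCleanFundus:
    def test_identical_spec_is_bit_identical(self):
        spec = FundusSpec(width=96, height=96, location="posterior", seed=1)
        a = generate_clean_fundus(spec)
        b = generate_clean_fundus(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_peripheral_has_no_disc_or_macula(self, clean_peripheral):
        assert "optic_disc" not in clean_peripheral.masks
        assert "macula" not in clean_peripheral.masks

    def test_retina_brighter_than_background(self, clean_posterior):
        px = clean_posterior.pixels.astype(float).mean(axis=-1)
        retina = clean_posterior.masks["retina"]
        assert px[retina].mean() > px[~retina].mean()

    def test_posterior_disc_is_brightest_region(self, clean_posterior):
        px = clean_posterior.pixels.astype(float).mean(axis=-1)
        m = clean_posterior.masks
        assert px[m["optic_disc"]].mean() > px[m["remaining"]].mean()
        assert px[m["macula"]].mean() < px[m["remaining"]].mean()

    @pytest.mark.parametrize("w,h", [(32, 96), (96, 32)])
    def test_too_small_rejected(self, w, h):
        with pytest.raises(ValidationError):
            FundusSpec(width=w, height=h)

    def test_location_implies_structures(self):
        with pytest.raises(ValidationError):
            FundusSpec(location="peripheral", has_optic_disc=True)
        with pytest.raises(ValidationError):
            FundusSpec(location="posterior", has_macula=False)


class TestApplyDefects:
    def test_no_defect_is_identity(self, clean_peripheral):
        rec = apply_defects(clean_peripheral, DefectSpec())
        assert np.array_equal(rec.image.pixels, clean_peripheral.pixels)
        assert all(v == "good" for v in rec.truth_labels.values())
        assert rec.truth_grade == "excellent"

    def test_full_darkening_blacks_out_field(self, clean_peripheral):
        rec = apply_defects(clean_peripheral, DefectSpec(
            illumination_strength=1.0, illumination_region="whole"))
        retina = clean_peripheral.masks["retina"]
        assert rec.image.pixels[retina].max() == 0
        assert rec.truth_labels["illumination"] == "poor"

    def test_blur_reduces_laplacian_variance(self, clean_peripheral):
        rec = apply_defects(clean_peripheral, DefectSpec(blur_sigma=3.0))
        var_before = ndimage.laplace(
            clean_peripheral.pixels.astype(float).mean(-1)).var()
        var_after = ndimage.laplace(
            rec.image.pixels.astype(float).mean(-1)).var()
        assert var_after < var_before
        assert rec.truth_labels["clarity"] == "poor"

    def test_integrity_removes_requested_fraction(self, clean_peripheral):
        frac = 0.3
        rec = apply_defects(clean_peripheral,
                            DefectSpec(integrity_missing_frac=frac))
        before = clean_peripheral.masks["retina"].sum()
        after = rec.image.masks["retina"].sum()
        assert after / before == pytest.approx(1 - frac, abs=0.03)
        assert rec.truth_labels["integrity"] == "poor"

    def test_region_location_mismatch_rejected(self, clean_posterior,
                                               clean_peripheral):
        with pytest.raises(ValidationError):
            apply_defects(clean_posterior, DefectSpec(
                illumination_strength=0.5, illumination_region="whole"))
        with pytest.raises(ValidationError):
            apply_defects(clean_peripheral, DefectSpec(
                illumination_strength=0.5, illumination_region="macula"))
        with pytest.raises(ValidationError):
            apply_defects(clean_posterior,
                          DefectSpec(integrity_missing_frac=0.3))

    @pytest.mark.parametrize("strength,expected", [
        (0.39, "good"), (0.40, "poor"), (0.8, "poor"),
    ])
    def test_illumination_label_threshold(self, clean_peripheral,
                                          strength, expected):
        rec = apply_defects(clean_peripheral, DefectSpec(
            illumination_strength=strength, illumination_region="whole"))
        assert rec.truth_labels["illumination"] == expected

    def test_grade_tiers(self, clean_peripheral):
        mild = apply_defects(clean_peripheral, DefectSpec(
            illumination_strength=0.5, illumination_region="whole"))
        severe = apply_defects(clean_peripheral, DefectSpec(
            illumination_strength=0.85, illumination_region="whole"))
        assert mild.truth_grade == "eligible"
        assert severe.truth_grade == "ineligible"

    def test_pixel_range_preserved(self, clean_posterior):
        rec = apply_defects(clean_posterior, DefectSpec(
            illumination_strength=0.6, illumination_region="macula",
            blur_sigma=2.0))
        assert rec.image.pixels.dtype == np.uint8


class TestRopFeatures:
    def test_stage_none_is_identity(self, clean_peripheral):
        out = add_rop_features(clean_peripheral, "none")
        assert out is clean_peripheral

    def test_ridge_adds_annular_brightness(self, clean_peripheral):
        out = add_rop_features(clean_peripheral, "ridge", seed=3)
        h, w = clean_peripheral.shape
        cy, cx = (h - 1) / 2, (w - 1) / 2
        yy, xx = np.mgrid[0:h, 0:w]
        retina = clean_peripheral.masks["retina"]
        radius = np.sqrt(retina.sum() / np.pi)
        rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        annulus = (np.abs(rr - 0.75 * radius) < 0.06 * radius) & retina
        before = clean_peripheral.pixels.astype(float).mean(-1)[annulus].mean()
        after = out.pixels.astype(float).mean(-1)[annulus].mean()
        assert after > before

    def test_plus_thickens_vessels(self, clean_posterior):
        out = add_rop_features(clean_posterior, "plus", seed=3)
        assert not np.array_equal(out.pixels, clean_posterior.pixels)

    def test_same_seed_identical(self, clean_peripheral):
        a = add_rop_features(clean_peripheral, "ridge", seed=5)
        b = add_rop_features(clean_peripheral, "ridge", seed=5)
        assert np.array_equal(a.pixels, b.pixels)


class TestGenerateDataset:
    def test_counts_and_determinism(self, tmp_path):
        strata = [Stratum("post", 5, "posterior"),
                  Stratum("peri", 5, "peripheral")]
        _, m1 = generate_dataset(strata, seed=3, out_dir=tmp_path / "a")
        _, m2 = generate_dataset(strata, seed=3)
        assert len(m1) == 10
        assert m1.equals(m2)
        assert (tmp_path / "a" / "manifest.csv").exists()
        assert len(list((tmp_path / "a").glob("*.png"))) == 10

    def test_stratified_label_counts(self):
        strata = [Stratum("clean", 5, "peripheral"),
                  Stratum("blurred", 5, "peripheral", blur_sigma=3.0)]
        _, manifest = generate_dataset(strata, seed=0)
        assert (manifest["aspect_clarity"] == "poor").sum() == 5

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            Stratum("bad", -1)
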