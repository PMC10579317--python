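"""Seeded generator of fundus-like images with known ground truth.

Emulates posterior/peripheral infant fundus photographs: a bright circular
retinal field on a dark background, an optic disc and macula on posterior
views, branching vessel curves, and controllable quality defects
(illumination, clarity, integrity) plus ROP-like features (a peripheral
ridge band, vessel tortuosity/dilatation for plus disease).

Every output is a pure function of (spec, seed); ground-truth labels are
deterministic functions of the defect parameters under the documented
thresholds below.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

POSTERIOR_ASPECTS = (
    "illumination_macula",
    "illumination_optic_disc",
    "illumination_remaining",
    "clarity_macula",
    "clarity_optic_disc",
    "clarity_remaining",
)
PERIPHERAL_ASPECTS = ("integrity", "illumination", "clarity")

# Defect-parameter thresholds at which the ground-truth label flips to "poor",
# and the severity factor beyond which an image is graded ineligible.
ILLUMINATION_POOR_STRENGTH = 0.4
CLARITY_POOR_SIGMA = 1.5
INTEGRITY_POOR_FRAC = 0.15
SEVERE_FACTOR = 2.0


class ValidationError(ValueError):
    """Raised when a spec violates its invariants."""


@dataclass(frozen=True)
class FundusSpec:
    """Geometry and content of a clean synthetic fundus image."""

    width: int = 128
    height: int = 128
    location: str = "posterior"
    retina_radius_frac: float = 0.92
    vessel_count: int = 6
    has_optic_disc: bool | None = None
    has_macula: bool | None = None
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValidationError("width and height must be >= 64")
        if self.location not in ("posterior", "peripheral"):
            raise ValidationError(f"unknown location {self.location!r}")
        if not 0 < self.retina_radius_frac <= 1:
            raise ValidationError("retina_radius_frac must be in (0, 1]")
        want = self.location == "posterior"
        for name in ("has_optic_disc", "has_macula"):
            val = getattr(self, name)
            if val is None:
                object.__setattr__(self, name, want)
            elif val != want:
                raise ValidationError(
                    f"{name}={val} inconsistent with location={self.location}"
                )


@dataclass(frozen=True)
class DefectSpec:
    """Controllable quality defects applied to a clean image."""

    illumination_strength: float = 0.0
    illumination_region: str = "none"
    blur_sigma: float = 0.0
    integrity_missing_frac: float = 0.0
    rop_stage: str = "none"

    def __post_init__(self):
        if not 0 <= self.illumination_strength <= 1:
            raise ValidationError("illumination_strength must be in [0, 1]")
        if self.illumination_region not in (
            "macula", "optic_disc", "remaining", "whole", "none",
        ):
            raise ValidationError(
                f"unknown illumination_region {self.illumination_region!r}"
            )
        if self.blur_sigma < 0:
            raise ValidationError("blur_sigma must be >= 0")
        if not 0 <= self.integrity_missing_frac < 1:
            raise ValidationError("integrity_missing_frac must be in [0, 1)")
        if self.rop_stage not in ("none", "ridge", "plus"):
            raise ValidationError(f"unknown rop_stage {self.rop_stage!r}")

    def validate_for(self, location: str) -> None:
        if self.illumination_strength > 0:
            if location == "posterior" and self.illumination_region == "whole":
                raise ValidationError(
                    "region 'whole' targets peripheral images only"
                )
            if location == "peripheral" and self.illumination_region in (
                "macula", "optic_disc", "remaining",
            ):
                raise ValidationError(
                    f"region {self.illumination_region!r} requires a posterior image"
                )
        if self.integrity_missing_frac > 0 and location != "peripheral":
            raise ValidationError("integrity defects apply to peripheral images only")


@dataclass
class FundusImage:
    """8-bit RGB fundus raster plus a location tag and generator metadata.

    ``masks`` carries boolean region masks from the generator (``retina``,
    and for posterior views ``optic_disc``, ``macula``, ``remaining``); they
    feed the classical assessment backend as ground-truth regions.
    """

    pixels: np.ndarray
    location: str
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError("pixels must be an (H, W, 3) array")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def copy(self) -> "FundusImage":
        return FundusImage(
            self.pixels.copy(), self.location,
            {k: v.copy() for k, v in self.masks.items()},
        )


@dataclass
class SyntheticRecord:
    """An image plus its deterministic ground truth."""

    image: FundusImage
    truth_labels: dict[str, str]
    truth_grade: str
    rop_label: str
    defects: DefectSpec


def aspects_for(location: str) -> tuple[str, ...]:
    return POSTERIOR_ASPECTS if location == "posterior" else PERIPHERAL_ASPECTS


def _vessel_tree(rng, start, angles, length, amplitude, width, shape, n_points=200):
    """Rasterize sinusoidally wiggling vessel curves; returns a float mask."""
    h, w = shape
    mask = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for ang in angles:
        freq = rng.uniform(1.5, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        amp = amplitude * rng.uniform(0.6, 1.4)
        t = np.linspace(0.0, 1.0, n_points)
        direction = np.array([np.sin(ang), np.cos(ang)])
        normal = np.array([direction[1], -direction[0]])
        pts = (
            np.asarray(start)[None, :]
            + t[:, None] * length * direction[None, :]
            + (amp * np.sin(2 * np.pi * freq * t + phase))[:, None] * normal[None, :]
        )
        widths = width * (1.0 - 0.5 * t)
        for (py, px), vw in zip(pts, widths):
            iy, ix = int(round(py)), int(round(px))
            r = max(1, int(np.ceil(vw)))
            y0, y1 = max(0, iy - r), min(h, iy + r + 1)
            x0, x1 = max(0, ix - r), min(w, ix + r + 1)
            if y0 >= y1 or x0 >= x1:
                continue
            d2 = (yy[y0:y1, x0:x1] - py) ** 2 + (xx[y0:y1, x0:x1] - px) ** 2
            patch = np.clip(1.0 - d2 / (vw**2 + 1e-9), 0, 1)
            np.maximum(mask[y0:y1, x0:x1], patch, out=mask[y0:y1, x0:x1])
    return mask


def generate_clean_fundus(spec: FundusSpec) -> FundusImage:
    """Render a clean synthetic fundus image from a validated spec.

    Posterior views get a bright elliptical optic disc on the nasal side and
    a darker macular region at the centre; peripheral views are a plain
    vascularised field. Identical spec (including seed) yields bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.retina_radius_frac * min(h, w) / 2.0

    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    retina = r2 <= radius**2
    rnorm = np.sqrt(r2) / radius

    # warm fundus base with gentle radial falloff and speckle texture
    falloff = np.clip(1.0 - 0.25 * rnorm**2, 0, 1)
    texture = rng.normal(0.0, 4.0, size=(h, w))
    base = np.zeros((h, w, 3), dtype=float)
    base[..., 0] = 195 * falloff + texture
    base[..., 1] = 120 * falloff + 0.8 * texture
    base[..., 2] = 45 * falloff + 0.5 * texture

    masks: dict[str, np.ndarray] = {"retina": retina}
    if spec.location == "posterior":
        dy, dx = cy, cx + 0.45 * radius
        disc = ((yy - dy) / (0.16 * radius)) ** 2 + (
            (xx - dx) / (0.13 * radius)
        ) ** 2 <= 1.0
        macula = (yy - cy) ** 2 + (xx - (cx - 0.15 * radius)) ** 2 <= (
            0.20 * radius
        ) ** 2
        base[disc] = base[disc] * 0.25 + np.array([235.0, 215.0, 150.0]) * 0.75
        base[macula] *= 0.62
        masks["optic_disc"] = disc & retina
        masks["macula"] = macula & retina
        masks["remaining"] = retina & ~disc & ~macula
        vessel_start = (dy, dx)
        angles = rng.uniform(0, 2 * np.pi, size=spec.vessel_count)
    else:
        vessel_start = (cy, cx - 0.8 * radius)
        angles = rng.uniform(-0.8, 0.8, size=spec.vessel_count)

    vmask = _vessel_tree(
        rng, vessel_start, angles, length=1.5 * radius,
        amplitude=0.05 * radius, width=max(1.2, 0.02 * radius), shape=(h, w),
    )
    vessel_color = np.array([115.0, 32.0, 28.0])
    base = base * (1 - 0.85 * vmask[..., None]) + vessel_color * (
        0.85 * vmask[..., None]
    )

    base[~retina] = rng.normal(8.0, 2.0, size=(h, w, 3))[~retina]
    pixels = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    return FundusImage(pixels, spec.location, masks)


def _truth_labels(location: str, d: DefectSpec) -> dict[str, str]:
    labels = {a: "good" for a in aspects_for(location)}
    ill_poor = d.illumination_strength >= ILLUMINATION_POOR_STRENGTH
    if location == "posterior":
        if ill_poor and d.illumination_region in ("macula", "optic_disc", "remaining"):
            labels[f"illumination_{d.illumination_region}"] = "poor"
        if d.blur_sigma >= CLARITY_POOR_SIGMA:
            for region in ("macula", "optic_disc", "remaining"):
                labels[f"clarity_{region}"] = "poor"
    else:
        if ill_poor and d.illumination_region == "whole":
            labels["illumination"] = "poor"
        if d.blur_sigma >= CLARITY_POOR_SIGMA:
            labels["clarity"] = "poor"
        if d.integrity_missing_frac >= INTEGRITY_POOR_FRAC:
            labels["integrity"] = "poor"
    return labels


def _truth_grade(labels: dict[str, str], d: DefectSpec) -> str:
    severe = (
        (d.illumination_strength >= SEVERE_FACTOR * ILLUMINATION_POOR_STRENGTH
         and d.illumination_region != "none")
        or d.blur_sigma >= SEVERE_FACTOR * CLARITY_POOR_SIGMA
        or d.integrity_missing_frac >= SEVERE_FACTOR * INTEGRITY_POOR_FRAC
    )
    if severe:
        return "ineligible"
    if all(v == "good" for v in labels.values()):
        return "excellent"
    return "eligible"


def apply_defects(image: FundusImage, d: DefectSpec) -> SyntheticRecord:
    """Degrade an image per a defect spec and attach ground-truth labels.

    Darkening multiplies the target region by ``1 - illumination_strength``;
    clarity loss is an isotropic Gaussian blur; an integrity defect truncates
    a chord of the retinal disc so that the requested fraction is lost.
    """
    d.validate_for(image.location)
    out = image.copy()
    px = out.pixels.astype(float)

    if d.illumination_strength > 0 and d.illumination_region != "none":
        if d.illumination_region == "whole":
            region = out.masks.get(
                "retina", np.ones(out.shape, dtype=bool)
            )
        else:
            region = out.masks[d.illumination_region]
        px[region] *= 1.0 - d.illumination_strength

    if d.blur_sigma > 0:
        px = ndimage.gaussian_filter(px, sigma=(d.blur_sigma, d.blur_sigma, 0))

    if d.integrity_missing_frac > 0:
        retina = out.masks.get("retina")
        if retina is None or not retina.any():
            raise ValidationError("integrity defect requires a retina mask")
        cols = np.nonzero(retina)[1]
        cut = np.quantile(cols, 1.0 - d.integrity_missing_frac)
        lost = retina & (np.arange(out.shape[1])[None, :] >= cut)
        px[lost] = 0.0
        out.masks["retina"] = retina & ~lost

    out.pixels = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    labels = _truth_labels(image.location, d)
    grade = _truth_grade(labels, d)
    rop = "Normal" if d.rop_stage == "none" else "ROP"
    return SyntheticRecord(out, labels, grade, rop, d)


def add_rop_features(image: FundusImage, stage: str, seed: int = 0) -> FundusImage:
    """Overlay ROP-like features: a bright peripheral ridge band or
    tortuous, dilated plus-disease vessels. ``stage='none'`` is a no-op."""
    if stage == "none":
        return image
    if stage not in ("ridge", "plus"):
        raise ValidationError(f"unknown rop stage {stage!r}")
    rng = np.random.default_rng(seed)
    out = image.copy()
    h, w = out.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    retina = out.masks.get("retina", np.ones((h, w), dtype=bool))
    radius = np.sqrt(retina.sum() / np.pi)
    px = out.pixels.astype(float)

    if stage == "ridge":
        # demarcation ridge: bright curvilinear band on an annular arc
        yy, xx = np.mgrid[0:h, 0:w]
        theta0 = rng.uniform(0, 2 * np.pi)
        rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ang = np.arctan2(yy - cy, xx - cx)
        dang = np.angle(np.exp(1j * (ang - theta0)))
        band = (
            (np.abs(rr - 0.75 * radius) < 0.045 * radius)
            & (np.abs(dang) < 1.1)
            & retina
        )
        soft = ndimage.gaussian_filter(band.astype(float), 1.0)
        soft /= max(soft.max(), 1e-9)
        ridge_color = np.array([250.0, 235.0, 205.0])
        px = px * (1 - 0.9 * soft[..., None]) + ridge_color * (0.9 * soft[..., None])
    else:  # plus disease
        n = 8
        angles = rng.uniform(0, 2 * np.pi, size=n)
        vmask = _vessel_tree(
            rng, (cy, cx), angles, length=1.1 * radius,
            amplitude=0.16 * radius, width=max(2.0, 0.035 * radius), shape=(h, w),
        )
        vmask = np.where(retina, vmask, 0.0)
        vessel_color = np.array([130.0, 25.0, 22.0])
        px = px * (1 - 0.9 * vmask[..., None]) + vessel_color * (0.9 * vmask[..., None])

    out.pixels = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return out


@dataclass(frozen=True)
class Stratum:
    """One homogeneous slice of a dataset: a location, a defect template
    and a count. Defect parameters may be scalar or (low, high) ranges
    sampled uniformly per image."""

    name: str
    count: int
    location: str = "posterior"
    illumination_strength: float | tuple[float, float] = 0.0
    illumination_region: str = "none"
    blur_sigma: float | tuple[float, float] = 0.0
    integrity_missing_frac: float | tuple[float, float] = 0.0
    rop_stage: str = "none"

    def __post_init__(self):
        if self.count < 0:
            raise ValidationError("stratum count must be >= 0")


def _draw(value, rng) -> float:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return float(rng.uniform(lo, hi))
    return float(value)


def generate_dataset(
    strata: list[Stratum],
    seed: int = 0,
    out_dir: str | Path | None = None,
    width: int = 128,
    height: int = 128,
) -> tuple[list[SyntheticRecord], pd.DataFrame]:
    """Generate a stratified dataset; optionally write PNGs + manifest CSV.

    Counts match the strata exactly and identical (strata, seed) yield
    identical manifests. The manifest has one row per image with the path,
    location, per-aspect labels, grade, ROP label and defect parameters.
    """
    rng = np.random.default_rng(seed)
    records: list[SyntheticRecord] = []
    rows = []
    all_aspects = list(POSTERIOR_ASPECTS) + list(PERIPHERAL_ASPECTS)
    idx = 0
    for st in strata:
        for _ in range(st.count):
            img_seed = int(rng.integers(0, 2**31 - 1))
            spec = FundusSpec(
                width=width, height=height, location=st.location, seed=img_seed
            )
            clean = generate_clean_fundus(spec)
            if st.rop_stage != "none":
                clean = add_rop_features(clean, st.rop_stage, seed=img_seed + 1)
            d = DefectSpec(
                illumination_strength=_draw(st.illumination_strength, rng),
                illumination_region=st.illumination_region,
                blur_sigma=_draw(st.blur_sigma, rng),
                integrity_missing_frac=_draw(st.integrity_missing_frac, rng),
                rop_stage=st.rop_stage,
            )
            rec = apply_defects(clean, d)
            rec.rop_label = "Normal" if st.rop_stage == "none" else "ROP"
            records.append(rec)
            path = f"img_{idx:05d}.png"
            row = {
                "path": path,
                "location": st.location,
                "stratum": st.name,
                "grade": rec.truth_grade,
                "rop_label": rec.rop_label,
                "param_illumination_strength": d.illumination_strength,
                "param_illumination_region": d.illumination_region,
                "param_blur_sigma": d.blur_sigma,
                "param_integrity_missing_frac": d.integrity_missing_frac,
                "param_rop_stage": d.rop_stage,
                "seed": img_seed,
            }
            for a in all_aspects:
                row[f"aspect_{a}"] = rec.truth_labels.get(a, "")
            rows.append(row)
            idx += 1

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(records, rows):
            iio.imwrite(out_dir / row["path"], rec.image.pixels)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        with open(out_dir / "strata.json", "w") as fh:
            json.dump([dataclasses.asdict(s) for s in strata], fh, indent=2)
    return records, manifest
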