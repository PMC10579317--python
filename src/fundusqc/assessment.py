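"""Multidimensional quality assessment: location plus per-aspect "poor"
probabilities.

Two interchangeable backends implement the same ``assess`` contract:

* :class:`ClassicalBackend` — deterministic hand-crafted features (region
  luminance, luminance-normalised Laplacian variance, field coverage) mapped
  through fixed logistic links. It needs region masks for posterior images,
  taken from generator metadata when present or from fixed geometric priors.
* A trained CNN backend (see :mod:`fundusqc.nn`) — one small binary conv-net
  per head, mirroring the one-model-per-task design of the original system.

The location decision is made first; only the aspect heads matching the
decided location are evaluated, so an image never receives probabilities for
aspects of the other location class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import (
    PERIPHERAL_ASPECTS,
    POSTERIOR_ASPECTS,
    FundusImage,
    ValidationError,
    aspects_for,
)

DECISION_THRESHOLD = 0.5  # binary "poor" call at p >= 0.5


@dataclass
class AspectProbabilities:
    """Per-aspect poor-quality probabilities for one image."""

    location: str
    p_posterior: float
    aspects: dict[str, float]

    def __post_init__(self):
        expected = aspects_for(self.location)
        if tuple(self.aspects) != expected:
            raise ValidationError(
                f"aspects for a {self.location} image must be exactly {expected}, "
                f"got {tuple(self.aspects)}"
            )
        for name, p in self.aspects.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p[{name}]={p} outside [0, 1]")

    def poor_calls(self) -> dict[str, bool]:
        return {a: p >= DECISION_THRESHOLD for a, p in self.aspects.items()}

    @property
    def p_vector(self) -> np.ndarray:
        return np.array(list(self.aspects.values()))


def _check_rgb(image: FundusImage) -> np.ndarray:
    px = np.asarray(image.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValidationError("assessment requires an (H, W, 3) RGB image")
    if px.size == 0:
        raise ValidationError("empty image")
    return px.astype(float)


def luminance(px: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of a float RGB raster."""
    return 0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2]


def geometric_prior_masks(shape: tuple[int, int], location: str,
                          retina_radius_frac: float = 0.92) -> dict[str, np.ndarray]:
    """Fixed geometric region priors matching the generator's layout:
    retinal disc centred in the frame, optic disc on the nasal side at
    0.45 R, macula slightly temporal of centre."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = retina_radius_frac * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    retina = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    masks = {"retina": retina}
    if location == "posterior":
        disc = ((yy - cy) / (0.16 * radius)) ** 2 + (
            (xx - (cx + 0.45 * radius)) / (0.13 * radius)
        ) ** 2 <= 1.0
        macula = (yy - cy) ** 2 + (xx - (cx - 0.15 * radius)) ** 2 <= (
            0.20 * radius
        ) ** 2
        masks["optic_disc"] = disc & retina
        masks["macula"] = macula & retina
        masks["remaining"] = retina & ~disc & ~macula
    return masks


def _logistic(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0))))


@dataclass
class ClassicalBackend:
    """Deterministic feature-based assessment backend.

    Illumination: p = logistic((L0 - mean region luminance) / s) with a
    per-region reference L0 placed at the luminance a region reaches when
    darkened to the generator's "poor" strength.

    Clarity: sharpness is the variance of the Laplacian of mildly
    pre-smoothed region luminance, normalised by (mean luminance / 100)^2.
    The pre-smoothing (Gaussian, sigma 1) makes the feature respond to
    structure-scale blur rather than pixel noise, and the luminance
    normalisation decouples blur detection from darkening;
    p = logistic((V0 - sharpness) / v).

    Integrity (peripheral only): coverage is the lit fraction of the
    expected circular field; p = logistic((C0 - coverage) / c) with C0 at
    the coverage left by the generator's "poor" missing fraction.

    All constants are fixed, documented calibration values.
    """

    # per-region illumination references (region luminance at the poor
    # threshold) and logistic scales
    L0: dict[str, float] = field(default_factory=lambda: {
        "macula": 49.0, "optic_disc": 94.0, "remaining": 69.0, "whole": 68.0,
    })
    s: dict[str, float] = field(default_factory=lambda: {
        "macula": 6.5, "optic_disc": 12.5, "remaining": 9.0, "whole": 9.0,
    })
    # per-region normalised-sharpness references (value at blur_sigma = 1.5)
    V0: dict[str, float] = field(default_factory=lambda: {
        "macula": 3.5, "optic_disc": 18.0, "remaining": 3.4, "whole": 3.5,
    })
    v: dict[str, float] = field(default_factory=lambda: {
        "macula": 1.0, "optic_disc": 5.0, "remaining": 1.0, "whole": 1.0,
    })
    C0: float = 0.85
    c: float = 0.03
    dark_level: float = 20.0       # luminance below which a pixel counts as unlit
    disc_blob_ref: float = 145.0   # smoothed-luminance peak separating posterior
    disc_blob_scale: float = 4.0

    name: str = "classical"

    # -- features ----------------------------------------------------------

    presmooth_sigma: float = 1.0

    def _sharpness(self, lum: np.ndarray, mask: np.ndarray) -> float:
        # the normalisation saturates below a luminance floor: darker than
        # that, the Laplacian is noise-dominated and the region is unclear
        lap = ndimage.laplace(ndimage.gaussian_filter(lum, self.presmooth_sigma))
        mean = max(float(lum[mask].mean()), 40.0)
        return float(lap[mask].var()) / (mean / 100.0) ** 2

    def _location_probability(self, lum: np.ndarray,
                              retina: np.ndarray) -> float:
        h, w = lum.shape
        size = max(3, int(0.1 * min(h, w)))
        blob = ndimage.uniform_filter(lum, size=size)
        peak = float(blob[retina].max()) if retina.any() else float(blob.max())
        return _logistic((peak - self.disc_blob_ref) / self.disc_blob_scale)

    # -- contract ----------------------------------------------------------

    def assess(self, image: FundusImage,
               location_override: str | None = None) -> AspectProbabilities:
        px = _check_rgb(image)
        lum = luminance(px)

        prior = geometric_prior_masks(image.shape, "posterior")
        retina_prior = prior["retina"]
        p_post = self._location_probability(lum, retina_prior)
        location = location_override or (
            "posterior" if p_post >= 0.5 else "peripheral"
        )

        masks = dict(geometric_prior_masks(image.shape, location))
        # generator metadata wins over the geometric prior where present
        for key in ("optic_disc", "macula", "remaining"):
            if key in image.masks:
                masks[key] = image.masks[key]
        if location == "posterior":
            missing = [k for k in ("macula", "optic_disc", "remaining")
                       if not masks.get(k, np.zeros(1, bool)).any()]
            if missing:
                raise ValidationError(
                    f"posterior assessment needs region masks; empty: {missing}"
                )

        probs: dict[str, float] = {}
        if location == "posterior":
            for region in ("macula", "optic_disc", "remaining"):
                m = masks[region]
                mean_lum = float(lum[m].mean())
                probs[f"illumination_{region}"] = _logistic(
                    (self.L0[region] - mean_lum) / self.s[region]
                )
            for region in ("macula", "optic_disc", "remaining"):
                m = masks[region]
                probs[f"clarity_{region}"] = _logistic(
                    (self.V0[region] - self._sharpness(lum, m)) / self.v[region]
                )
            ordered = {a: probs[a] for a in POSTERIOR_ASPECTS}
        else:
            field_mask = geometric_prior_masks(image.shape, "peripheral")["retina"]
            coverage = float((lum[field_mask] > self.dark_level).mean())
            probs["integrity"] = _logistic((self.C0 - coverage) / self.c)
            mean_lum = float(lum[field_mask].mean())
            probs["illumination"] = _logistic(
                (self.L0["whole"] - mean_lum) / self.s["whole"]
            )
            probs["clarity"] = _logistic(
                (self.V0["whole"] - self._sharpness(lum, field_mask))
                / self.v["whole"]
            )
            ordered = {a: probs[a] for a in PERIPHERAL_ASPECTS}

        return AspectProbabilities(location, p_post, ordered)


def assess(image: FundusImage, backend,
           location_override: str | None = None) -> AspectProbabilities:
    """Assess one image with any backend honouring the backend contract."""
    return backend.assess(image, location_override=location_override)
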