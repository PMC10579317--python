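"""Targeted quality enhancement gated by assessment results.

Images in the eligible IQCS band get defect-specific operators: poor
illumination triggers a gamma transform of the red and green channels
(exponents 0.7 and 0.9) followed by an edge-preserving bilateral filter
(radius 10, spatial sigma 30, range sigma 40); poor clarity triggers CLAHE
on the red and green channels. Images below the lower threshold are flagged
for discard, images at or above the upper threshold are left untouched, and
integrity defects are never digitally fixed — they are recorded as
rephotograph advice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

from .assessment import AspectProbabilities, assess
from .scoring import IQCSWeights, ThresholdPair, compute_iqcs
from .synthetic import FundusImage, ValidationError


@dataclass(frozen=True)
class GammaParams:
    """Power-law exponents for the red and green channels; blue is never
    transformed. Exponents below one brighten."""

    r_red: float = 0.7
    r_green: float = 0.9

    def __post_init__(self):
        if self.r_red <= 0 or self.r_green <= 0:
            raise ValidationError("gamma exponents must be positive")


@dataclass(frozen=True)
class BilateralParams:
    radius: int = 10
    sigma_s: float = 30.0
    sigma_r: float = 40.0

    def __post_init__(self):
        if self.radius < 1:
            raise ValidationError("bilateral radius must be >= 1")
        if self.sigma_s <= 0 or self.sigma_r <= 0:
            raise ValidationError("bilateral sigmas must be positive")


@dataclass(frozen=True)
class ClaheParams:
    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ValidationError("clip_limit must be positive")
        if min(self.tile_grid) < 1:
            raise ValidationError("tile grid must be at least 1x1")


@dataclass
class EnhancementParams:
    """Operator parameters for the enhancement dispatcher.

    The bilateral spatial parameters (radius, sigma_s) are stated for
    clinical-resolution photographs of about ``reference_width`` pixels.
    Spatial extents scale with resolution while intensity units do not, so
    the dispatcher shrinks radius and sigma_s proportionally to the image
    width (never below radius 1) and keeps sigma_r unchanged. Set
    ``reference_width=None`` to use the raw parameters at any size.
    """

    gamma: GammaParams = field(default_factory=GammaParams)
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    clahe: ClaheParams = field(default_factory=ClaheParams)
    reference_width: int | None = 1600

    def bilateral_for(self, image_width: int) -> BilateralParams:
        if self.reference_width is None:
            return self.bilateral
        scale = image_width / self.reference_width
        return BilateralParams(
            radius=max(1, round(self.bilateral.radius * scale)),
            sigma_s=max(0.5, self.bilateral.sigma_s * scale),
            sigma_r=self.bilateral.sigma_r,
        )


@dataclass
class EnhancementReport:
    """Which operators ran and the IQCS before/after."""

    actions: list[str]
    iqcs_before: float
    iqcs_after: float | None = None
    rephotograph_advised: bool = False


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8)


def gamma_transform(image: FundusImage, g: GammaParams | None = None) -> FundusImage:
    """Per-pixel Y = (I/255)^r * 255 on the red and green channels."""
    g = g or GammaParams()
    out = image.copy()
    px = out.pixels.astype(float)
    px[..., 0] = (px[..., 0] / 255.0) ** g.r_red * 255.0
    px[..., 1] = (px[..., 1] / 255.0) ** g.r_green * 255.0
    out.pixels = _round_half_up(px)
    return out


def _bilateral_channel(ch: np.ndarray, b: BilateralParams) -> np.ndarray:
    """Vectorised shift-and-accumulate bilateral filter of one channel.

    The square neighbourhood is clipped at the borders; Gaussians are the
    unnormalised exp(-x^2 / 2 sigma^2); the weight sum normalises.
    """
    h, w = ch.shape
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    r = b.radius
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            gs = np.exp(-(dy * dy + dx * dx) / (2.0 * b.sigma_s**2))
            ys0, ys1 = max(0, dy), min(h, h + dy)       # q rows
            xs0, xs1 = max(0, dx), min(w, w + dx)       # q cols
            yt0, yt1 = max(0, -dy), min(h, h - dy)      # p rows
            xt0, xt1 = max(0, -dx), min(w, w - dx)      # p cols
            q = ch[ys0:ys1, xs0:xs1]
            p = ch[yt0:yt1, xt0:xt1]
            wgt = gs * np.exp(-((p - q) ** 2) / (2.0 * b.sigma_r**2))
            num[yt0:yt1, xt0:xt1] += wgt * q
            den[yt0:yt1, xt0:xt1] += wgt
    return num / den


def bilateral_filter(image: FundusImage, b: BilateralParams | None = None,
                     quantize: bool = True):
    """Edge-preserving smoother applied to all three channels.

    With ``quantize=False`` the raw float result is returned (useful for
    numerical comparison against a reference implementation); otherwise the
    output is rounded half-up back to 8 bits.
    """
    b = b or BilateralParams()
    px = image.pixels.astype(float)
    out = np.stack([_bilateral_channel(px[..., c], b) for c in range(3)], axis=-1)
    if not quantize:
        return out
    res = image.copy()
    res.pixels = _round_half_up(out)
    return res


def clahe_rg(image: FundusImage, c: ClaheParams | None = None) -> FundusImage:
    """Contrast-limited adaptive histogram equalisation of the red and
    green channels; the blue channel passes through untouched.

    skimage's normalised clip limit is the OpenCV-style ``clip_limit``
    divided by the 256-bin histogram size.
    """
    c = c or ClaheParams()
    out = image.copy()
    h, w = image.shape
    kernel = (max(1, h // c.tile_grid[0]), max(1, w // c.tile_grid[1]))
    px = out.pixels.copy()
    for ch in (0, 1):
        eq = exposure.equalize_adapthist(
            px[..., ch], kernel_size=kernel,
            clip_limit=c.clip_limit / 256.0, nbins=256,
        )
        px[..., ch] = _round_half_up(eq * 255.0)
    out.pixels = px
    return out


def enhance(
    image: FundusImage,
    probs: AspectProbabilities,
    t: ThresholdPair,
    params: EnhancementParams | None = None,
    backend=None,
    weights: IQCSWeights | None = None,
) -> tuple[FundusImage, EnhancementReport]:
    """Dispatch enhancement operators according to assessment results.

    IQCS below the lower threshold: flag for discard (severe defects are
    not salvageable). IQCS at or above the upper threshold: do nothing.
    In the eligible band: gamma + bilateral for any poor illumination
    aspect, then CLAHE for any poor clarity aspect; a poor integrity call
    only sets rephotograph advice. ``iqcs_after`` is recomputed with the
    same backend whenever an operator ran.
    """
    if t is None:
        raise ValidationError("thresholds are required")
    params = params or EnhancementParams()
    score = compute_iqcs(probs, weights).score
    calls = probs.poor_calls()
    rephotograph = any(
        poor for name, poor in calls.items() if name.startswith("integrity")
    )

    if score < t.lower:
        report = EnhancementReport(["discard_flag"], score,
                                   rephotograph_advised=rephotograph)
        return image, report
    if score >= t.upper:
        return image, EnhancementReport(["none"], score,
                                        rephotograph_advised=rephotograph)

    ill_poor = any(p for n, p in calls.items() if n.startswith("illumination"))
    clar_poor = any(p for n, p in calls.items() if n.startswith("clarity"))
    actions: list[str] = []
    out = image
    if ill_poor:
        out = gamma_transform(out, params.gamma)
        out = bilateral_filter(out, params.bilateral_for(image.shape[1]))
        actions += ["gamma", "bilateral"]
    if clar_poor:
        out = clahe_rg(out, params.clahe)
        actions.append("clahe")
    if not actions:
        return image, EnhancementReport(["none"], score,
                                        rephotograph_advised=rephotograph)

    iqcs_after = None
    if backend is None:
        from .assessment import ClassicalBackend
        backend = ClassicalBackend()
    after_probs = assess(out, backend, location_override=probs.location)
    iqcs_after = compute_iqcs(after_probs, weights).score
    return out, EnhancementReport(actions, score, iqcs_after, rephotograph)
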