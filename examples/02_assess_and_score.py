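"""Assess image quality and compute the comprehensive score (IQCS).

The classical backend maps region luminance, normalised sharpness and
field coverage through fixed logistic links into per-aspect "poor"
probabilities; IQCS = 1 - mean(p) ranges 0 (worst) to 1 (best).
"""
from fundusqc import (ClassicalBackend, DefectSpec, FundusSpec, ThresholdPair,
                      apply_defects, assess, classify_grade, compute_iqcs,
                      generate_clean_fundus)

backend = ClassicalBackend()
img = generate_clean_fundus(FundusSpec(width=128, height=128,
                                       location="peripheral", seed=3))
dark = apply_defects(img, DefectSpec(illumination_strength=0.55,
                                     illumination_region="whole")).image

for name, image in (("clean", img), ("darkened", dark)):
    probs = assess(image, backend, location_override="peripheral")
    result = compute_iqcs(probs)
    grade = classify_grade(result.score, ThresholdPair(0.2, 0.8))
    print(f"{name}: p = { {k: round(v, 2) for k, v in probs.aspects.items()} }"
          f" -> IQCS {result.score:.3f} ({grade})")
# the darkened image's illumination probability rises, pulling IQCS down
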