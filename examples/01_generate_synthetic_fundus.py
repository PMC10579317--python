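"""Generate a small synthetic fundus dataset with ground-truth labels.

Creates clean posterior/peripheral images, applies controlled defects
(darkening, blur, field truncation), and writes PNGs plus a CSV manifest.
"""
from fundusqc import DefectSpec, FundusSpec, Stratum, apply_defects, generate_clean_fundus, generate_dataset

img = generate_clean_fundus(FundusSpec(width=128, height=128,
                                       location="posterior", seed=1))
rec = apply_defects(img, DefectSpec(illumination_strength=0.6,
                                    illumination_region="macula"))
print("defect labels:", rec.truth_labels)
print("grade:", rec.truth_grade)
# labels flip to "poor" when a defect parameter crosses its documented
# threshold (darkening >= 0.4, blur sigma >= 1.5, missing field >= 0.15)

strata = [Stratum("clean", 5, "peripheral"),
          Stratum("blurred", 5, "peripheral", blur_sigma=(2.0, 3.0))]
records, manifest = generate_dataset(strata, seed=7, out_dir="out/demo")
print(manifest[["path", "location", "aspect_clarity", "grade"]])
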