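"""Does enhancement help a downstream ROP classifier?

Trains two identical tiny classifiers on degraded synthetic ROP images —
one arm raw, one arm enhanced — and compares held-out AUC (DeLong test)
and accuracy (two-proportion z), averaged over 3 seeds.
"""
from fundusqc.pipeline import PipelineConfig, cmd_rop_demo

report = cmd_rop_demo(PipelineConfig(seed=1))  # 60 images/class, 3 seeds
print("mean AUC raw:     ", round(report["mean_auc_raw"], 3))
print("mean AUC enhanced:", round(report["mean_auc_enhanced"], 3))
print("first-seed DeLong p:", round(report["per_seed"][0]["delong_p"], 3))
# the enhanced arm should match or beat the raw arm on degraded inputs
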