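"""Validate IQCS against simulated expert rankings via ELO tournaments.

Thirty images with strictly increasing degradation are ranked by six
noiseless simulated raters (15 rounds of random pairings each); the
consensus ranking is compared with the IQCS ranking by Spearman's rho.
"""
from fundusqc.pipeline import PipelineConfig, cmd_rank_demo

report = cmd_rank_demo(PipelineConfig(seed=1), n_images=30, n_raters=6,
                       rounds=15)
print(report)
# rho near 1 means the comprehensive score orders images like the raters do
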