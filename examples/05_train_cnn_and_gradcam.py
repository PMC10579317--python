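"""Train a tiny CNN quality head and visualise it with Grad-CAM.

A three-block NumPy conv-net is trained to detect blur on synthetic
peripheral images; the Grad-CAM heatmap shows where the head looks.
"""
import numpy as np

from fundusqc import Stratum, generate_dataset, gradcam
from fundusqc.nn import desk_scale_config, train_cnn_backend

strata = [Stratum("clean", 60, "peripheral"),
          Stratum("blurred", 60, "peripheral", blur_sigma=(2.5, 4.0))]
records, _ = generate_dataset(strata, seed=5, width=96, height=96)
backend = train_cnn_backend(records, desk_scale_config(seed=1),
                            tasks=["clarity"])
print("validation accuracy:", backend.heads["clarity"].val_accuracy)

heatmap = gradcam(records[-1].image, backend, "clarity")
print("heatmap shape:", heatmap.values.shape,
      "max:", round(float(heatmap.values.max()), 2))
# values in [0,1]; larger values mark regions driving the "poor" call
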