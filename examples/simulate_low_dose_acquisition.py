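"""Simulate paired baseline / low-dose chest acquisitions of one phantom.

Builds a synthetic chest phantom (lungs, ribs, vessels, a nodule), exposes
it at the baseline dose and at the three reduced-dose arms of a paired
study (60%, 50%, 40%), and prints the flat-region noise of each arm in
the display domain — noise should grow like 1/sqrt(dose fraction).
"""

import numpy as np

from radnoise import (AcquisitionConfig, PhantomConfig, clean_display,
                      generate_phantom, preprocess, simulate_acquisition)

truth = generate_phantom(PhantomConfig(
    image_size=256, seed=0, nodules=(((0.35, 0.3), 10, 0.25),)))
print(f"phantom: {truth.image.shape}, signal range "
      f"[{truth.image.min():.3f}, {truth.image.max():.3f}] (linear domain)")

roi = (slice(140, 180), slice(104, 136))  # mediastinum interior: flat
for dose in (1.0, 0.6, 0.5, 0.4):
    acq = AcquisitionConfig(dose_fraction=dose, seed=42)
    raw = simulate_acquisition(truth, acq)
    proc = preprocess(raw)
    clean = clean_display(truth, acq, proc)
    sigma = (proc.pixels - clean)[roi].std()
    print(f"dose fraction {dose:.1f}: display-domain flat-region noise "
          f"sigma = {sigma:.4f}")
print("\nNoise rises as the dose drops (~1/sqrt(dose)): this is the "
      "degradation the denoising engines must remove.")
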