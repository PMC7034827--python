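"""Run both denoising engines on a noisy phantom and compare them.

The conventional engine shrinks every pyramid band with one global
threshold; the new engine filters each band with non-local means driven
by the local noise sigma. On an image whose noise varies across space the
new engine removes a similar *fraction* of noise everywhere and keeps
edges sharper at the same overall noise suppression.
"""

import numpy as np

from radnoise import (AcquisitionConfig, NlmParams, PhantomConfig,
                      PyramidSpec, clean_display, denoise_conventional,
                      denoise_new, edge_preservation_index, generate_phantom,
                      preprocess, simulate_acquisition, ssim_psnr)

truth = generate_phantom(PhantomConfig(
    image_size=128, seed=3, nodules=(((0.35, 0.3), 6, 0.25),)))
acq = AcquisitionConfig(dose_fraction=0.5, seed=7)
proc = preprocess(simulate_acquisition(truth, acq))
clean = clean_display(truth, acq, proc)

spec = PyramidSpec(n_levels=3)
res_new = denoise_new(proc, spec=spec, nlm=NlmParams(2, 5, 0.8))
res_conv = denoise_conventional(proc, spec=spec)

roi = (slice(70, 90), slice(52, 68))
s_in = (proc.pixels - clean)[roi].std()
print(f"input:        flat noise {s_in:.4f}, "
      f"SSIM {ssim_psnr(clean, proc.pixels)[0]:.4f}")
for name, res in (("new engine", res_new), ("conventional", res_conv)):
    out = res.image.pixels
    s_out = (out - clean)[roi].std()
    ssim, psnr = ssim_psnr(clean, out)
    epi = edge_preservation_index(clean, out)
    print(f"{name:13s} flat noise {s_out:.4f} "
          f"({100 * (1 - s_out / s_in):.0f}% removed), SSIM {ssim:.4f}, "
          f"PSNR {psnr:.1f} dB, edge preservation {epi:.4f}")
print("\nBoth engines suppress noise; the adaptive one holds a higher "
      "edge-preservation index — boundaries survive the smoothing.")
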