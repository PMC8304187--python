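"""Render a synthetic PET phantom and inspect its planted regions.

The phantom carries a heterogeneous hot tumor, six vertebral bodies and a
homogeneous liver sphere on a low-uptake background — the geometry every
downstream measurement in this package operates on.
"""

import numpy as np

from petscore import PhantomSpec, generate_phantom

spec = PhantomSpec(heterogeneity=0.6, seed=7)
volume, truth = generate_phantom(spec)

print(f"volume shape {volume.shape}, spacing {volume.spacing} mm")
print(f"tumor: {truth.tumor_mask.sum()} voxels, "
      f"mean SUV {volume.data[truth.tumor_mask].mean():.2f} "
      f"(planted {spec.tumor_mean_suv})")
for k, mask in enumerate(truth.vertebra_masks, start=1):
    print(f"vertebra {k}: {mask.sum()} voxels, mean SUV "
          f"{volume.data[mask].mean():.2f} (planted {spec.vertebra_mean_suvs[k-1]})")
print(f"liver: mean SUV {volume.data[truth.liver_mask].mean():.2f} "
      f"(planted {spec.liver_mean_suv})")
print(f"background mean SUV "
      f"{volume.data[~(truth.tumor_mask | truth.liver_mask)].mean():.2f}")

# The measured means sit on the planted values up to the configured noise
# (SD 0.05 SUV); identical spec + seed reproduce the volume bit-for-bit.
v2, _ = generate_phantom(spec)
print("deterministic re-render identical:", bool(np.array_equal(volume.data, v2.data)))
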