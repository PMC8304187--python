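"""Delineate the tumor with Nestle's adaptive threshold and measure
bone-marrow and liver uptake.

threshold = 0.3 x (mean SUV of voxels > 70% of the lesion max) + background
mean; BM SUV averages the six vertebral 75%-isocontour means; BLR divides
BM SUV by the liver mean.
"""

from petscore import (
    PhantomSpec,
    default_background_shell,
    generate_phantom,
    measure_bone_marrow,
    nestle_threshold,
)

volume, truth = generate_phantom(PhantomSpec(heterogeneity=0.6, seed=7))

background = default_background_shell(volume, truth.tumor_mask)
seg = nestle_threshold(volume, truth.tumor_mask, background)
print(f"hot-voxel mean SUV : {seg.hot_mean:.2f}")
print(f"background mean SUV: {seg.background_mean:.2f}")
print(f"Nestle threshold   : {seg.threshold:.2f} "
      f"(= 0.3 x {seg.hot_mean:.2f} + {seg.background_mean:.2f})")
print(f"segmented tumor    : {seg.voxel_count} of {int(truth.tumor_mask.sum())} "
      "VOI voxels at or above the threshold")

marrow = measure_bone_marrow(volume, list(truth.vertebra_masks), truth.liver_mask)
print("per-vertebra SUV   :", [round(v, 2) for v in marrow.vertebra_suvs])
print(f"BM SUV             : {marrow.bm_suv:.3f} (mean of the six vertebrae)")
print(f"liver mean SUV     : {marrow.liver_suv:.3f}")
print(f"BLR                : {marrow.blr:.3f} (BM SUV / liver mean)")
# A BLR below 1 indicates marrow uptake below liver uptake, the usual state;
# values above 1 mark the hypermetabolic-marrow phenotype.
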