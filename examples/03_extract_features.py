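"""Extract the 41 imaging parameters of a segmented tumor.

4 conventional parameters, 6 first-order features and 31 higher-order
texture features (6 GLCM, 3 NGLDM, 11 GLRLM, 11 GLZLM) computed after
resampling the lesion SUVs into 64 relative grey levels.
"""

from petscore import (
    PhantomSpec,
    default_background_shell,
    extract_all,
    generate_phantom,
    nestle_threshold,
)
from petscore.radiomics import (
    CONVENTIONAL_NAMES,
    FIRST_ORDER_NAMES,
    HIGHER_ORDER_NAMES,
)

volume, truth = generate_phantom(PhantomSpec(heterogeneity=0.6, seed=7))
seg = nestle_threshold(
    volume, truth.tumor_mask, default_background_shell(volume, truth.tumor_mask)
)
features = extract_all(volume, seg.tumor_mask, levels=64)

print(f"{len(features)} features "
      f"({len(CONVENTIONAL_NAMES)} conventional / {len(FIRST_ORDER_NAMES)} "
      f"first-order / {len(HIGHER_ORDER_NAMES)} higher-order)\n")
for name in CONVENTIONAL_NAMES + FIRST_ORDER_NAMES:
    print(f"  {name:22s} {features[name]:10.4f}")
print("  ...")
for name in ("glcm_energy", "glcm_entropy", "glzlm_zlnu"):
    print(f"  {name:22s} {features[name]:10.4f}")

# TLG (g) is MTV (cm^3) times the mean lesion SUV — the metabolically
# weighted tumor burden; first-order entropy (bits) quantifies how evenly
# the lesion occupies its 64 relative grey levels (higher = more
# heterogeneous uptake).
print(f"\ncheck: TLG {features['tlg_g']:.2f} g over MTV {features['mtv_cm3']:.2f} cm^3")
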