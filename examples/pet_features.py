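"""PET radiomics on a synthetic FDG-avid lesion.

Builds an ellipsoidal lesion with correlated intensity texture, then
extracts SUVmax, histogram, GLCM and NGLDM features under absolute
resampling (64 bins over [0, 32] SUV, bin width 0.5).
"""

from heteroduo import PetConfig, PetSimParams, gen_pet_lesion, pet_feature_vector

for amplitude in (0.2, 2.0):
    params = PetSimParams(semi_axes_mm=(15.0, 12.0, 10.0), base_suv=8.0,
                          texture_amplitude=amplitude, seed=5)
    vol, voi, truth = gen_pet_lesion(params)
    feats = pet_feature_vector(vol, voi, PetConfig())
    print(f"\nlesion with texture amplitude {amplitude} SUV "
          f"({int(truth['n_voxels'])} voxels):")
    for name, value in feats.as_dict().items():
        print(f"  {name:>26}: {value:.4f}")

# Higher texture amplitude spreads the uptake over more SUV bins: histogram
# entropy rises, uniformity falls, GLCM entropy rises and NGLDM coarseness
# drops — the metabolically heterogeneous lesion scores "rougher" on every
# family of features.
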