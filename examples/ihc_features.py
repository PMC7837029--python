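"""Slide-level heterogeneity features from a synthetic stained section.

Generates a spatially correlated stained-ratio field with a right-skewed
Beta(2, 8) marginal, renders it as a brown-on-pink RGB slide, and runs the
full tile / rank / co-occurrence pipeline on the image.
"""

import numpy as np

from heteroduo import (
    IhcConfig,
    IhcSimParams,
    RoiMask,
    gen_ratio_field,
    ihc_feature_vector,
    render_slide,
)

params = IhcSimParams(grid_shape=(10, 10), tile_px=48, beta_a=2.0, beta_b=8.0,
                      correlation_length=1.5, seed=11)
field = gen_ratio_field(params)
slide, truth = render_slide(field, params)
print(f"slide: {slide.shape[0]}x{slide.shape[1]} px at "
      f"{slide.microns_per_pixel} um/px")

features = ihc_feature_vector(slide, RoiMask.full(slide), IhcConfig(tile_px=48))
for name, value in features.as_dict().items():
    print(f"  {name:>14}: {value:.4f}" if isinstance(value, float)
          else f"  {name:>14}: {value}")

# The skewness of the per-tile stained ratios should track the Beta(2, 8)
# marginal planted by the generator (analytic skewness ~0.83, positive =
# most tiles weakly stained with a bright tail); contrast and entropy
# summarize how abruptly neighboring tiles change staining level.
print(f"\nplanted field skewness: "
      f"{float(np.mean(((field - field.mean()) / field.std()) ** 3)):.3f}")
print(f"recovered image skewness: {features.skewness:.3f}")
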