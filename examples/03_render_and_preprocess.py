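"""Render a synthetic lamin-stained nucleus and run the conditioning chain.

The renderer produces a two-channel micrograph (nucleoplasmic fill +
peripheral lamin rim) with point-spread blur, noise and an illumination
gradient; pre-processing segments it via the HSV value channel, sharpens,
grayscales, removes the background and normalises the foreground. The
moment-based ellipse refit on the segmentation mask recovers the ground-truth
axes to within a few percent.
"""

import numpy as np

from nucdhl import (
    EllipseNucleus,
    RenderStyle,
    fit_ellipse,
    preprocess,
    render_nucleus,
)
from nucdhl.preprocessing import build_segmentation_mask

geom = EllipseNucleus(a=6.0, b=4.0, theta=0.9, label="cancer", stain="laminA")
image = render_nucleus(geom, RenderStyle(), seed=42)
print(f"rendered {image.width}x{image.height} image, "
      f"{image.n_channels} channels, pixel size {image.pixel_size} um")

mask = build_segmentation_mask(image)
refit = fit_ellipse(mask.astype(bool), image.pixel_size)
print(f"ground truth a={geom.a:.2f}, b={geom.b:.2f} um; "
      f"refit from mask a={refit.a:.2f}, b={refit.b:.2f} um")

clean = preprocess(image)
background = clean.pixels[~mask.astype(bool)]
print(f"preprocessed: background max = {background.max():.1f} (exactly zero), "
      f"foreground spans [{clean.pixels[mask.astype(bool)].min():.2f}, "
      f"{clean.pixels.max():.2f}]")
print("The background carries no signal after conditioning; only nuclear "
      "morphology remains for the encoder.")
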