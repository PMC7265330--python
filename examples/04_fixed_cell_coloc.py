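"""Auto-thresholded colocalization percentage on a two-channel 2D image.

Builds a pair of blob images with known overlap, then applies the
Costes-style downward threshold sweep and the thresholded Manders-style
overlap fraction, as used for fixed-cell immunofluorescence ROIs.
"""


import numpy as np

from kinetocoloc import Roi2D, coloc_percent_fixed, max_projection

# a small z-stack with idealized intensities: channel a blob fully inside
# the image, channel b blob shifted so half of a's blob overlaps it
stack_a = np.zeros((4, 32, 32))
stack_b = np.zeros((4, 32, 32))
stack_a[:, 12:20, 4:12] = 100.0
stack_b[:, 12:20, 8:16] = 100.0
a = max_projection(stack_a)
b = max_projection(stack_b)

roi = Roi2D.square_of_area(pixel_size=0.1, area_um2=4.2, origin=(6, 0))  # ~20x20 px
result = coloc_percent_fixed(a, b, roi)

print(f"ROI: {roi.height}x{roi.width} px = {roi.area:.2f} um^2")
print(f"colocalization: {result.percent:.1f}% "
      f"(thresholds a={result.threshold_a:.1f}, b={result.threshold_b:.1f}, "
      f"denominator={result.denominator})")
# ~50% of above-threshold reference (a) pixels coincide with above-threshold
# b pixels, matching the constructed half-overlap geometry.
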