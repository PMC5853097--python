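"""Digitise a scatter plot by template cross-correlation.

Renders a synthetic scatter figure with known coordinates, detects the
markers by normalized cross-correlation against a disc template, maps
pixel centers back to data units with a two-anchor axis calibration,
and reports the recovery error.
"""

import numpy as np

from fattyroc.figure_extract import (
    AxisCalibration,
    MarkerTemplate,
    detect_markers,
    disc_template,
    pixels_to_data,
    render_scatter,
)

rng = np.random.default_rng(3)
cal = AxisCalibration(
    x_anchors=((50.0, 0.0), (450.0, 10.0)),
    y_anchors=((450.0, 0.0), (50.0, 10.0)),
)
points = []
while len(points) < 30:
    cand = rng.uniform(0.5, 9.5, size=2)
    if all(np.hypot(*(cand - p)) > 0.6 for p in points):
        points.append(cand)
points = np.array(points)

image = render_scatter(points, cal, (500, 500), radius=4)
centers = detect_markers(image, MarkerTemplate(disc_template(4), threshold=0.8))
recovered = pixels_to_data(centers, cal)

errors = [min(np.hypot(*(recovered - p).T)) for p in points]
print(f"rendered {len(points)} markers, detected {len(centers)}")
print(f"max recovery error: {max(errors):.4f} data units "
      f"({max(errors) / (10 / 400):.2f} px)")
print("sub-pixel accuracy comes from the quadratic refinement of each")
print("correlation peak; real figures need user-supplied axis anchors.")
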