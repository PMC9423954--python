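"""Hand-eye calibration with height fine-tuning on a synthetic rig.

Fits the image->robot perspective map T from 13 base-plane reference
points and the height transform F from 13 points on a plane 1 cm higher,
then maps an image point seen on the 1 cm plane into robot millimetres
with and without the height correction.
"""

import numpy as np

from acupilot import (
    estimate_height_calibration,
    estimate_perspective,
    image_to_robot,
)
from acupilot.synth import generate_calibration_points, generate_scene

scene, _ = generate_scene(seed=0)
base, offset = generate_calibration_points(scene, n_base=13, n_offset=13,
                                           offset_cm=1.0, seed=0)

transform = estimate_perspective(base)
calibration = estimate_height_calibration(offset, offset_cm=1.0)

target_mm = np.array([35.0, -20.0])          # true robot coordinate
pixel = scene.world_plane_to_pixel(target_mm, height_mm=10.0)

corrected = image_to_robot(transform, calibration, pixel, 1.0)
uncorrected = image_to_robot(transform, calibration, pixel, 0.0)

print(f"target robot coordinate : ({target_mm[0]:.3f}, {target_mm[1]:.3f}) mm")
print(f"with height correction  : ({corrected[0]:.3f}, {corrected[1]:.3f}) mm "
      f"(error {np.linalg.norm(corrected - target_mm):.2e} mm)")
print(f"without correction      : ({uncorrected[0]:.3f}, {uncorrected[1]:.3f}) mm "
      f"(error {np.linalg.norm(uncorrected - target_mm):.3f} mm)")
print("-> ignoring a 1 cm height offset shifts the robot by about a "
      "millimetre; the fitted F transform removes it to numerical precision.")
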