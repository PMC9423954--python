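"""Pulse amplitude and PRV response to an acupuncture stimulation.

Generates two 5-minute wrist PPG recordings at 25 Hz: a baseline, and a
post-stimulation recording with 20% larger pulse amplitude and 50% more
high-frequency PP-interval power (the signature of increased
parasympathetic activity).  The analysis chain recovers both changes.
"""

import numpy as np

from acupilot import compare_pre_post
from acupilot.synth import generate_ppg

pre, _ = generate_ppg(duration_s=300, fs_hz=25, hr_bpm=60,
                      amplitude_mv=1.0, hf_mod=(0.25, 30.0), seed=1)
post, _ = generate_ppg(duration_s=300, fs_hz=25, hr_bpm=60,
                       amplitude_mv=1.2, hf_mod=(0.25, 30.0 * np.sqrt(1.5)),
                       seed=2)

result = compare_pre_post(pre, post, arm="laser+lift-thrust",
                          acupoint="Neiguan")

print(f"stimulation: {result.arm} at {result.acupoint}")
print(f"pulse amplitude : {result.pre_amplitude_mv:.3f} -> "
      f"{result.post_amplitude_mv:.3f} mV  "
      f"(delta {result.amplitude_delta_mv:+.3f} mV)")
print(f"PRV HF power    : {result.pre_hf_ms2:7.1f} -> "
      f"{result.post_hf_ms2:7.1f} ms^2 (delta {result.hf_delta_ms2:+.1f} ms^2)")
print("-> positive deltas indicate vasodilation and increased vagal "
      "modulation after the stimulation.")
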