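"""Simulate a particle stack and reconstruct it at the true poses.

Generates 300 projections of a blob phantom at SNR 0.1 with CTF, runs the
direct Fourier-inversion reconstruction with phase flipping, and reports the
FSC resolution against the known ground truth.  The 0.143 crossing tells you
the frequency up to which the reconstruction agrees with the truth.
"""

import numpy as np

from biaslab import (GeneratorConfig, fsc, generate_dataset, reconstruct,
                     resolution_at)

cfg = GeneratorConfig(n_particles=300, box=48, voxel_size=2.0, snr=0.1, seed=1)
stack, volumes = generate_dataset(cfg)
truth = volumes["class1"]
print(f"simulated {len(stack)} particles, box {stack.box}, SNR {stack.snr}")

rec = reconstruct(stack, ctf_mode="phase_flip")
curve = fsc(rec, truth)
r143 = resolution_at(curve, 0.143)
r05 = resolution_at(curve, 0.5)
print(f"FSC(reconstruction, truth) first shells: {np.round(curve.values[:8], 3)}")
for name, r in (("0.143", r143), ("0.5", r05)):
    label = f"{1 / r:.1f} A" if np.isfinite(r) else "no crossing"
    print(f"resolution at FSC={name}: {label}")
print("(higher frequency = finer detail; the 0.5 crossing is the conservative "
      "estimate)")
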