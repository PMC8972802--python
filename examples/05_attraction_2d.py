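"""The attraction problem in 2-D classification.

Classifies balanced two-class data at high and very low SNR with the
Euclidean metric.  At low SNR the class with more members develops a
cleaner background, wins more images, and the occupancies drift away from
50/50 -- the positive-feedback attraction instability.
"""

import numpy as np

from biaslab import classify2d
from biaslab.experiments import two_class_images

for snr in (1.0, 0.05):
    occs = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        imgs, _ = two_class_images(60, 32, snr, rng)
        res = classify2d(imgs, 2, metric="euclidean", n_iter=15, rng=seed)
        occs.append(res.occupancies[-1].max())
    print(f"SNR {snr}: final max class occupancy per seed = {np.round(occs, 3)}"
          f" (mean {np.mean(occs):.3f})")
print("(0.5 means a clean balanced split; larger values mean one class is "
      "attracting images it does not own)")
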