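"""Segment and track nuclei on a synthetic movie, then score the linking.

Enhancement (anisotropic diffusion + derivative sum), Otsu thresholding,
seeded-watershed splitting, and distance-minimizing frame linking.
"""

import numpy as np

from locreset import segmentation as seg
from locreset import tracking
from locreset.synthetic import SceneConfig, generate_monolayer_movie

cfg = SceneConfig(shape=(10, 1, 256, 256), n_cells=10, read_noise_sd=5.0,
                  step_sigma_px=1.5, seed=7)
movie, gt = generate_monolayer_movie(cfg)
stain = movie.channel("stain")

label_maps = []
for t in range(cfg.shape[0]):
    enhanced = seg.enhance(stain[t, 0])
    label_maps.append(seg.segment_2d(enhanced, intensity=stain[t, 0]))

tracks = tracking.link(label_maps, gate=15.0)
n_full = sum(len(tr) == cfg.shape[0] for tr in tracks)
print(f"nuclei per frame: {[lm.n_labels for lm in label_maps]}")
print(f"tracks: {len(tracks)}, full-length: {n_full}/{cfg.n_cells}")

# compare tracked centroids to ground truth for the first track
tr = tracks[0]
gt_pos = gt.tracks.set_index(["frame", "cell"])
errs = []
for f, c in zip(tr.frames, tr.centroids):
    sub = gt_pos.loc[f]
    errs.append(np.hypot(sub["y"] - c[0], sub["x"] - c[1]).min())
print(f"track 1 centroid error vs ground truth: "
      f"mean {np.mean(errs):.2f} px")
# 10 tracks of full length with sub-pixel centroid error indicate correct
# segmentation and identity-preserving linking.
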