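"""Generate a small corpus of synthetic endoscopy scenes.

Each scene is a triplet: composite (with highlights), clean background
(ground truth) and the planted-core mask, plus a JSON config sidecar —
everything needed to benchmark a highlight-removal method offline.
"""

from pathlib import Path

import endoclear as ec
from endoclear.synthetic import save_scene

out_dir = Path(__file__).parent / "scene_corpus"
for seed in range(3):
    cfg = ec.SceneConfig(seed=seed, n_spots=6)
    scene = ec.generate_scene(cfg)
    paths = save_scene(scene, out_dir, f"scene{seed:03d}")
    print(f"seed {seed}: {scene.truth_mask.count()} highlight px -> {len(paths)} files")
print(f"corpus written to {out_dir}")
# Re-running with the same seeds reproduces the corpus byte-for-byte.
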