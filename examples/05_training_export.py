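"""Export paired image/label volumes for training a voxel classifier.

Each pair is a noisy fluorescence image plus its exact 3-class annotation
map (background / cell interior / cell boundary) with density and SBR drawn
at random; the JSON manifest records everything needed to regenerate any
volume bit-for-bit.
"""
import json
import tempfile
from pathlib import Path

from biofilm3d.config import PipelineConfig
from biofilm3d.pipeline import export_training_set

cfg = PipelineConfig(seed=11)
cfg.arrangement.max_cells = 40
out = Path(tempfile.mkdtemp()) / "training"
manifest = export_training_set(2, cfg, out)
print(f"wrote {manifest['n_volumes']} image/label pairs to {out}")
for vol in manifest["volumes"]:
    print(f"  {vol['image']}: {vol['n_cells']} cells, "
          f"target SBR {vol['target_sbr']:.2f}, "
          f"density {vol['achieved_density']}")
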