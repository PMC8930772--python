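"""Train the embedding segmentation network on synthetic brightfield.

Trains the residual U-Net (seed map + bandwidth + offsets) with the
soft-mask Dice objective on freshly generated 128-px training scenes,
and writes checkpoint.npz plus the per-step loss trace under
results/run.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import demo_config

from dropseg.pipeline import stage_train

cfg = demo_config()
ckpt = stage_train(cfg)
trace = pd.read_csv(Path(cfg.out_dir) / "training_log.csv")
val = pd.read_csv(Path(cfg.out_dir) / "validation_log.csv")
print(f"checkpoint: {ckpt}")
print(
    f"loss {trace['total'].iloc[0]:.3f} -> {trace['total'].iloc[-1]:.3f} "
    f"over {len(trace)} steps; best validation loss "
    f"{val['val_loss'].min():.3f} at step {int(val.loc[val['val_loss'].idxmin(), 'step'])}"
)
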