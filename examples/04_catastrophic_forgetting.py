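"""Sequential learning: frozen wiring forgets catastrophically, plastic
wiring saturates gracefully.

Two networks store the same kind of memory blocks one after the other.  The
static network (weight plasticity only) retrieves everything until its
capacity is exceeded, then loses all blocks at once.  The structurally
plastic network consolidates each block into dedicated synapses: early
blocks stay retrievable forever, and only the ability to store new blocks
fades as the migratable synapse pool is used up.

Runs the two canonical 25-block protocols (~20 s total).
"""

import numpy as np

from plastinet import ExperimentConfig, run_block_learning

static = ExperimentConfig.blocks_static_defaults(seed=0, eval_stride=5)
plastic = ExperimentConfig.blocks_structural_defaults(seed=0, eval_stride=5)

for name, cfg in (("frozen structure", static), ("structural plasticity", plastic)):
    rec = run_block_learning(cfg)
    eps = np.round(rec.final_eps(), 2)
    print(f"\n{name}: final output noise per block (block 1 oldest)")
    print("  ", eps)
    retained = int((rec.final_eps() <= cfg.retained_threshold).sum())
    print(f"  blocks retained (eps <= {cfg.retained_threshold}): "
          f"{retained} / {cfg.n_blocks}")
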