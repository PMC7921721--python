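"""Working-memory recall: memorize a three-symbol sequence, replay it.

Builds the working-memory circuit alone, presents the sequence (1, 2, 5)
with Poisson-encoded stimulation, and then delivers only the start signal.
The STDP-formed synaptic chain replays the sequence, decoded by strict
majority firing of the symbol populations.
"""

import numpy as np

from spikeseq.architecture import build_wmc
from spikeseq.config import ExperimentConfig
from spikeseq.protocol import (
    reset_wmc,
    run_memory_stage,
    run_recall_probe,
)

cfg = ExperimentConfig()
rng = np.random.default_rng(0)
net = build_wmc(cfg, rng)

seq = (1, 2, 5)
reset_wmc(net, rng)
run_memory_stage(net, seq, cfg)

# chain weights after the memory stage
def mean_weight(pre, post):
    return net.find_groups(pre_pop=pre, post_pop=post)[0].w.mean()

print(f"memorized sequence: {seq}")
print("mean chain weights after STDP:")
print(f"  begin->sym1 {mean_weight('begin','sym1'):5.1f}   sym1->sym2 {mean_weight('sym1','sym2'):5.1f}   sym2->sym5 {mean_weight('sym2','sym5'):5.1f}")
print(f"  sym2->sym1  {mean_weight('sym2','sym1'):5.1f}   sym1->sym5 {mean_weight('sym1','sym5'):5.1f}   (reverse/skip stay near zero)")

net.run(cfg.timing.delay)
decoded = run_recall_probe(net, cfg)
print(f"replayed sequence : {decoded}")
# Only the presented order was wired into the chain, so the start signal
# alone regenerates the sequence.
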