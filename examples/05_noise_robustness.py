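"""Population coding protects recall against background noise.

Measures recall accuracy of the memory circuit for population sizes
C = 1, 30 and 60 under Gaussian background current, a small version of the
robustness sweep.
"""

import numpy as np

from spikeseq.config import ExperimentConfig
from spikeseq.evaluation import population_size_sweep

cfg = ExperimentConfig()
rng = np.random.default_rng(0)
table = population_size_sweep(
    cfg, c_values=[1, 30, 60], sigma2_grid=[0.0, 36.0], n_trials=15, rng=rng
)
print(table.to_string(index=False))
# Accuracy grows with the population size C: small populations cannot
# deliver enough synaptic drive to sustain the replay chain at all, while
# 60-neuron populations recall reliably; their advantage over C = 1
# persists across the noise grid (the full sweep uses more trials and
# stronger noise to map the degradation).
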