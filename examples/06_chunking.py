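"""Chunking a six-symbol sequence into two three-symbol chunks.

Builds the chunked network (two working-memory units sharing one
reinforcement-learning circuit), trains the repeat grammar, and produces a
six-symbol sequence chunk by chunk.
"""

import numpy as np

from spikeseq.architecture import build_network
from spikeseq.config import ExperimentConfig
from spikeseq.protocol import chunk_sequence, run_chunked_trial, train

cfg = ExperimentConfig.model_validate({"sequence_length": 6, "chunking": True})
rng = np.random.default_rng(0)
net = build_network(cfg, rng)
print(f"working-memory units: {len(net.meta['units'])}  shared RLC positions: {net.meta['n_positions']}")

net, curve = train(net, "repeat", 80, cfg, rng)  # 80 shaping trials suffice here

seq = (1, 2, 5, 3, 6, 4)
print(f"sequence : {seq}  chunks: {chunk_sequence(seq, 3)}")
trial = run_chunked_trial(net, seq, "repeat", cfg, rng)
print(f"produced : {trial.output_seq}   correct: {trial.correct}")
# Each chunk is memorized into its own unit and produced immediately, so
# replay timing errors cannot accumulate across more than three symbols.
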