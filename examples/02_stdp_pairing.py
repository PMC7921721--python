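"""The STDP pairing kernel and reward-modulated eligibility traces.

Prints the weight increment for a few pre/post spike-time differences, then
shows how an eligibility trace buffers a pairing until a reward converts it
into weight change.
"""

import numpy as np

from spikeseq.plasticity import (
    STDPParams,
    SynapseGroup,
    apply_rstdp,
    stdp_delta,
    update_eligibility,
)

params = STDPParams()  # A+=4, A-=0.95, tau_s=15 ms, tau_w=10 ms
print("pairing kernel (delta_t = t_post - t_pre):")
for dt in (2.0, 5.0, 9.0, -5.0, 12.0):
    print(f"  delta_t {dt:+5.1f} ms -> dw {stdp_delta(dt, params):+.3f}")
# Positive differences (pre leads) potentiate, negative depress, and nothing
# happens outside the +-10 ms pairing window.

group = SynapseGroup(w=np.zeros((1, 1)), mode="rstdp",
                     params=STDPParams(w_min=0.0, w_max=20.0))
inc = group.pairing_increments(np.array([0]), np.array([], dtype=int), 10.0)
inc = group.pairing_increments(np.array([], dtype=int), np.array([0]), 15.0)
update_eligibility(group, inc, 1.0)
print(f"\neligibility after a +5 ms pairing : {group.trace.e[0,0]:.3f}")
for _ in range(100):  # one tenth of a second passes before the reward
    update_eligibility(group, None, 1.0)
print(f"eligibility 100 ms later          : {group.trace.e[0,0]:.3f}")
for _ in range(5):  # reward window T_R = 5 steps, R = +10
    apply_rstdp(group, 10.0, 1.0, eta=0.01)
print(f"weight after the reward window    : {group.w[0,0]:.3f}")
# The pairing alone never moved the weight; only the reward did.
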