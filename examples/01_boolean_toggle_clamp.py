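"""Boolean clamp protocol on the toggle switch.

Builds the canonical two-gene toggle switch (A and B mutually inhibiting,
each self-activating, A the epithelial marker), finds a low-frustration
epithelial start state, clamps B on for 400 unit times at pseudo-temperature
0.5, then quenches and reports how often the run ends mesenchymal.
"""

import numpy as np

import grnclamp as gc

topo, anno = gc.make_toggle_switch()
J = gc.interaction_matrix(topo)
vec = anno.vector(topo)
cfg = gc.BooleanConfig(T=0.5, t_c=400, frustration_max=0,
                       e_score_start_min=1, m_score_end_max=-1)
rng = np.random.default_rng(0)

wins = 0
n_runs = 100
for _ in range(n_runs):
    s0 = gc.find_initial_state(J, vec, 0.5, cfg, rng)
    out = gc.run_clamp_protocol(s0, J, vec, gc.ClampSpec({"B": 1}), cfg,
                                rng, topo)
    wins += out.success

print(f"start state: {gc.find_initial_state(J, vec, 0.5, cfg, rng)} "
      f"(epithelial corner, frustration 0)")
print(f"clamp B on for t_c=400 at T=0.5, quench at T=0.5 for 10 units")
print(f"successful transitions: {wins}/{n_runs} "
      f"({100.0 * wins / n_runs:.0f}%)")
print("a success means the quenched state has epithelial score below the "
      "mesenchymal threshold, i.e. the network latched into the M corner")
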