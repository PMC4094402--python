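"""Simulate a profiled inhibitor library and a two-cell-line screen.

Generates 140 drugs profiled on 291 kinases and a screen of 140 drug-pair
treatments whose viabilities follow the multiplicative model, then prints
the most selective treatments (those sparing normal cells relative to
cancer cells).
"""

import numpy as np

from kinresp import SimulationConfig, simulate_activity_matrix, simulate_screen

config = SimulationConfig(seed=0)  # 140 drugs x 291 kinases, 140 pairs
profiles = simulate_activity_matrix(config)
screen, truth = simulate_screen(profiles, config, cell_lines=("IMR90", "A549"))

print(f"library : {profiles.n_drugs} drugs x {profiles.n_kinases} kinases")
print(f"screen  : {len(screen)} treatments on {screen.cell_lines}")
print(f"truth   : {len(truth['A549']['active_kinases'])} active kinases per line")

# selectivity S = v_N / v_C; S > 1 means the pair spares normal cells
S = screen.selectivity_vector("IMR90", "A549")
order = np.argsort(-S)[:5]
print("\ntop 5 selective treatments (S = v_IMR90 / v_A549):")
for i in order:
    rec = screen.records[i]
    print(
        f"  {str(rec.treatment):16s} S = {S[i]:5.2f}  "
        f"(v_N = {rec.viability['IMR90']:.3f}, v_C = {rec.viability['A549']:.3f})"
    )
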