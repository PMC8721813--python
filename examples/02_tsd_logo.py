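"""Composition-adjusted TSD logo: does the transposase care where it lands?

Plants 200 copies under a bias model that prefers A at TSD positions 6
and 7 (p = 0.8), rediscovers them, and scores the recovered target sites
against the genome composition in bits of relative entropy.
"""

import numpy as np

from tsdscan import (
    Background,
    BiasModel,
    default_element,
    discover,
    element_end_query,
    genome_composition,
    plant_insertions,
    simulate_genome,
)

te = default_element()
genome = simulate_genome(600_000, seed=7)
bias = BiasModel.single_base_bias([5, 6], "A", 0.8)  # 0-based rows 5,6 = positions 6,7
genome, truths = plant_insertions(genome, te, 200, bias=bias, seed=7)

report = discover([genome], element_end_query(te))
background = genome_composition([genome])
profile = report.tsd_logo(background)

print(f"TSD-valid insertions: {report.n_tsd_valid}")
print("pos  D_i(bits)  p(A)")
for i in range(8):
    print(f"{i + 1:>3}  {profile.kl_bits[i]:>9.3f}  {profile.freqs.p[i, 0]:.3f}")
# Positions 6-7 carry ~0.5-0.9 bits of information (the planted A bias);
# the other six positions sit near 0 bits, i.e. indistinguishable from the
# genome composition -- the signature of a low-specificity transposase
# everywhere except the biased positions.
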