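"""Closed-network attractor analysis of a controller.

Clamps the receptor input of an isolated CTRNN to its two realizable
values — 0 (no contact) and r (sustained contact, after the receptor
gain) — and inventories the attracting fixed points from many random
initial states.  A controller whose closed dynamics hold a single
attractor that shifts with the input realizes its behavioral complexity
relationally: the richness lives in the sensorimotor loop, not inside
the network.
"""

import numpy as np

from mimicry import Genotype, attractor_scan, attractor_shift, decode

params = decode(Genotype(np.random.default_rng(5).random(84)))
scan = attractor_scan(params, [0.0, params.r], n_starts=50, seed=0,
                      step_budget=200_000)

for value, result in scan.items():
    label = "no contact" if value == 0 else f"contact (I = r = {value:.2f})"
    print(f"clamped input {label}: {len(result.equilibria)} attractor(s), "
          f"{result.n_converged}/{result.n_starts} starts converged")
    for eq in result.equilibria:
        print(f"  basin {eq.basin_fraction:5.0%}  residual {eq.residual:.2e}  "
              f"outputs {np.round(eq.o, 3)}")

sets = list(scan.values())
print(f"\nattractor shift between input conditions: {attractor_shift(sets[0], sets[1]):.3f} "
      "(distance in state space)")
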