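"""Simulate one coupled two-agent trial and print its basic readouts.

Uses an arbitrary (non-evolved) controller: the point here is the trial
machinery — initialization, the sense/update/act loop, and the recorded
series — not solved behavior.
"""

import numpy as np

from mimicry import Genotype, TrialConfig, decode, run_trial

params = decode(Genotype(np.random.default_rng(5).random(84)))
config = TrialConfig(steps=3000, seed=42)
record = run_trial(config, params)

print(f"realized perturbations: u1 = {record.u1:+.3f} (RF1), u2 = {record.u2:+.3f} (D1)")
print(f"initial body offset D1+D2 : {record.u2:+.3f}")
print(f"final body offset         : {record.offset[-1]:+.3f}")
print(f"steps with contact (A1/A2): {record.contacts[:, 0].mean():.1%} / "
      f"{record.contacts[:, 1].mean():.1%}")
print(f"clicks (A1 L/R, A2 L/R)   : {record.clicks[:, 0, 0].sum()}/"
      f"{record.clicks[:, 0, 1].sum()}  {record.clicks[:, 1, 0].sum()}/"
      f"{record.clicks[:, 1, 1].sum()}")
# The body offset is the task's order parameter: 0 means the two agents'
# receptor-to-body link distances are complementary (mimicry); an untrained
# controller typically leaves it near its initial value.
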