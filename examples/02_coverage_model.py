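"""Lander-Waterman coverage expectations vs simulated pileups.

At 1.6x mean depth a Poisson model predicts ~80% of bases see at least
one read and ~47% see at least two; this script checks the closed form
against simulated read counts.
"""

import numpy as np

from exlwgs import reads

c = 1.6
for k in (1, 2, 3):
    p = reads.prob_depth_at_least(c, k)
    print(f"P(depth >= {k}) at {c}x = {100 * p:5.1f}%")

pile = reads.simulate_pileups(
    np.zeros((10, 20_000), dtype=np.int8), np.full(10, c), 0.005, seed=1
)
emp = [(pile.depth >= k).mean() for k in (1, 2, 3)]
print("empirical:", " ".join(f"{100 * e:5.1f}%" for e in emp))
# The ~47% two-read figure is the coverage budget that makes joint
# population-level calling (rather than per-sample calling) essential at
# this depth.
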