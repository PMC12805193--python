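"""User-defined cannot-link constraints.

The bounded-coloring machinery behind the dispersion solver separates any
explicit list of forbidden pairs — or reports that no partition can.
"""

import numpy as np

from anticlustering import InfeasibleConstraintsError, satisfy_cannot_link

rng = np.random.default_rng(0)

part = satisfy_cannot_link([(0, 1), (2, 3), (0, 4)], N=8, K=2, sizes=[4, 4], rng=rng)
print("assignment:", part.assignment)
for a, b in [(0, 1), (2, 3), (0, 4)]:
    print(f"  objects {a} and {b} separated:", part.assignment[a] != part.assignment[b])

try:
    satisfy_cannot_link([(0, 1), (0, 2), (0, 3)], N=4, K=2, sizes=[2, 2], rng=rng)
except InfeasibleConstraintsError as exc:
    print("infeasible as expected:", exc)
# Object 0 cannot avoid all three others when its group must hold two
# objects: a pigeonhole infeasibility the solver certifies exactly.
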