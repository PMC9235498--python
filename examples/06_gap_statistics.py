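"""Gap and match-block statistics implied by the three-state machine.

The machine's self-transition probabilities make match blocks and gaps
geometric random variables, subsuming the classical affine gap penalty:
Pr(m|m) sets the expected match-block length 1/(1-Pr(m|m)) and the
gap-open probability 1-Pr(m|m); Pr(i|i) sets the expected gap length.
The expected amino-acid change of a base matrix traces divergence over time.
"""

import numpy as np

from mmlsub import expected_change, expected_run_length, random_reversible_base

p_mm, p_ii = 0.9958, 0.8759
print(f"Pr(m|m) = {p_mm}: expected match block = {expected_run_length(p_mm):.0f} residues")
print(f"          gap-open probability = {1 - p_mm:.4f}")
print(f"Pr(i|i) = {p_ii}: expected gap length = {expected_run_length(p_ii):.0f} residues")

M = random_reversible_base(np.random.default_rng(0), change=0.01)
print("\nexpected change under a 1%-unit base matrix:")
for t in (1, 10, 50, 150, 400, 1000):
    print(f"  t = {t:4d}: {100 * expected_change(M, t):5.1f}%")
# the curve rises from 1% at unit time toward the stationary plateau where
# residues are effectively randomized.
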