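"""Convert a published log-odds scoring matrix to a unit-time Markov matrix.

BLOSUM62 scores are half-bit log-odds.  Given background amino-acid
frequencies, the scores invert to a conditional-probability matrix C; the
integer matrix root C^(1/k) closest to 1% expected change then puts the
matrix on the common divergence-time scale, so divergence times inferred
under it are comparable with those of any other converted matrix.
"""

import numpy as np
from Bio.Align import substitution_matrices

from mmlsub import (
    RESIDUES,
    ScoringMatrix,
    expected_change,
    find_unit_root,
    scoring_to_conditional,
)

# background frequencies: here the MML multinomial estimate from a synthetic
# collection's indel regions stands in for the frequencies a real alignment
# collection would supply (the handling used when a matrix does not publish
# its own frequencies)
from mmlsub import GeneratorSpec, generate_benchmark, multinomial_mml_estimate
from mmlsub.alignments import state_counts

bench, _, _, _ = generate_benchmark(GeneratorSpec(n_pairs=50, seed=1))
indel_totals = sum(state_counts(p).indel_counts for p in bench)
freqs = multinomial_mml_estimate(indel_totals)

blosum = substitution_matrices.load("BLOSUM62")
scores = np.array([[blosum[a, b] for b in RESIDUES] for a in RESIDUES])
scoring = ScoringMatrix(scores, scale=0.5, base=2.0, name="BLOSUM62")

C = scoring_to_conditional(scoring, freqs)
print(f"expected change of C itself: {expected_change(C, 1):.4f}")

M, k = find_unit_root(C, target=0.01, k_max=1000)
print(f"k-th root bringing C to the 1% unit: k = {k}")
print(f"expected change of M(1): {expected_change(M, 1):.4f}")
# C represents a deep divergence (tens of percent expected change); the k-th
# root is the one-time-unit matrix whose k-step composition reproduces it.
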