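"""Recover per-pair divergence times from alignments alone.

Pairs are simulated at known times on the discrete grid; encoding them under
the generator matrix infers each pair's time as the grid value minimizing
its total message (time + machine parameters + alignment string + residues).
Inferred times should track the truth closely when pairs carry enough
matched columns.
"""

import numpy as np
from scipy.stats import spearmanr

from mmlsub import GeneratorSpec, benchmark_information, generate_benchmark

spec = GeneratorSpec(
    n_pairs=40,
    seed=8,
    t_distribution=lambda rng: int(rng.integers(30, 451)),
    length_distribution=lambda rng: 350,
)
bench, truth, M, _ = generate_benchmark(spec)
bd = benchmark_information(bench, M)

rho = spearmanr(bd.times, truth.t).statistic
err = np.abs(bd.times - truth.t)
print("pair        true t   inferred t")
for pid, tt, ti in list(zip(truth.id, truth.t, bd.times))[:8]:
    print(f"{pid}  {tt:6d}   {ti:6d}")
print(f"...\nSpearman rho(truth, inferred) = {rho:.3f} over {len(bench)} pairs")
print(f"median |error| = {np.median(err):.0f} time units")
# rho near 1 means the encoder orders pairs by divergence almost perfectly;
# absolute errors grow at large t where the substitution signal saturates.
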