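# mmlsub — minimum message length models of amino-acid substitution

`mmlsub` evaluates and infers amino-acid substitution models by lossless
compression of pairwise protein alignments.  It is aimed at people who build
or compare substitution matrices (PAM/BLOSUM-style scoring tables, Markov
models for phylogenetics) and want an objective, parameter-free yardstick:
the matrix that lets you transmit a collection of alignments in the fewest
bits is the best explanation of that collection.

## The model

A collection *D* = {⟨A₁,S₁,T₁⟩, …} of sequence pairs with three-state
alignment strings (match **m**, insert **i**, delete **d**) is encoded as a
two-part message whose length, in bits, is

    I(H,D) = I(M) + I(P) + I(α)
           + Σᵢ [ I(tᵢ) + I(Θᵢ|α,tᵢ) + I(Aᵢ|Θᵢ) + I(⟨Sᵢ,Tᵢ⟩|Aᵢ,M,P,tᵢ) ]

with the following components:

- **M** — a 20×20 column-stochastic Markov matrix; M(t) = Mᵗ via the
  eigendecomposition S Λᵗ S⁻¹.  Unit time is fixed by convention at 1%
  expected residue change under the stationary distribution π (the
  eigenvector of eigenvalue 1), so divergence times are comparable across
  matrices.  Matched residues cost −log₂ P(a) − log₂ M(t)[b|a] per column.
- **P** — a multinomial background over the 20 amino acids for residues in
  gapped regions, estimated by the MML multinomial rule
  (nᵢ + ½)/(N + K/2) from the collection's indel regions.
- **Θ** — a symmetric three-state machine generating the alignment string,
  with three free parameters {Pr(m|m), Pr(i|i), Pr(m|i)}; match blocks and
  gaps are geometric, so the machine subsumes affine gap penalties
  (expected block length 1/(1−Pr(m|m)), gap-open probability 1−Pr(m|m)).
- **α(t)** — per-time-bin Dirichlet priors (a 1-simplex and a 2-simplex)
  over Θ, learnt from the collection, which let gap behaviour vary with
  divergence time.
- **tᵢ** — each pair's divergence time, inferred by exhaustive search over
  the discrete grid t ∈ {1,…,1000} and transmitted with the log-star code.

Continuous parameters are costed with the Wallace–Freeman (MML87) statement
length −log₂ h(η) + ½log₂ det F(η) + (d/2)log₂ κ_d + d/(2 ln 2).

On top of the encoder the package provides: conversion of published
log-odds scoring matrices to this representation (via the integer matrix
root C^(1/k) nearest 1% expected change), ranking of matrices across
benchmarks by ranksum of encoding totals, simulated-annealing inference of
the optimal matrix for a collection, and a forward simulator that generates
benchmarks with known ground truth.

## Worked example

```python
from mmlsub import GeneratorSpec, benchmark_information, generate_benchmark

spec = GeneratorSpec(n_pairs=100, seed=42)       # known matrix, times, machine
bench, truth, M, P = generate_benchmark(spec)
bd = benchmark_information(bench, M)
print(f"{bd.total:.1f} bits in {bd.rounds} rounds")
```

prints `261494.2 bits in 10 rounds`, decomposed as (run
`python examples/02_evaluate_benchmark.py`):

```
I(M)        =     2414.7 bits   (matrix statement)
I(P)        =       80.3 bits   (background multinomial)
I(alpha)    =      164.2 bits   (time-binned Dirichlet priors)
sum I(t)    =     1393.4 bits   (divergence times)
sum I(Th)   =      275.9 bits   (machine parameters)
sum I(A)    =    14232.2 bits   (alignment strings)
sum I(S,T)  =   242933.6 bits   (residues)
```

The residue term dominates, as it should: the models are a small fixed
overhead and the data pays for itself.  Encoding the same benchmark under a
perturbed or uniform matrix costs thousands of bits more
(`examples/04_rank_matrices.py`), which is exactly how matrices are ranked.

The `examples/` directory holds one short script per capability: scoring
matrix conversion, benchmark evaluation, divergence-time recovery, matrix
ranking, annealing inference, and gap statistics.  A thin CLI mirrors them:
`mmlsub simulate|evaluate|compare|convert|infer-matrix|infer-time`.

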