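# Methods

## Model overview and assumptions

The package treats a collection of pairwise protein alignments as data to
be transmitted losslessly and scores substitution models by the resulting
two-part message length.  The generative reading is: each pair has a
divergence time t on a discrete grid; a three-state machine emits the
alignment string; matched columns draw a source residue from the background
multinomial P and a target residue from column a of M(t); indel columns
draw a single residue from P.  Assumptions worth stating explicitly:

- **Markov substitution.**  Residue evolution is a homogeneous Markov chain
  over the 20 canonical amino acids; site independence; no rate
  heterogeneity across sites.  Non-standard residue codes (B, Z, X, U, O)
  are rejected at parse time rather than silently recoded, so encoding
  totals stay comparable across inputs.
- **Column-stochastic convention.**  Entry (i, j) of M is Pr(j → i); every
  column is L1-normalized.  All tables are read and written in the fixed
  residue order `ARNDCQEGHILKMFPSTWYV`.
- **Unit time.**  t = 1 is defined as 1% expected residue change, where the
  expectation weights the diagonal of M by the stationary distribution π of
  M itself.  π is the self-consistent choice (it is invariant under
  powering, so the time semantics do not drift with t); weighting by
  dataset frequencies instead would make the unit depend on the collection.
- **Symmetric indels.**  Insert and delete are exchangeable in the machine,
  leaving three free transition probabilities; out-of-i and out-of-d counts
  are pooled before estimation.
- **Directional match encoding.**  Match columns condition the target
  residue on the source residue (S → T).  A `symmetrize_match` flag
  averages both directions; it is off by default, and because the same
  convention is applied to every matrix under comparison the rankings are
  unaffected by the choice.

## Statement lengths

All code lengths are in bits; natural-log formulations are converted once,
centrally (`mml.LN2`).

- **Continuous parameters** use the Wallace–Freeman (MML87) form
  −log₂ h(η) + ½ log₂ det F(η) + (d/2) log₂ κ_d + d/(2 ln 2), with the
  exact quantizing-lattice constants κ₁ = 1/12, κ₂ = 5/(36√3),
  κ₃ = 19/(192·2^{1/3}).  The per-pair machine statement uses d = 3 with
  the factorized Fisher determinant
  [N_m/(p_mm(1−p_mm))]·[N_id²/(p_ii p_mi p_di)] and the product of the two
  bin Dirichlet densities as prior.  Pairs with no gaps carry no
  information about the indel simplex, so the statement degrades gracefully
  to the 1-simplex block (d = 1), and symmetrically.
- **K = 20 multinomial statements** (the 20 columns of I(M), and I(P)) have
  19 free parameters, beyond the exact lattice constants; these use the
  asymptotic constant κ_d → 1/(2πe) with a uniform Dirichlet prior and the
  standard multinomial Fisher determinant N^{K−1}/Π pᵢ.  I(M)'s per-column
  observation counts come from the benchmark's matched pairs grouped by
  source residue; columns never observed cost nothing.  Because this
  structure is identical for every matrix being compared, it shifts totals
  but never rankings.
- **Dirichlet hyperparameters α** are transmitted to fixed precision 0.01
  under a log-uniform density on [0.01, 10³]: a small, simple cost for a
  handful of shared components.
- **Integer times** use the log-star universal code (c = 2.865064).  It is
  proper (Kraft sum ≤ 1), parameter-free, and penalizes large t by only
  log₂ t + O(log log t) bits, which is the mild preference for small times
  one wants when the likelihood is nearly flat in t.
- **The initial alignment state** is coded uniformly (log₂ 3 bits); no
  initial distribution is modeled.

The MML87 multinomial estimate (nᵢ + ½)/(N + K/2) and its Dirichlet-prior
generalization (nᵢ + αᵢ − ½)/(N + Σα − K/2) are exact minimizers of the
corresponding statement-plus-data lengths; the test suite probes this local
optimality directly and checks the 1-parameter statement against a
brute-force discretized two-part code (offset-averaged over grid placement,
so no grid centre coincidentally lands on the estimate).

## Encoder iteration

`benchmark_information` alternates: (1) estimate P (from indel regions by
default; stationary-π or user-supplied frequencies selectable), (2) infer
every pair's time by exhaustive grid search with Θ re-estimated per
candidate time from its bin's prior, (3) refit the time-binned Dirichlets
from the inferred (t, Θ) pairs.  The loop stops when the total moves by
less than 1 bit, or after 10 rounds; everything is deterministic given the
inputs.  Powers M(t) for the whole grid are precomputed by repeated
multiplication (numerically safe for any valid matrix; the eigendecomposition
path in `power` is cross-checked against repeated multiplication in tests).
Time bins are 10 grid units wide, merged rightward until each holds at
least 30 pairs; a collection too small for any bin falls back to one global
bin.  The exact per-t inference scheme is an open design point — binning
trades resolution in t for stable Dirichlet fits.

## Scoring-matrix conversion

Published log-odds matrices are inverted to conditional form via
q_ij = f_i f_j · base^(s_ij·scale), column-normalized, then brought to the
1% time unit by searching integer k ∈ [1, 1000] for the root C^{1/k}
(principal branch through one eigendecomposition) whose expected change is
nearest 0.01, ties toward smaller k.  Matrix roots of empirical matrices
need not be elementwise non-negative: small negative entries are clipped to
zero and columns renormalized, with the clipped mass logged; a root that is
materially complex (clipped mass > 10⁻³ per column) is an error rather than
a silent repair.  Background frequencies must be supplied for matrices that
do not publish them (the MML estimate from the collection's indel regions
is the natural source).

## Dirichlet fitting

Maximum likelihood via Minka's digamma fixed point
α_k ← ψ⁻¹(ψ(Σα) + ⟨log x_k⟩), moment-matching initialization, tolerance
10⁻⁸ on successive α, at most 1000 iterations, with an explicit
non-convergence error.  ML (rather than MML) per bin is deliberate: α is
shared across the whole collection, so its statement is a small constant
that cannot affect the ranking of matrices evaluated with the same scheme.
Degenerate bins (too few or zero-variance samples) fall back to a weak
mean-matching prior with a warning.

## Annealing search

`infer_matrix` starts from the collection's own matched-pair conditional
frequencies (MML multinomial estimates per column) rooted to the 1% unit.
Proposals move a Uniform(0, 0.05·entry) amount of mass between two entries
of one random column, preserving column stochasticity and non-negativity by
construction.  Acceptance is Metropolis on the change in total message
length, where per-pair times and machine parameters are frozen between
refreshes; every 500 accepted moves (configurable) the matrix is re-rooted
to the 1% unit and the encoder's inner loop re-optimizes the nuisance
models — an alternating optimization whose refresh cadence trades fidelity
for speed.  The initial temperature is calibrated so the expected
acceptance rate over 200 sampled proposals is 0.8 (solved on the sampled
uphill deltas — the delta distribution is heavy-tailed, so a mean-based
calibration would overheat the chain); cooling multiplies T by 0.98 every
100 proposals; the search stops after 2000 proposals without a cumulative
>1-bit improvement of the best total.  The trace records the running
minimum of genuine totals, so the best-seen curve is non-increasing by
construction, and the whole run is bit-reproducible from the seed.  These
schedule defaults are recorded choices, not derived quantities.

## Synthetic benchmarks

The generator is the model read forwards.  Defaults define the study
conditions: a seeded random reversible base matrix at 1% expected change
(built from a symmetric exchangeability matrix and a Dirichlet-drawn
stationary distribution, then scaled by root-finding on the expected
change; reversibility gives a real positive spectrum, so powers have exact
integer roots — the property the unit-root round-trip studies rely on);
background P = the matrix's stationary distribution; machine parameters
θ(t) with Pr(m|m) = 0.9958 for t ≤ 40 declining linearly to ≈0.923 at
t = 300 and gently beyond, and Pr(i|i) rising from ≈0.52 to a 0.8759
plateau (expected gaps of ~8 residues); times uniform on [20, 400]; pair
lengths geometric with mean 300 columns (long enough for time recovery,
small enough for desk-scale tests).

What the generator does *not* emulate: site-rate heterogeneity,
composition drift across families, alignment errors from structural
aligners, and the length/identity distributions of real curated benchmarks.
Passing recovery tests therefore demonstrates internal consistency of
inference under the model's own assumptions, not performance on real
structural alignments.

## Problem sizes and numerical notes

Tests run the encoder on benchmarks of 40–300 pairs and the annealing
search on 50–200 pairs with reduced stall limits (400–600 proposals
without improvement); these sizes were chosen so the whole suite stays at
desk scale while leaving each recovery signal far above its tolerance.
Probabilities are floored at 10⁻³⁰⁰ before logs; matrix entries at 10⁻³⁰
inside Fisher determinants; machine-parameter estimates are clamped to the
open simplex at 10⁻¹⁰.  Ties in the unit-root search break toward smaller
k; ties in ranksum columns take average ranks with a warning.

## Known limitations

- The encoder's inner loop is a coordinate descent over (τ, Θ, α, P); it is
  deterministic and monotone in practice but not guaranteed to find the
  joint optimum.
- Matrices with zero entries are only usable when the corresponding residue
  pairs never occur; converted published matrices are strictly positive.
- `mml87_length` is restricted to ≤ 3 free parameters by design; larger
  blocks go through the multinomial statement.
- Alignment *search* (aligning unaligned pairs) is out of scope; inputs are
  given alignments.
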