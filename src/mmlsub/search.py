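"""Simulated-annealing inference of the MML-optimal substitution matrix.

Starting from the benchmark's own matched-pair conditional frequencies
(brought to the 1%-change time unit by the matrix-root conversion), single
columns of the evolving matrix are perturbed in their near-neighbourhood
and each proposal is accepted or rejected by the Metropolis criterion on
the change in total message length.  Per-pair times and machine parameters
are held fixed between periodic refreshes, at which the full encoder inner
loop re-optimizes them for the current matrix — an alternating optimization
of the matrix and the nuisance models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignments import Benchmark
from .encoder import (
    EncoderConfig,
    _BenchStats,
    _matrix_statement_length,
    benchmark_information,
)
from .matrices import StochasticMatrix, find_unit_root
from .mml import multinomial_mml_estimate
from .residues import N_RESIDUES

_TINY = 1e-300


@dataclass
class AnnealConfig:
    """Schedule of the annealing search.

    ``t0=None`` calibrates the initial temperature so that roughly 80% of
    the first proposals would be accepted.  ``stall_limit`` counts proposals
    without a >1 bit improvement of the best-seen total.
    """

    seed: int
    t0: float | None = None
    cooling: float = 0.98
    cool_every: int = 100
    perturb_mag: float = 0.05
    stall_limit: int = 2000
    refresh_every: int = 500
    calibration_proposals: int = 200
    target_accept: float = 0.8
    max_proposals: int = 200_000

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling must be in (0, 1)")
        if not (0.0 < self.perturb_mag <= 0.05):
            raise ValueError("perturb_mag must be in (0, 0.05]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def perturb_column(
    M: StochasticMatrix, rng: np.random.Generator, perturb_mag: float = 0.05
) -> StochasticMatrix:
    """Move a small amount of mass between two entries of one random column."""
    entries = M.entries.copy()
    j = int(rng.integers(M.n))
    src, dst = rng.choice(M.n, size=2, replace=False)
    delta = rng.uniform(0.0, perturb_mag * entries[src, j])
    entries[src, j] -= delta
    entries[dst, j] += delta
    return StochasticMatrix(entries, labels=M.labels)


def metropolis_accept(
    delta_bits: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept downhill moves always, uphill with probability exp(-Δ/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_bits <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_bits / temperature))


class _FrozenObjective:
    """Eq.-2 total as a function of M with times, thetas, α and P frozen.

    Only the matched-residue term and I(M) depend on M; match counts are
    aggregated per inferred time so that each evaluation costs one pass of
    repeated matrix powers over the distinct times.
    """

    def __init__(self, stats: _BenchStats, breakdown):
        self.match_total = stats.match_flat.sum(axis=0)
        times = np.asarray(breakdown.times)
        self.t_sorted = np.unique(times)
        self.cnt_t = {
            int(t): stats.match_flat[times == t].sum(axis=0) for t in self.t_sorted
        }
        self.const = 0.0  # set by _build_frozen once match_bits(M) is known

    def match_bits(self, M: StochasticMatrix) -> float:
        bits = 0.0
        cur = None
        prev_t = 0
        for t in self.t_sorted:
            t = int(t)
            if cur is None:
                cur = np.linalg.matrix_power(M.entries, t)
            else:
                cur = cur @ np.linalg.matrix_power(M.entries, t - prev_t)
            prev_t = t
            bits += float(self.cnt_t[t] @ (-np.log2(np.maximum(cur, _TINY)).ravel()))
        return bits

    def __call__(self, M: StochasticMatrix) -> float:
        return self.const + self.match_bits(M) + _matrix_statement_length(M, self.match_total)


def _build_frozen(stats: _BenchStats, benchmark: Benchmark, M: StochasticMatrix,
                  enc_config: EncoderConfig):
    bd = benchmark_information(benchmark, M, enc_config)
    frozen = _FrozenObjective(stats, bd)
    # const = total minus the parts the objective recomputes, evaluated at M
    frozen.const = bd.total - frozen.match_bits(M) - bd.i_matrix
    return frozen, bd


def infer_matrix(
    benchmark: Benchmark,
    config: AnnealConfig,
    enc_config: EncoderConfig | None = None,
) -> tuple[StochasticMatrix, pd.DataFrame]:
    """Infer the substitution matrix minimizing the benchmark's message length.

    Returns the best-seen matrix and a trace DataFrame with one row per
    proposal (temperature, current and best totals).  Deterministic given
    ``config.seed``.
    """
    if len(benchmark) == 0:
        raise ValueError("empty benchmark")
    enc_config = enc_config or EncoderConfig()
    rng = np.random.default_rng(config.seed)
    stats = _BenchStats(benchmark, symmetrize=enc_config.symmetrize_match)

    # initial matrix: MML multinomial estimates of the matched-pair
    # conditional counts, rooted to ~1% expected change
    match_total = stats.match_flat.sum(axis=0).reshape(N_RESIDUES, N_RESIDUES)
    C = np.stack(
        [multinomial_mml_estimate(match_total[:, j]) for j in range(N_RESIDUES)], axis=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        M, _k = find_unit_root(StochasticMatrix(C), target=0.01)

    frozen, bd = _build_frozen(stats, benchmark, M, enc_config)
    current = frozen(M)
    best_val, best_M = current, M

    # temperature calibration on proposals from the start point: choose T so
    # the expected acceptance rate over sampled proposals hits target_accept
    if config.t0 is None:
        uphill = []
        cal_rng = np.random.default_rng(rng.integers(2**31))
        for _ in range(config.calibration_proposals):
            cand = perturb_column(M, cal_rng, config.perturb_mag)
            d = frozen(cand) - current
            if d > 0:
                uphill.append(d)
        if uphill:
            d = np.array(uphill)
            n_all = config.calibration_proposals

            def accept_rate(T: float) -> float:
                return float((n_all - len(d)) + np.exp(-d / T).sum()) / n_all

            lo, hi = 1e-9, float(d.max()) * 10.0
            if accept_rate(hi) < config.target_accept:
                temperature = hi
            else:
                for _ in range(200):
                    mid = math.sqrt(lo * hi)
                    if accept_rate(mid) < config.target_accept:
                        lo = mid
                    else:
                        hi = mid
                temperature = hi
        else:
            temperature = 1.0
    else:
        temperature = config.t0
    temperature = max(temperature, 1e-12)

    trace = []
    stall = 0
    accepted = 0
    mark = best_val  # best value at the last stall reset
    for proposal in range(1, config.max_proposals + 1):
        cand = perturb_column(M, rng, config.perturb_mag)
        cand_val = frozen(cand)
        if metropolis_accept(cand_val - current, temperature, rng):
            M, current = cand, cand_val
            accepted += 1
            if accepted % config.refresh_every == 0:
                # re-root to the 1% time unit and re-optimize nuisances
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    M, _ = find_unit_root(M, target=0.01)
                frozen, bd = _build_frozen(stats, benchmark, M, enc_config)
                current = frozen(M)
        if not np.isfinite(current):
            raise RuntimeError(
                f"non-finite objective at proposal {proposal}; matrix min entry "
                f"{M.entries.min():g}"
            )
        if current < best_val:
            best_val, best_M = current, M
        if best_val < mark - 1.0:
            stall = 0
            mark = best_val
        else:
            stall += 1
        trace.append((proposal, temperature, current, best_val))
        if proposal % config.cool_every == 0:
            temperature = max(temperature * config.cooling, 1e-12)
        if stall >= config.stall_limit:
            break

    trace_df = pd.DataFrame(trace, columns=["proposal", "temperature", "current", "best"])
    return best_M, trace_df
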