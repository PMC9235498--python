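"""Minimum message length primitives.

All code lengths are in bits.  The Wallace–Freeman (MML87) statement length
for a model with ``d`` free continuous parameters is

    I(η) = -log2 h(η) + (1/2) log2 det F(η) + (d/2) log2 κ_d + d / (2 ln 2)

where ``h`` is the prior density, ``F`` the (expected) Fisher information,
and ``κ_d`` the optimal quantizing-lattice constant in dimension ``d``.
Integer parameters (the divergence times) are transmitted with the log-star
universal code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

LN2 = math.log(2.0)

#: Optimal quantizing-lattice constants for dimensions 1-3.
KAPPA = {
    1: 1.0 / 12.0,
    2: 5.0 / (36.0 * math.sqrt(3.0)),
    3: 19.0 / (192.0 * 2.0 ** (1.0 / 3.0)),
}

#: Asymptotic lattice constant, lim_{d->inf} κ_d = 1/(2 π e); used for d > 3.
KAPPA_INF = 1.0 / (2.0 * math.pi * math.e)

#: Normalizing constant of the log-star code, Σ_t 2^{-log*(t)} = 1.
LOG_STAR_C = 2.865064


def multinomial_mml_estimate(counts) -> np.ndarray:
    """MML estimate of multinomial probabilities from counts over K >= 2 states.

    ``p_i = (n_i + 1/2) / (N + K/2)``: strictly positive and summing to 1
    even for empty cells.
    """
    counts = np.asarray(counts, dtype=float)
    K = counts.shape[-1]
    if K < 2:
        raise ValueError(f"need at least 2 states, got K={K}")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    p = (counts + 0.5) / (counts.sum(axis=-1, keepdims=True) + K / 2.0)
    return p / p.sum(axis=-1, keepdims=True)


@dataclass
class MML87Terms:
    """Additive pieces of a Wallace–Freeman statement, all in bits."""

    neg_log2_prior: float
    half_log2_fisher_det: float
    n_free: int
    neg_log2_likelihood: float

    def __post_init__(self):
        if self.n_free < 0:
            raise ValueError("n_free must be >= 0")


def lattice_constant(d: int) -> float:
    """Quantizing-lattice constant κ_d (exact for d <= 3, asymptotic beyond)."""
    if d <= 0:
        raise ValueError("dimension must be positive")
    return KAPPA.get(d, KAPPA_INF)


def mml87_length(terms: MML87Terms) -> float:
    """Total MML87 two-part message length in bits.

    Supports 0-3 free parameters, which covers every statement the alignment
    model makes per pair (the K=20 multinomial statements go through
    :func:`multinomial_statement_length` instead).
    """
    d = terms.n_free
    if d == 0:
        return terms.neg_log2_prior + terms.half_log2_fisher_det + terms.neg_log2_likelihood
    if d > 3:
        raise ValueError(f"n_free={d} unsupported here (use multinomial_statement_length)")
    const = (d / 2.0) * math.log2(KAPPA[d]) + d / (2.0 * LN2)
    return (
        terms.neg_log2_prior
        + terms.half_log2_fisher_det
        + const
        + terms.neg_log2_likelihood
    )


def multinomial_statement_length(probs, n_obs: float) -> float:
    """MML87 cost in bits of stating a K-state multinomial parameter vector.

    Uses a uniform Dirichlet(1, ..., 1) prior (density (K-1)! on the
    simplex) and the multinomial Fisher determinant ``N^(K-1) / Π p_i``.
    Returns 0 when there are no observations (nothing needs stating: the
    receiver can decode no data with it).
    """
    p = np.asarray(probs, dtype=float)
    K = p.shape[0]
    if K < 2:
        raise ValueError("need at least 2 states")
    if n_obs <= 0:
        return 0.0
    d = K - 1
    p = np.maximum(p, 1e-30)
    neg_log2_prior = -gammaln(K) / LN2
    half_log2_fisher = 0.5 * (d * math.log2(n_obs) - np.log2(p).sum())
    const = (d / 2.0) * math.log2(lattice_constant(d)) + d / (2.0 * LN2)
    return float(neg_log2_prior + half_log2_fisher + const)


def integer_code_length(t: int) -> float:
    """Log-star universal code length for a positive integer, in bits.

    ``log2 c + log2 t + log2 log2 t + ...`` over the positive iterates,
    with ``c = 2.865064`` making the implied probabilities sum to 1.
    """
    if t < 1 or not float(t).is_integer():
        raise ValueError(f"t must be a positive integer, got {t!r}")
    bits = math.log2(LOG_STAR_C)
    x = math.log2(t)
    while x > 0:
        bits += x
        x = math.log2(x) if x > 1 else 0.0
    return bits


def integer_code_lengths(t_max: int) -> np.ndarray:
    """Vector of log-star code lengths for ``t = 1..t_max`` (index t-1)."""
    return np.array([integer_code_length(t) for t in range(1, t_max + 1)])
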