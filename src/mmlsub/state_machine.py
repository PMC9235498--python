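"""Symmetric three-state alignment machine and its time-binned Dirichlet priors.

The machine walks over states {m, i, d}.  Treating insert and delete
symmetrically leaves three free transition probabilities,
``Pr(m|m), Pr(i|i), Pr(m|i)``; the remaining six follow:

    Pr(i|m) = Pr(d|m) = (1 - Pr(m|m)) / 2
    Pr(d|i) = Pr(i|d) = 1 - Pr(i|i) - Pr(m|i)
    Pr(d|d) = Pr(i|i),   Pr(m|d) = Pr(m|i)

Match-block and gap lengths are geometric, with expectations
``1 / (1 - Pr(m|m))`` and ``1 / (1 - Pr(i|i))``.  The free parameters are
given per-divergence-time Dirichlet priors — a 1-simplex Dirichlet for
``Pr(m|m)`` and a 2-simplex Dirichlet for ``(Pr(i|i), Pr(m|i))`` — fitted
per time bin from the alignment collection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import digamma, gammaln, polygamma

from .alignments import PairCounts
from .mml import LN2, MML87Terms, mml87_length

_EPS = 1e-10


@dataclass(frozen=True)
class MachineParams:
    """The three free transition probabilities of the symmetric machine."""

    p_mm: float
    p_ii: float
    p_mi: float

    def __post_init__(self):
        if not (0.0 < self.p_mm <= 1.0):
            raise ValueError(f"p_mm must be in (0, 1], got {self.p_mm}")
        if not (0.0 < self.p_ii < 1.0):
            raise ValueError(f"p_ii must be in (0, 1), got {self.p_ii}")
        if not (0.0 < self.p_mi < 1.0):
            raise ValueError(f"p_mi must be in (0, 1), got {self.p_mi}")
        if self.p_ii + self.p_mi > 1.0:
            raise ValueError(
                f"p_ii + p_mi = {self.p_ii + self.p_mi:g} > 1 leaves Pr(d|i) negative"
            )

    @property
    def p_di(self) -> float:
        return 1.0 - self.p_ii - self.p_mi


class ThetaFit(NamedTuple):
    """Estimate of machine parameters plus prior-fallback flags."""

    theta: MachineParams
    match_from_prior: bool
    indel_from_prior: bool


class BinAlpha(NamedTuple):
    """Dirichlet parameters of one time bin."""

    alpha_match: np.ndarray  # 2 components for (p_mm, 1 - p_mm)
    alpha_indel: np.ndarray  # 3 components for (p_ii, p_mi, p_di)


def complete_parameters(free: MachineParams) -> np.ndarray:
    """Full 3x3 transition table (rows = from-state, order m, i, d).

    Rows sum to 1 by construction and the insert/delete symmetry is exact.
    """
    q = (1.0 - free.p_mm) / 2.0
    p_di = 1.0 - free.p_ii - free.p_mi
    return np.array(
        [
            [free.p_mm, q, q],
            [free.p_mi, free.p_ii, p_di],
            [free.p_mi, p_di, free.p_ii],
        ]
    )


def expected_run_length(p_self: float) -> float:
    """Expected length of a geometric run with self-transition ``p_self``.

    ``1 / (1 - p_self)``: e.g. a match self-transition of 0.9958 sustains
    blocks of ~238 matches, and a gap self-transition of 0.8759 gaps of ~8.
    """
    if not (0.0 < p_self < 1.0):
        raise ValueError(f"p_self must be in (0, 1), got {p_self}")
    return 1.0 / (1.0 - p_self)


def alignment_encoding_length(states: str, theta: MachineParams) -> float:
    """Bits to transmit a three-state string under the completed machine.

    ``log2 3`` for the initial state (uniform) plus ``-log2 Pr(next|prev)``
    per transition.
    """
    table = complete_parameters(theta)
    idx = {"m": 0, "i": 1, "d": 2}
    st = np.array([idx[c] for c in states], dtype=np.int8)
    bits = math.log2(3.0)
    if len(st) > 1:
        probs = table[st[:-1], st[1:]]
        if (probs <= 0.0).any():
            k = int(np.argmax(probs <= 0.0))
            raise ValueError(
                f"transition {states[k]}->{states[k + 1]} has probability 0"
            )
        bits += float(-np.log2(probs).sum())
    return bits


# ---------------------------------------------------------------------------
# estimation under a Dirichlet prior


def _pooled_counts(transitions: np.ndarray):
    """(n_mm, n_m_out, pooled indel count triple (self, to-m, cross), N_id)."""
    T = np.asarray(transitions)
    n_mm = float(T[..., 0, 0])
    n_m_out = float(T[..., 0, :].sum(-1))
    n_self = float(T[..., 1, 1] + T[..., 2, 2])
    n_to_m = float(T[..., 1, 0] + T[..., 2, 0])
    n_cross = float(T[..., 1, 2] + T[..., 2, 1])
    return n_mm, n_m_out, np.array([n_self, n_to_m, n_cross]), n_self + n_to_m + n_cross


def estimate_theta(counts: PairCounts, alpha: BinAlpha) -> ThetaFit:
    """MML87 posterior estimate of the machine parameters for one pair.

    For the 1-simplex (out-of-m) block,
    ``p_mm = (n_mm + a1 - 1/2) / (n_m + a1 + a2 - 1)``; the 2-simplex block
    pools out-of-i and out-of-d counts under the i<->d symmetry and uses the
    analogous ``(n_k + a_k - 1/2) / (N + Σa - 3/2)``.  Blocks with no
    observations fall back to the prior mean (flagged).
    """
    am = np.asarray(alpha.alpha_match, dtype=float)
    ai = np.asarray(alpha.alpha_indel, dtype=float)
    n_mm, n_m_out, pooled, n_id = _pooled_counts(counts.transitions)

    match_prior = n_m_out == 0
    if match_prior:
        p_mm = am[0] / am.sum()
    else:
        p_mm = (n_mm + am[0] - 0.5) / (n_m_out + am.sum() - 1.0)
    p_mm = float(np.clip(p_mm, _EPS, 1.0 - _EPS))

    indel_prior = n_id == 0
    if indel_prior:
        p3 = ai / ai.sum()
    else:
        p3 = (pooled + ai - 0.5) / (n_id + ai.sum() - 1.5)
    p3 = np.clip(p3, _EPS, None)
    p3 = p3 / p3.sum()
    # keep p_di > 0 after completion
    p3 = np.clip(p3, _EPS, 1.0 - 2 * _EPS)
    p3 = p3 / p3.sum()

    theta = MachineParams(p_mm=p_mm, p_ii=float(p3[0]), p_mi=float(p3[1]))
    return ThetaFit(theta, match_prior, indel_prior)


def _dirichlet_log2pdf(alpha: np.ndarray, x: np.ndarray) -> float:
    alpha = np.asarray(alpha, dtype=float)
    x = np.clip(np.asarray(x, dtype=float), 1e-300, None)
    ln = gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(x)).sum()
    return float(ln / LN2)


def theta_statement_length(theta: MachineParams, counts: PairCounts, alpha: BinAlpha) -> float:
    """MML87 cost in bits of stating the machine parameters for one pair.

    Prior = product of the two Dirichlet densities at ``theta``; Fisher
    determinant factorizes as ``[N_m / (p_mm (1-p_mm))] ·
    [N_id^2 / (p_ii p_mi p_di)]`` with 3 free parameters.  When a block has
    no observations its parameters need not be stated and the statement
    degrades to the remaining block.
    """
    _, n_m_out, _, n_id = _pooled_counts(counts.transitions)
    p_di = theta.p_di
    for name, v in (("p_mm", theta.p_mm), ("p_ii", theta.p_ii),
                    ("p_mi", theta.p_mi), ("p_di", p_di)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"boundary parameter {name}={v:g}: statement length undefined")

    neg_prior = 0.0
    half_fisher = 0.0
    d = 0
    if n_m_out > 0:
        neg_prior -= _dirichlet_log2pdf(alpha.alpha_match, [theta.p_mm, 1.0 - theta.p_mm])
        half_fisher += 0.5 * math.log2(n_m_out / (theta.p_mm * (1.0 - theta.p_mm)))
        d += 1
    if n_id > 0:
        neg_prior -= _dirichlet_log2pdf(alpha.alpha_indel, [theta.p_ii, theta.p_mi, p_di])
        half_fisher += 0.5 * math.log2(n_id**2 / (theta.p_ii * theta.p_mi * p_di))
        d += 2
    if d == 0:
        return 0.0
    return mml87_length(
        MML87Terms(
            neg_log2_prior=neg_prior,
            half_log2_fisher_det=half_fisher,
            n_free=d,
            neg_log2_likelihood=0.0,
        )
    )


# ---------------------------------------------------------------------------
# Dirichlet fitting (maximum likelihood, Minka fixed point)


def _inv_digamma(y: np.ndarray) -> np.ndarray:
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(8):
        x = x - (digamma(x) - y) / polygamma(1, x)
        x = np.maximum(x, 1e-12)
    return x


def fit_dirichlet(
    samples, simplex_dim: int | None = None, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Maximum-likelihood Dirichlet parameters from points on a simplex.

    Digamma fixed-point iteration: ``α_k <- ψ^-1(ψ(Σα) + mean log x_k)``,
    stopping when successive α change by less than ``tol``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("samples must be a 2-D array of simplex points")
    if simplex_dim is not None and x.shape[1] != simplex_dim + 1:
        raise ValueError(
            f"samples have {x.shape[1]} components, expected {simplex_dim + 1}"
        )
    if x.shape[0] < 5:
        raise ValueError(f"need at least 5 samples, got {x.shape[0]}")
    if (x <= 0).any() or (x >= 1).any():
        raise ValueError("samples must be strictly interior simplex points")
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    if (var < 1e-14).any():
        raise ValueError("degenerate samples: zero variance in some component")
    log_mean = np.log(x).mean(axis=0)
    # moment-matching initialization
    s = mean[0] * (1.0 - mean[0]) / var[0] - 1.0
    alpha = np.maximum(mean * max(s, 1e-3), 1e-3)
    for it in range(max_iter):
        new = _inv_digamma(digamma(alpha.sum()) + log_mean)
        if np.max(np.abs(new - alpha)) < tol:
            return new
        alpha = new
    raise RuntimeError(
        f"Dirichlet fit did not converge in {max_iter} iterations; "
        f"last α = {alpha}, last step = {np.max(np.abs(new - alpha)):g}"
    )


# ---------------------------------------------------------------------------
# time-binned Dirichlet sets


@dataclass
class TimeDirichletSet:
    """Per-time-bin Dirichlet parameters over the machine's two simplices.

    ``bins`` are contiguous inclusive integer intervals covering
    ``[1, t_max]``; lookup resolves a time to its containing bin.
    """

    bins: list[tuple[int, int]]
    alpha_match: list[np.ndarray]
    alpha_indel: list[np.ndarray]

    def __post_init__(self):
        if not self.bins:
            raise ValueError("need at least one bin")
        for (a, b), (c, _) in zip(self.bins, self.bins[1:]):
            if c != b + 1:
                raise ValueError(f"bins not contiguous at {(a, b)} -> {c}")
        for arr in list(self.alpha_match) + list(self.alpha_indel):
            if (np.asarray(arr) <= 0).any():
                raise ValueError("all Dirichlet components must be positive")

    def bin_index(self, t: int) -> int:
        if t < self.bins[0][0]:
            return 0
        for k, (a, b) in enumerate(self.bins):
            if a <= t <= b:
                return k
        return len(self.bins) - 1

    def lookup(self, t: int) -> BinAlpha:
        k = self.bin_index(t)
        return BinAlpha(self.alpha_match[k], self.alpha_indel[k])

    @classmethod
    def uniform(cls, t_max: int = 1000) -> "TimeDirichletSet":
        """A single global bin with uniform priors on both simplices."""
        return cls([(1, t_max)], [np.ones(2)], [np.ones(3)])

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("# bin_start\tbin_end\talpha_mm\talpha_mq\talpha_ii\talpha_mi\talpha_di\n")
            for (a, b), am, ai in zip(self.bins, self.alpha_match, self.alpha_indel):
                vals = "\t".join(f"{v:.17g}" for v in np.concatenate([am, ai]))
                fh.write(f"{a}\t{b}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "TimeDirichletSet":
        bins, ams, ais = [], [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split("\t")
                bins.append((int(f[0]), int(f[1])))
                vals = np.array([float(v) for v in f[2:7]])
                ams.append(vals[:2])
                ais.append(vals[2:])
        return cls(bins, ams, ais)


_FALLBACK_CONC = 2.0


def _fit_bin(points: np.ndarray, k: int) -> np.ndarray:
    """Fit one simplex's α for a bin, falling back to a weak mean-matching prior."""
    if len(points) >= 5:
        try:
            return fit_dirichlet(points)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"Dirichlet fit fell back to mean-matching prior: {exc}",
                          stacklevel=2)
    mean = points.mean(axis=0) if len(points) else np.full(k, 1.0 / k)
    mean = np.clip(mean, 1e-3, None)
    return mean / mean.sum() * k * _FALLBACK_CONC


def fit_time_dirichlets(
    times,
    thetas,
    t_max: int = 1000,
    bin_width: int = 10,
    min_samples: int = 30,
) -> TimeDirichletSet:
    """Fit per-time-bin Dirichlet priors from per-pair times and parameters.

    Bins of ``bin_width`` cover ``[1, t_max]``; bins holding fewer than
    ``min_samples`` pairs are merged rightward (a trailing remainder merges
    into the last full bin).  A collection too small for any bin yields a
    single global bin with a warning.
    """
    times = np.asarray(times, dtype=int)
    match_pts = np.array([[th.p_mm, 1.0 - th.p_mm] for th in thetas])
    indel_pts = np.array([[th.p_ii, th.p_mi, th.p_di] for th in thetas])
    match_pts = np.clip(match_pts, 1e-9, 1.0 - 1e-9)
    indel_pts = np.clip(indel_pts, 1e-9, 1.0 - 1e-9)
    match_pts /= match_pts.sum(axis=1, keepdims=True)
    indel_pts /= indel_pts.sum(axis=1, keepdims=True)

    if len(times) < min_samples:
        warnings.warn(
            f"only {len(times)} pairs: using a single global Dirichlet bin", stacklevel=2
        )
        edges = [(1, t_max)]
    else:
        raw = [(a, min(a + bin_width - 1, t_max)) for a in range(1, t_max + 1, bin_width)]
        edges = []
        start, count = raw[0][0], 0
        for a, b in raw:
            count += int(((times >= a) & (times <= b)).sum())
            if count >= min_samples:
                edges.append((start, b))
                start, count = b + 1, 0
        if start <= t_max:
            if edges:
                edges[-1] = (edges[-1][0], t_max)
            else:
                edges = [(1, t_max)]

    ams, ais = [], []
    for a, b in edges:
        mask = (times >= a) & (times <= b)
        ams.append(_fit_bin(match_pts[mask], 2))
        ais.append(_fit_bin(indel_pts[mask], 3))
    return TimeDirichletSet(edges, ams, ais)
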