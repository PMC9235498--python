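"""Stochastic substitution matrices: powering, conversion and analysis.

A substitution model is a column-stochastic Markov matrix ``M`` over the 20
amino acids, entry ``(i, j)`` being ``Pr(residue j -> residue i)`` in one
discrete time step.  The unit of time is fixed by convention: ``t = 1`` is
the time over which 1% of residues are expected to change, where the
expectation is taken under the stationary distribution of ``M``.  Powers
``M(t) = M^t`` are computed through the cached eigendecomposition
``S Λ^t S^-1``.

Published log-odds scoring matrices (BLOSUM, VTML, PFASUM, ...) can be
converted back to conditional-probability form given their scale and
background frequencies, and then brought onto the common time scale by
numerically extracting the integer matrix root ``C^(1/k)`` closest to 1%
expected change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import brentq

from .residues import RESIDUES, N_RESIDUES, residue_index

logger = logging.getLogger(__name__)

_COLSUM_TOL = 1e-9
_EIG_TOL = 1e-6


class StochasticMatrix:
    """Column-stochastic Markov matrix with a cached eigendecomposition.

    Parameters
    ----------
    entries:
        Square non-negative array; every column must sum to 1 within 1e-9.
        Entry ``(i, j)`` is the probability of state ``j`` becoming state
        ``i`` in one step.
    labels:
        State labels; defaults to the canonical amino-acid order for
        20-state matrices.
    """

    def __init__(self, entries, labels: str | None = None):
        entries = np.asarray(entries, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError(f"matrix must be square, got shape {entries.shape}")
        if (entries < -1e-12).any():
            i, j = np.unravel_index(int(np.argmin(entries)), entries.shape)
            raise ValueError(f"negative entry {entries[i, j]:g} at ({i}, {j})")
        entries = np.maximum(entries, 0.0)
        colsums = entries.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=_COLSUM_TOL, rtol=0.0):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"column {j} sums to {colsums[j]:.12g}, not 1 within {_COLSUM_TOL:g}"
            )
        self.entries = entries
        self.entries.setflags(write=False)
        self.n = entries.shape[0]
        if labels is None and self.n == N_RESIDUES:
            labels = RESIDUES
        self.labels = labels
        self._eig = None

    # -- eigendecomposition ------------------------------------------------

    def eig(self):
        """``(eigvals, S, S_inv)`` of the matrix, cached.

        Verifies on first use that the spectral radius is 1 within 1e-6
        (a property every valid stochastic matrix has).  ``S_inv`` is None
        for defective matrices whose eigenbasis is singular.
        """
        if self._eig is None:
            lam, S = np.linalg.eig(self.entries)
            if abs(np.max(np.abs(lam)) - 1.0) > _EIG_TOL:
                raise ValueError(
                    f"largest-magnitude eigenvalue {np.max(np.abs(lam)):.8g} "
                    "differs from 1; not a valid stochastic matrix"
                )
            try:
                Sinv = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                Sinv = None
            self._eig = (lam, S, Sinv)
        return self._eig

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"StochasticMatrix(n={self.n})"


@dataclass
class ScoringMatrix:
    """A published substitution scoring matrix in linearly scaled log-odds form.

    ``odds(i, j) = base ** (scores[i, j] * scale)``: e.g. BLOSUM62 scores are
    half-bit log-odds, ``base=2, scale=0.5``.
    """

    scores: np.ndarray
    scale: float
    base: float = 2.0
    background_freqs: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError(f"scores must be square, got {self.scores.shape}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.background_freqs is not None:
            f = np.asarray(self.background_freqs, dtype=float)
            if abs(f.sum() - 1.0) > 1e-6:
                raise ValueError(f"background frequencies sum to {f.sum():g}, not 1")
            self.background_freqs = f / f.sum()


# ---------------------------------------------------------------------------
# analysis


def stationary_distribution(M: StochasticMatrix) -> np.ndarray:
    """Stationary distribution π of ``M``: the eigenvector of eigenvalue 1.

    Raises ``ValueError`` when eigenvalue 1 is not simple (e.g. the identity
    or a reducible matrix), since π is then not unique.
    """
    lam, S, _ = M.eig()
    close = np.abs(lam - 1.0) < 1e-8
    n_unit = int(close.sum())
    if n_unit == 0:
        # eig() guarantees spectral radius 1; fall back to the largest
        close = np.abs(lam - 1.0) < 1e-6
        n_unit = int(close.sum())
    if n_unit != 1:
        raise ValueError(
            f"eigenvalue 1 is not simple ({n_unit} eigenvalues within tolerance); "
            "the stationary distribution is not unique (degenerate or reducible matrix)"
        )
    v = S[:, int(np.argmax(close))]
    if np.max(np.abs(v.imag)) > 1e-8 * max(1.0, np.max(np.abs(v.real))):
        raise ValueError("stationary eigenvector has a significant imaginary part")
    pi = v.real
    pi = pi / pi.sum()
    pi = np.maximum(pi, 0.0)
    pi = pi / pi.sum()
    resid = np.max(np.abs(M.entries @ pi - pi))
    if resid > 1e-8:
        raise ValueError(f"stationary residual |Mπ - π| = {resid:g} exceeds 1e-8")
    return pi


def _repair_columns(
    raw: np.ndarray, context: str, warn_above: float = 1e-6,
    level: int = logging.WARNING,
) -> np.ndarray:
    """Clip tiny negative entries to 0 and renormalize columns, logging repairs."""
    clipped = np.where(raw < 0, -raw, 0.0).sum(axis=0)
    worst = float(clipped.max()) if clipped.size else 0.0
    if worst > warn_above:
        logger.log(level, "%s: clipped negative mass up to %.3g per column", context, worst)
    out = np.maximum(raw, 0.0)
    return out / out.sum(axis=0)


def power(M: StochasticMatrix, t: int) -> StochasticMatrix:
    """``M(t) = M^t`` via the eigendecomposition ``S Λ^t S^-1``.

    Small imaginary residue is discarded and tiny negative entries are
    clipped and the columns renormalized.  Falls back to exact repeated
    multiplication when the eigenbasis is ill-conditioned.
    """
    if not float(t).is_integer() or t < 1:
        raise ValueError(f"t must be a positive integer, got {t!r}")
    t = int(t)
    if t == 1:
        return M
    lam, S, Sinv = M.eig()
    if Sinv is None or np.linalg.cond(S) > 1e12:
        # defective or near-defective matrix: multiply directly
        raw = np.linalg.matrix_power(M.entries, t)
    else:
        raw = (S * lam**t) @ Sinv
        raw = np.linalg.matrix_power(M.entries, t) if np.max(np.abs(raw.imag)) > 1e-9 else raw.real
    return StochasticMatrix(_repair_columns(raw, f"power(t={t})"), labels=M.labels)


def expected_change(M: StochasticMatrix, t: int = 1) -> float:
    """Stationary-weighted probability that a residue differs after ``t`` steps.

    ``1 - Σ_j π_j M(t)_jj``; with the unit-time convention this is ~0.01 for
    a base matrix at ``t = 1``.
    """
    pi = stationary_distribution(M)
    Mt = M.entries if t == 1 else power(M, t).entries
    return float(1.0 - np.diag(Mt) @ pi)


# ---------------------------------------------------------------------------
# conversion of published scoring matrices


def scoring_to_conditional(
    scoring: ScoringMatrix, freqs: np.ndarray | None = None
) -> StochasticMatrix:
    """Convert a log-odds scoring matrix to conditional-probability form.

    The implied joint is ``q_ij = f_i f_j base^(s_ij * scale)``; the
    conditional matrix ``C`` normalizes each column j so that
    ``C_ij = Pr(i | j)``.  ``freqs`` is used when the matrix does not
    publish its own background frequencies.
    """
    f = scoring.background_freqs if freqs is None else np.asarray(freqs, dtype=float)
    if f is None:
        raise ValueError("no background frequencies: supply freqs")
    if (f <= 0).any():
        raise ValueError(f"background frequency must be strictly positive, got min {f.min():g}")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"background frequencies sum to {f.sum():g}, not 1")
    f = f / f.sum()
    with np.errstate(over="raise"):
        try:
            odds = scoring.base ** (scoring.scores * scoring.scale)
        except FloatingPointError:
            ij = np.unravel_index(int(np.argmax(scoring.scores)), scoring.scores.shape)
            raise ValueError(f"overflow exponentiating score at cell {ij}") from None
    q = np.outer(f, f) * odds
    C = q / q.sum(axis=0, keepdims=True)
    return StochasticMatrix(C)


def find_unit_root(
    C, target: float = 0.01, k_max: int = 1000
) -> tuple[StochasticMatrix, int]:
    """Integer matrix root ``M = C^(1/k)`` closest to ``target`` expected change.

    Searches ``k`` exhaustively over ``1..k_max`` using a single
    eigendecomposition of ``C`` (principal branch ``Λ^(1/k)``); negative
    entries of each candidate root are clipped and columns renormalized.
    Ties break toward smaller ``k``.  Returns ``(M, k)``.
    """
    if not isinstance(C, StochasticMatrix):
        C = StochasticMatrix(C)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ec1 = expected_change(C, 1)
    if ec1 <= target:
        warnings.warn(
            f"matrix already at or below {target:g} expected change ({ec1:g}); "
            "returning k = 1",
            stacklevel=2,
        )
        return C, 1
    lam, S, Sinv = C.eig()
    if Sinv is None:
        raise ValueError("matrix eigenbasis is singular; no usable matrix root")
    lam_c = lam.astype(complex)
    best: tuple[float, int, StochasticMatrix] | None = None
    for k in range(1, k_max + 1):
        raw = (S * lam_c ** (1.0 / k)) @ Sinv
        raw_r = raw.real
        neg_mass = np.where(raw_r < 0, -raw_r, 0.0).sum(axis=0).max()
        if np.max(np.abs(raw.imag)) > 1e-6 and neg_mass > 1e-3:
            raise ValueError(
                f"complex {k}-th root with clipped mass {neg_mass:.3g} per column; "
                "matrix has no usable stochastic root at this k"
            )
        Mk = StochasticMatrix(
            _repair_columns(raw_r, f"root(k={k})", level=logging.DEBUG), labels=C.labels
        )
        try:
            err = abs(expected_change(Mk, 1) - target)
        except ValueError:
            continue
        if best is None or err < best[0] - 1e-15:
            best = (err, k, Mk)
    assert best is not None
    return best[2], best[1]


# ---------------------------------------------------------------------------
# synthetic base matrices


def random_reversible_base(
    rng: np.random.Generator, change: float = 0.01, n: int = N_RESIDUES
) -> StochasticMatrix:
    """Random time-reversible base matrix with the given expected change.

    Draws a stationary distribution and a symmetric exchangeability matrix,
    forms the reversible rate matrix ``R_ij = x_ij π_i`` (columns summing to
    zero) and exponentiates ``expm(c R)``, solving for the scale ``c`` that
    yields the requested stationary expected change.  Reversibility gives the
    matrix a real positive spectrum, so integer powers have exact principal
    roots — convenient for round-trip studies of the unit-time conversion.
    """
    if not 0 < change < 1:
        raise ValueError("change must be in (0, 1)")
    pi = rng.dirichlet(np.full(n, 10.0))
    x = rng.uniform(0.5, 1.5, size=(n, n))
    x = (x + x.T) / 2.0
    np.fill_diagonal(x, 0.0)
    R = x * pi[:, None]
    np.fill_diagonal(R, -R.sum(axis=0))

    def ec(c: float) -> float:
        Mc = scipy.linalg.expm(c * R)
        return float(1.0 - np.diag(Mc) @ pi)

    rate = float(-np.diag(R) @ pi)
    c0 = change / rate
    lo, hi = c0 / 100.0, c0 * 100.0
    c = brentq(lambda c: ec(c) - change, lo, hi, xtol=1e-14)
    M = scipy.linalg.expm(c * R)
    return StochasticMatrix(_repair_columns(M, "random_reversible_base"))


# ---------------------------------------------------------------------------
# I/O


def read_scoring_matrix(
    path,
    scale: float,
    base: float = 2.0,
    background_freqs: np.ndarray | None = None,
    name: str = "",
) -> ScoringMatrix:
    """Read an NCBI-style square scoring-matrix text file.

    Uses Biopython's substitution-matrix reader ('#' comments, a header row
    of residue letters) and extracts the 20 canonical residues in canonical
    order.  ``scale`` and ``base`` define the published log-odds scaling and
    must be supplied alongside (they are not embedded in the format).
    """
    from Bio.Align import substitution_matrices

    arr = substitution_matrices.read(str(path))
    missing = [aa for aa in RESIDUES if aa not in arr.alphabet]
    if missing:
        raise ValueError(f"scoring matrix at {path} lacks residues {missing}")
    scores = np.empty((N_RESIDUES, N_RESIDUES))
    for i, a in enumerate(RESIDUES):
        for j, b in enumerate(RESIDUES):
            scores[i, j] = arr[a, b]
    return ScoringMatrix(scores, scale=scale, base=base,
                         background_freqs=background_freqs, name=name)


def write_stochastic_tsv(M: StochasticMatrix, path) -> None:
    """Serialize a stochastic matrix as TSV: residue header, 20 rows, 17 sig digits."""
    labels = M.labels or "".join(str(i) for i in range(M.n))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in M.entries:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_stochastic_tsv(path) -> StochasticMatrix:
    """Read a stochastic matrix TSV written by :func:`write_stochastic_tsv`.

    Validates the header against the canonical residue order (for 20-state
    matrices) and the column sums.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    n = len(header)
    if n == N_RESIDUES and "".join(header) != RESIDUES:
        raise ValueError(
            f"header order {''.join(header)!r} differs from canonical {RESIDUES!r}"
        )
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} data rows, found {len(lines) - 1}")
    entries = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
    return StochasticMatrix(entries, labels="".join(header))
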