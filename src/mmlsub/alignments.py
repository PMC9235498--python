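"""Pairwise-aligned sequences and their three-state alignment strings.

An alignment of sequences S and T is stored as the gap-free sequences plus
a string over ``{m, i, d}``: ``m`` aligns one residue of S with one of T,
``i`` (insert) consumes a residue of T only, ``d`` (delete) a residue of S
only.  A :class:`Benchmark` is an ordered collection of such pairs, read
either from gapped pairwise FASTA (records consumed two at a time) or from
a 4-column TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .residues import N_RESIDUES, encode_sequence

STATES = "mid"
_STATE_INDEX = {"m": 0, "i": 1, "d": 2}
GAP = "-"


@dataclass(frozen=True)
class AlignedPair:
    """Two gap-free amino-acid sequences and their three-state alignment string."""

    id: str
    seq_s: str
    seq_t: str
    states: str

    def __post_init__(self):
        if not self.states:
            raise ValueError(f"pair {self.id!r}: empty state string")
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"pair {self.id!r}: invalid state characters {sorted(bad)}")
        n_m = self.states.count("m")
        n_i = self.states.count("i")
        n_d = self.states.count("d")
        if n_m + n_d != len(self.seq_s):
            raise ValueError(
                f"pair {self.id!r}: m+d = {n_m + n_d} does not match |S| = {len(self.seq_s)}"
            )
        if n_m + n_i != len(self.seq_t):
            raise ValueError(
                f"pair {self.id!r}: m+i = {n_m + n_i} does not match |T| = {len(self.seq_t)}"
            )
        # validate residues eagerly so downstream code can trust the pair
        encode_sequence(self.seq_s)
        encode_sequence(self.seq_t)


@dataclass
class Benchmark:
    """Ordered collection of aligned pairs with unique ids."""

    pairs: list[AlignedPair]
    name: str = ""

    def __post_init__(self):
        ids = [p.id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate pair id {dup!r} in benchmark {self.name!r}")

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class PairCounts:
    """Sufficient statistics of one aligned pair.

    ``transitions[p, q]`` counts one-step transitions from state p to state q
    (order m, i, d); ``match_counts[b, a]`` counts match columns pairing
    source residue ``a`` (from S) with target residue ``b`` (from T), in the
    same (row=target, column=source) convention as the substitution matrix;
    ``indel_counts`` counts residues in insert and delete columns together.
    """

    initial: str
    transitions: np.ndarray
    match_counts: np.ndarray
    indel_counts: np.ndarray


def parse_gapped_pair(row_s: str, row_t: str, pair_id: str = "") -> AlignedPair:
    """Build an :class:`AlignedPair` from two gapped alignment rows.

    Per column: residues in both rows -> ``m``; residue only in the second
    (T) row -> ``i``; residue only in the first (S) row -> ``d``.  Only
    ``'-'`` is accepted as the gap character.
    """
    if len(row_s) != len(row_t):
        raise ValueError(
            f"pair {pair_id!r}: rows have unequal lengths {len(row_s)} and {len(row_t)}"
        )
    states = []
    for col, (a, b) in enumerate(zip(row_s, row_t)):
        if a == GAP and b == GAP:
            raise ValueError(f"pair {pair_id!r}: column {col} gapped in both rows")
        states.append("m" if (a != GAP and b != GAP) else ("d" if b == GAP else "i"))
    return AlignedPair(
        id=pair_id,
        seq_s=row_s.replace(GAP, ""),
        seq_t=row_t.replace(GAP, ""),
        states="".join(states),
    )


def state_counts(pair: AlignedPair) -> PairCounts:
    """Transition and emission sufficient statistics of a pair."""
    st = np.array([_STATE_INDEX[c] for c in pair.states], dtype=np.int8)
    trans = np.zeros((3, 3), dtype=np.int64)
    if len(st) > 1:
        np.add.at(trans, (st[:-1], st[1:]), 1)
    s = encode_sequence(pair.seq_s)
    t = encode_sequence(pair.seq_t)
    # positions of each state within its source sequence
    s_cols = st != 1  # m or d consume S
    t_cols = st != 2  # m or i consume T
    s_states = st[s_cols]
    t_states = st[t_cols]
    match_counts = np.zeros((N_RESIDUES, N_RESIDUES), dtype=np.int64)
    a = s[s_states == 0]
    b = t[t_states == 0]
    np.add.at(match_counts, (b, a), 1)
    indel_counts = np.bincount(
        np.concatenate([s[s_states == 2], t[t_states == 1]]), minlength=N_RESIDUES
    ).astype(np.int64)
    return PairCounts(
        initial=pair.states[0],
        transitions=trans,
        match_counts=match_counts,
        indel_counts=indel_counts,
    )


# ---------------------------------------------------------------------------
# I/O


def read_benchmark(path, name: str | None = None) -> Benchmark:
    """Read a benchmark from gapped pairwise FASTA or 4-column TSV.

    The format is sniffed from the first non-blank character ('>' means
    FASTA).  FASTA records are consumed two at a time; an odd record count
    is an error naming the dangling record.
    """
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        head = ""
        for line in fh:
            if line.strip():
                head = line.lstrip()[0]
                break
    if name is None:
        name = path
    if head == ">":
        return _read_fasta_benchmark(path, name)
    return _read_tsv_benchmark(path, name)


def _read_fasta_benchmark(path: str, name: str) -> Benchmark:
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(
            f"{path}: odd number of FASTA records; record {records[-1].id!r} has no partner"
        )
    pairs = []
    for k in range(0, len(records), 2):
        r1, r2 = records[k], records[k + 1]
        try:
            pairs.append(parse_gapped_pair(str(r1.seq), str(r2.seq), pair_id=r1.id))
        except ValueError as exc:
            raise ValueError(f"{path}: pair {r1.id!r}/{r2.id!r}: {exc}") from exc
    return Benchmark(pairs, name=name)


def _read_tsv_benchmark(path: str, name: str) -> Benchmark:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            pid, seq_s, seq_t, states = fields
            try:
                pairs.append(AlignedPair(pid, seq_s, seq_t, states))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return Benchmark(pairs, name=name)


def write_benchmark(benchmark: Benchmark, path) -> None:
    """Write a benchmark as 4-column TSV (id, seq_s, seq_t, states)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p in benchmark:
            fh.write(f"{p.id}\t{p.seq_s}\t{p.seq_t}\t{p.states}\n")
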