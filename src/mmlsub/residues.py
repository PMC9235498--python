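"""Canonical amino-acid alphabet and index helpers.

All 20x20 tables in this package are read and written in the fixed order
``ARNDCQEGHILKMFPSTWYV``.  Non-standard residue codes (B, Z, X, U, O, *)
are rejected at parse time so that encoding lengths remain comparable
across inputs.
"""

from __future__ import annotations

import numpy as np

RESIDUES = "ARNDCQEGHILKMFPSTWYV"
N_RESIDUES = len(RESIDUES)

_INDEX = {aa: i for i, aa in enumerate(RESIDUES)}

# lookup table for fast sequence encoding; -1 marks invalid codes
_LUT = np.full(128, -1, dtype=np.int8)
for _aa, _i in _INDEX.items():
    _LUT[ord(_aa)] = _i


def residue_index(aa: str) -> int:
    """Index of a single residue letter in the canonical order."""
    try:
        return _INDEX[aa]
    except KeyError:
        raise ValueError(
            f"non-standard residue {aa!r}: only the 20 canonical amino acids "
            f"({RESIDUES}) are supported"
        ) from None


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a protein sequence as an int8 array of canonical indices.

    Raises ``ValueError`` on any character outside the canonical alphabet.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _LUT[np.minimum(raw, 127)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(
            f"non-standard residue {bad!r} in sequence: only {RESIDUES} are supported"
        )
    return codes
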