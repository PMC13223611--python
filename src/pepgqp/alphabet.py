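"""Canonical amino-acid alphabet and residue classes.

Single source of truth for the residue sets used by the synthetic generators,
the covariate computations and the screening score model, so that a change to
e.g. the hydrophobic set propagates consistently.
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL)

#: Aromatic residues.
AROMATIC = frozenset("FWY")

#: Default hydrophobic set (configurable wherever it is consumed).
HYDROPHOBIC = frozenset("ACFILMVW")

#: Strongly solubilizing residues (aspartate, glutamate, serine).
SOLUBILIZING = frozenset("DES")

#: Adjacent mixed-charge pairs characteristic of zwitterionic, highly
#: hydrated (non-fouling) chemistries.
MIXED_CHARGE_PAIRS = frozenset(
    {"EK", "KE", "DK", "KD", "ER", "RE", "DR", "RD"}
)

#: Special tokens used by the toy encoder.
CLS, EOS, PAD = "<cls>", "<eos>", "<pad>"
SPECIAL_TOKENS = (CLS, EOS, PAD)

#: Index assignment: residues 0..19, then CLS, EOS, PAD.
TOKEN_INDEX = {aa: i for i, aa in enumerate(CANONICAL)}
TOKEN_INDEX[CLS] = 20
TOKEN_INDEX[EOS] = 21
TOKEN_INDEX[PAD] = 22
N_TOKEN_TYPES = 23

# uint8 lookup from ASCII byte -> residue index (255 = invalid), for fast
# vectorized conversion of sequence strings.
_BYTE_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _aa in CANONICAL:
    _BYTE_TO_INDEX[ord(_aa)] = TOKEN_INDEX[_aa]


def validate_sequence(sequence: str, name: str = "sequence") -> str:
    """Check that ``sequence`` is a non-empty canonical residue string.

    Returns the sequence unchanged.  Raises ``ValueError`` naming the first
    offending character and its 1-based position.
    """
    if not sequence:
        raise ValueError(f"{name} is empty")
    for pos, ch in enumerate(sequence):
        if ch not in CANONICAL_SET:
            raise ValueError(
                f"{name} contains non-canonical residue {ch!r} at position {pos + 1}"
            )
    return sequence


def sequence_to_indices(sequence: str) -> np.ndarray:
    """Vectorized residue-string -> integer-code conversion (validated)."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = _BYTE_TO_INDEX[raw]
    if (idx == 255).any():
        bad = int(np.argmax(idx == 255))
        raise ValueError(
            f"sequence contains non-canonical residue {sequence[bad]!r} "
            f"at position {bad + 1}"
        )
    return idx.astype(np.int64)
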