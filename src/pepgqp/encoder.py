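"""Sequence-encoder contract and a deterministic toy encoder.

The contract is intentionally minimal: any encoder maps a peptide sequence to
per-token embeddings ``X`` (one row per token, including CLS/EOS specials and
optional right padding), a boolean validity mask, and the token identities.
External protein language models can be plugged in behind the same
:class:`TokenEmbeddings` structure; this package ships a seeded lookup-table
encoder so the full pipeline runs deterministically with no pretrained
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    CLS,
    EOS,
    N_TOKEN_TYPES,
    PAD,
    TOKEN_INDEX,
    sequence_to_indices,
)

#: Maximum residue count so that with CLS+EOS the token count stays <= 512.
MAX_RESIDUES = 510

_INDEX_TO_SYMBOL = {v: k for k, v in TOKEN_INDEX.items()}


@dataclass
class TokenEmbeddings:
    """Per-token embeddings for one peptide.

    Attributes
    ----------
    X : (L_tok, d) float64 array of token embeddings.
    valid_mask : (L_tok,) bool array; True = attendable. Padding is False.
    special_positions : set of token indices holding CLS/EOS/padding.
    residue_at : list mapping token index -> residue letter or special symbol.
    """

    X: np.ndarray
    valid_mask: np.ndarray
    special_positions: frozenset[int]
    residue_at: list[str]
    d: int = field(init=False)
    L_tok: int = field(init=False)

    def __post_init__(self) -> None:
        self.L_tok, self.d = self.X.shape
        if not self.valid_mask.any():
            raise ValueError("TokenEmbeddings must have at least one valid position")

    @property
    def residue_positions(self) -> np.ndarray:
        """Indices of valid, non-special (i.e. residue) tokens."""
        keep = self.valid_mask.copy()
        for p in self.special_positions:
            keep[p] = False
        return np.flatnonzero(keep)


class ToyEncoder:
    """Deterministic per-residue embedding from a seeded lookup table.

    Each of the 20 residues plus CLS/EOS/PAD gets a fixed random ``d``-vector
    drawn once from ``numpy.random.default_rng(seed)``.  With
    ``positional_mixing=True`` (default) a fixed sinusoid-like positional
    signal of modest amplitude is added, so embeddings carry both content and
    position; switching it off makes the encoder permutation-covariant, which
    several invariance tests rely on.
    """

    def __init__(self, d: int = 16, seed: int = 0, positional_mixing: bool = True,
                 positional_scale: float = 0.25):
        if d < 1:
            raise ValueError("d must be >= 1")
        self.d = d
        self.seed = seed
        self.positional_mixing = positional_mixing
        self.positional_scale = positional_scale
        rng = np.random.default_rng(seed)
        # unit-scale Gaussian lookup table, rows indexed by token type
        self.table_ = rng.standard_normal((N_TOKEN_TYPES, d))
        self.table_[TOKEN_INDEX[PAD]] = 0.0

    def _positional_signal(self, L_tok: int) -> np.ndarray:
        pos = np.arange(L_tok, dtype=np.float64)[:, None]
        j = np.arange(self.d, dtype=np.float64)[None, :]
        freq = 1.0 / (50.0 ** (j / max(self.d - 1, 1)))
        return self.positional_scale * np.sin(pos * freq + j)

    def encode(self, sequence: str) -> TokenEmbeddings:
        """Encode one peptide as CLS + residues + EOS (no padding)."""
        return self.encode_padded(sequence, pad_to=None)

    def encode_padded(self, sequence: str, pad_to: int | None) -> TokenEmbeddings:
        idx = sequence_to_indices(sequence)
        if idx.size > MAX_RESIDUES:
            raise ValueError(
                f"sequence has {idx.size} residues; the encoder accepts at most "
                f"{MAX_RESIDUES} so the token count stays within 512"
            )
        codes = np.concatenate((
            [TOKEN_INDEX[CLS]], idx, [TOKEN_INDEX[EOS]],
        ))
        n_real = codes.size
        if pad_to is not None:
            if pad_to < n_real:
                raise ValueError(f"pad_to={pad_to} < token count {n_real}")
            codes = np.concatenate((codes, np.full(pad_to - n_real, TOKEN_INDEX[PAD])))
        X = self.table_[codes].copy()
        if self.positional_mixing:
            X[:n_real] += self._positional_signal(n_real)
        X[n_real:] = 0.0
        valid = np.zeros(codes.size, dtype=bool)
        valid[:n_real] = True
        specials = frozenset(
            [0, n_real - 1] + list(range(n_real, codes.size))
        )
        residue_at = [_INDEX_TO_SYMBOL[int(c)] for c in codes]
        return TokenEmbeddings(X=X, valid_mask=valid,
                               special_positions=specials, residue_at=residue_at)

    def batch_encode(self, sequences: list[str], pad_to: int | None = None
                     ) -> list[TokenEmbeddings]:
        """Encode a batch with right padding to a common length."""
        if not sequences:
            return []
        max_tok = max(len(s) for s in sequences) + 2
        if pad_to is None:
            pad_to = max_tok
        if pad_to < max_tok:
            raise ValueError(f"pad_to={pad_to} < max token length {max_tok}")
        return [self.encode_padded(s, pad_to=pad_to) for s in sequences]

    def encode_batch_arrays(self, sequences: list[str]
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized batch encoding to dense arrays.

        Returns ``(X, mask)`` with shapes ``(B, L_tok, d)`` and ``(B, L_tok)``;
        rows are right-padded to the longest peptide.  Content equals
        :meth:`batch_encode` for valid positions.
        """
        B = len(sequences)
        if B == 0:
            return np.zeros((0, 0, self.d)), np.zeros((0, 0), dtype=bool)
        n_tok = np.array([len(s) + 2 for s in sequences])
        L = int(n_tok.max())
        codes = np.full((B, L), TOKEN_INDEX[PAD], dtype=np.int64)
        for i, s in enumerate(sequences):
            idx = sequence_to_indices(s)
            if idx.size > MAX_RESIDUES:
                raise ValueError(
                    f"sequence has {idx.size} residues; the encoder accepts at "
                    f"most {MAX_RESIDUES} so the token count stays within 512"
                )
            codes[i, 0] = TOKEN_INDEX[CLS]
            codes[i, 1:1 + idx.size] = idx
            codes[i, 1 + idx.size] = TOKEN_INDEX[EOS]
        mask = np.arange(L)[None, :] < n_tok[:, None]
        X = self.table_[codes]
        if self.positional_mixing:
            X = X + self._positional_signal(L)[None, :, :]
        X = np.where(mask[:, :, None], X, 0.0)
        return X, mask


def encode_toy(sequence: str, d: int = 16, seed: int = 0,
               positional_mixing: bool = True) -> TokenEmbeddings:
    """Convenience wrapper: encode one peptide with a fresh toy encoder."""
    return ToyEncoder(d=d, seed=seed, positional_mixing=positional_mixing).encode(sequence)


def batch_encode(sequences: list[str], d: int = 16, seed: int = 0,
                 pad_to: int | None = None,
                 positional_mixing: bool = True) -> list[TokenEmbeddings]:
    """Convenience wrapper over :meth:`ToyEncoder.batch_encode`."""
    enc = ToyEncoder(d=d, seed=seed, positional_mixing=positional_mixing)
    return enc.batch_encode(sequences, pad_to=pad_to)
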