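"""Attention-based interpretability for the GQP readout.

Two summaries are exported.  The token-level mass ``M_l = sum_p A~_pl``
(column sum of the gated-and-renormalized attention over queries) shows
where the readout concentrates evidence along one peptide; masked positions
are fixed at 0.  The class-level, frequency-weighted mass ``M_y(aa)``
aggregates token masses over all residue positions of class ``y`` — padding
and special tokens (CLS/EOS) excluded — dividing by the total residue-
position count ``N_y``, and the class contrast is
``dM(aa) = M_1(aa) - M_0(aa)``: positive values mark residues receiving more
gated attention mass in the positive class.

These are diagnostic routing signals, not faithfulness claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import CANONICAL
from .pooling import AttentionState


@dataclass
class TokenMass:
    """Per-token gated attention mass for one peptide."""

    M: np.ndarray                 # (L_tok,) nonnegative; 0 at masked positions
    residue_at: list[str]
    valid_mask: np.ndarray
    special_positions: frozenset[int]

    @property
    def total(self) -> float:
        return float(self.M.sum())


@dataclass
class ClassMassSummary:
    """Frequency-weighted per-residue mass for both classes and their contrast."""

    M_y: dict[int, dict[str, float]]     # class -> residue -> mean mass
    N_y: dict[int, int]                  # class -> total residue positions
    delta_M: dict[str, float]            # residue -> M_1 - M_0
    counts_n: dict[str, int]             # residue -> instance count (both classes)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"residue": aa,
                 "M_0": self.M_y[0].get(aa, 0.0),
                 "M_1": self.M_y[1].get(aa, 0.0),
                 "delta_M": self.delta_M.get(aa, 0.0),
                 "n": self.counts_n.get(aa, 0)} for aa in CANONICAL]
        return pd.DataFrame(rows)


def token_mass(state: AttentionState) -> TokenMass:
    """Column sum of the gated attention weights over queries.

    With ``m`` queries each row of ``A~`` sums to ~1 over valid tokens, so
    the masses total ~``m``; the mass at a position grows when several gated
    queries concentrate there.  Masked positions carry exactly 0.
    """
    M = state.A_tilde.sum(axis=0)
    M = np.where(state.valid_mask, M, 0.0)
    return TokenMass(M=M, residue_at=list(state.residue_at),
                     valid_mask=state.valid_mask.copy(),
                     special_positions=state.special_positions)


def class_mass_summary(records) -> ClassMassSummary:
    """Aggregate token masses into per-residue class means and contrast.

    ``records`` is an iterable of ``(TokenMass, label)`` pairs (or
    ``(TokenMass, residue_at, label)`` triples for explicitly supplied
    residue identities).  For each class ``y`` and residue ``aa``,
    ``M_y(aa)`` is the summed mass over all positions carrying ``aa`` across
    class-``y`` peptides divided by ``N_y``, the total residue-position count
    of the class — padding and special tokens never contribute.
    """
    mass_sum = {0: {}, 1: {}}
    N_y = {0: 0, 1: 0}
    counts = {}
    seen = {0: 0, 1: 0}
    for rec in records:
        if len(rec) == 2:
            tm, label = rec
            residue_at = tm.residue_at
        else:
            tm, residue_at, label = rec
        label = int(label)
        keep = tm.valid_mask.copy()
        for p in tm.special_positions:
            keep[p] = False
        for pos in np.flatnonzero(keep):
            aa = residue_at[pos]
            mass_sum[label][aa] = mass_sum[label].get(aa, 0.0) + float(tm.M[pos])
            counts[aa] = counts.get(aa, 0) + 1
            N_y[label] += 1
        seen[label] += 1
    if seen[0] == 0 or seen[1] == 0:
        raise ValueError("class_mass_summary needs at least one peptide per class")
    M_y = {y: {aa: s / N_y[y] for aa, s in mass_sum[y].items()} for y in (0, 1)}
    residues = set(M_y[0]) | set(M_y[1])
    delta = {aa: M_y[1].get(aa, 0.0) - M_y[0].get(aa, 0.0) for aa in residues}
    return ClassMassSummary(M_y=M_y, N_y=N_y, delta_M=delta, counts_n=counts)


def model_class_mass(model, sequences, labels) -> ClassMassSummary:
    """Convenience: attention states -> token masses -> class summary."""
    states = model.attention_states(sequences)
    recs = [(token_mass(st), int(y)) for st, y in zip(states, labels)]
    return class_mass_summary(recs)


def position_mass_table(model, sequences, ids=None) -> pd.DataFrame:
    """Long-form per-peptide per-position mass table (1-based positions)."""
    ids = ids if ids is not None else [f"pep{i+1}" for i in range(len(sequences))]
    rows = []
    for pid, seq, st in zip(ids, sequences, model.attention_states(sequences)):
        tm = token_mass(st)
        res_positions = [p for p in np.flatnonzero(tm.valid_mask)
                         if p not in tm.special_positions]
        for k, pos in enumerate(res_positions):
            rows.append({"id": pid, "position": k + 1,
                         "residue": tm.residue_at[pos],
                         "mass": float(tm.M[pos])})
    return pd.DataFrame(rows, columns=["id", "position", "residue", "mass"])
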