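"""Controlled in-silico saturation mutagenesis.

For a fixed trained scorer ``f`` (positive-class logit), the raw effect of
substituting residue ``a`` at position ``i`` by ``a'`` is the logit
difference ``delta = (f(s') - f(s)) / max(T, 1e-3)``.  Each occupied
position contributes all 19 non-identity substitutions.  Because sequences
with many copies of a residue would otherwise dominate, the sequence is the
unit of analysis: per-sequence effects average the per-position deltas over
all positions carrying ``a``.

Raw effects confound residue identity with global composition.  The
controlled substitution effect (CSE) therefore stratifies sequences by net
charge ``Q = #(K,R) + 0.1 #(H) - #(D,E)``, hydrophobic fraction and length
(default bin widths 1.0 / 0.05 / 25), averages the per-stratum means with
empirical stratum weights computed separately for each from-residue over the
sequences that contain it — a discrete standardization (g-formula).  Strata
with fewer than five qualifying sequences are dropped and the remaining
weights renormalized.  Intervenability ``I(a)`` is the mean CSE over the 19
non-identity substitutions from ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import CANONICAL, HYDROPHOBIC, validate_sequence

#: Default covariate bin widths (charge, hydrophobic fraction, length).
DEFAULT_BINS = {"q_bin": 1.0, "h_bin": 0.05, "l_bin": 25}


@dataclass(frozen=True)
class CovariateProfile:
    """Global covariates of one sequence and its stratum assignment."""

    Q: float
    H_frac: float
    L_seq: int
    stratum_id: tuple[int, int, int]


@dataclass(frozen=True)
class SubstitutionEffect:
    """One single-residue edit and its scaled logit difference."""

    sequence: str
    position: int          # 0-based internally; reports add 1
    from_aa: str
    to_aa: str
    delta: float


@dataclass
class ControlledEffectMatrix:
    """20x19 controlled-effect grid with stratum bookkeeping.

    ``cse`` maps (from_aa, to_aa) -> CSE; ``stratum_estimates`` maps
    from_aa -> {stratum_id: (mean effect per to_aa dict, n_sequences)};
    ``weights`` maps from_aa -> {stratum_id: weight} (summing to 1 over the
    eligible strata); ``intervenability`` maps from_aa -> mean over its row;
    ``row_support`` counts the entries behind each row mean; ``missing_rows``
    lists from-residues with no eligible stratum, with the excluded-stratum
    count.
    """

    cse: dict[tuple[str, str], float]
    weights: dict[str, dict]
    intervenability: dict[str, float]
    row_support: dict[str, int] = field(default_factory=dict)
    missing_rows: dict[str, int] = field(default_factory=dict)
    stratum_sizes: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """20x20 DataFrame (NaN diagonal and missing rows)."""
        mat = pd.DataFrame(np.nan, index=list(CANONICAL), columns=list(CANONICAL))
        for (a, b), v in self.cse.items():
            mat.loc[a, b] = v
        return mat

    def intervenability_series(self) -> pd.Series:
        return pd.Series(self.intervenability, dtype=float).reindex(list(CANONICAL))

    def max_abs_effect(self) -> float:
        if not self.cse:
            return float("nan")
        return max(abs(v) for v in self.cse.values())


def _charge_tenths(sequence: str) -> int:
    """Net charge in exact tenths: 10*#(K,R) + #(H) - 10*#(D,E)."""
    kr = sum(c in "KR" for c in sequence)
    h = sequence.count("H")
    de = sum(c in "DE" for c in sequence)
    return 10 * kr + h - 10 * de


def covariates(sequence: str, bins: dict | None = None,
               hydrophobic=HYDROPHOBIC) -> CovariateProfile:
    """Net charge, hydrophobic fraction, length, and the stratum triple.

    Bin index = floor(value / width) with half-open bins anchored at 0;
    negatives floor downward (Q = -0.5 -> bin -1).  For the default widths
    the indices are computed in exact integer arithmetic, so bin boundaries
    (e.g. charge exactly 1.0 from ten histidines) never misbin through
    floating-point error.  A hydrophobic fraction of exactly 1.0 goes to the
    top bin.
    """
    validate_sequence(sequence)
    bins = {**DEFAULT_BINS, **(bins or {})}
    L = len(sequence)
    q10 = _charge_tenths(sequence)
    Q = q10 / 10.0
    h_count = sum(c in hydrophobic for c in sequence)
    H_frac = h_count / L

    if bins["q_bin"] == 1.0:
        q_idx = q10 // 10
    else:
        q_idx = math.floor(Q / bins["q_bin"] + 1e-9)
    if bins["h_bin"] == 0.05:
        h_idx = (20 * h_count) // L
        h_idx = min(h_idx, 19)          # H_frac == 1.0 -> top bin
    else:
        if h_count == L:
            h_idx = math.floor((1.0 - 1e-12) / bins["h_bin"])
        else:
            h_idx = math.floor(H_frac / bins["h_bin"] + 1e-9)
    l_idx = L // int(bins["l_bin"])
    return CovariateProfile(Q=Q, H_frac=H_frac, L_seq=L,
                            stratum_id=(int(q_idx), int(h_idx), int(l_idx)))


def saturation_scan(model, sequence: str, T: float = 1.0
                    ) -> list[SubstitutionEffect]:
    """All 19 non-identity substitutions at every position of one sequence.

    Every mutant is fully re-encoded and re-scored; the logit differences
    are divided by ``max(T, 1e-3)``.
    """
    validate_sequence(sequence)
    scale = max(T, 1e-3)
    mutants, meta = [], []
    for i, a in enumerate(sequence):
        for b in CANONICAL:
            if b == a:
                continue
            mutants.append(sequence[:i] + b + sequence[i + 1:])
            meta.append((i, a, b))
    logits = np.asarray(model.decision_function(mutants + [sequence]))
    f0 = logits[-1]
    return [SubstitutionEffect(sequence=sequence, position=i, from_aa=a,
                               to_aa=b, delta=float((fm - f0) / scale))
            for (i, a, b), fm in zip(meta, logits[:-1])]


def sequence_level_effect(effects: list[SubstitutionEffect], a: str, b: str
                          ) -> float:
    """Mean delta of a -> b over all positions of one sequence carrying a.

    Raises ``ValueError`` if the sequence has no occurrence of ``a`` (such
    sequences are excluded from aggregation, not averaged as zero).
    """
    deltas = [e.delta for e in effects if e.from_aa == a and e.to_aa == b]
    if not deltas:
        raise ValueError(f"no occurrence of {a!r} in this sequence's scan")
    return float(sum(deltas) / len(deltas))


def _batched_scan(model, sequences: list[str], T: float, chunk: int = 20000):
    """Per-sequence dict (a, b) -> sequence-level mean delta, batched.

    Scores all mutants of many sequences in large chunks through one
    ``decision_function`` call per chunk to amortize encoding cost.
    """
    scale = max(T, 1e-3)
    base_logits = np.asarray(model.decision_function(sequences))
    per_seq: list[dict] = []
    buf_seqs: list[str] = []
    buf_meta: list[tuple[int, str, str]] = []   # (seq index, a, b)

    sums: list[dict] = [{} for _ in sequences]
    counts: list[dict] = [{} for _ in sequences]

    def flush():
        if not buf_seqs:
            return
        logits = np.asarray(model.decision_function(buf_seqs))
        for (si, a, b), fm in zip(buf_meta, logits):
            d = (fm - base_logits[si]) / scale
            key = (a, b)
            sums[si][key] = sums[si].get(key, 0.0) + d
            counts[si][key] = counts[si].get(key, 0) + 1
        buf_seqs.clear()
        buf_meta.clear()

    for si, s in enumerate(sequences):
        for i, a in enumerate(s):
            for b in CANONICAL:
                if b == a:
                    continue
                buf_seqs.append(s[:i] + b + s[i + 1:])
                buf_meta.append((si, a, b))
        if len(buf_seqs) >= chunk:
            flush()
    flush()
    for si in range(len(sequences)):
        per_seq.append({k: sums[si][k] / counts[si][k] for k in sums[si]})
    return per_seq


def controlled_cse(sequences, model, T: float = 1.0, bins: dict | None = None,
                   min_stratum: int = 5, hydrophobic=HYDROPHOBIC
                   ) -> ControlledEffectMatrix:
    """Standardized controlled substitution effects over a sequence set.

    Steps: assign each sequence a (charge, hydrophobic-fraction, length)
    stratum; scan all single-residue edits; reduce to sequence-level means;
    per from-residue ``a``, keep strata with at least ``min_stratum``
    sequences containing ``a``; CSE(a -> b) is the stratum-size-weighted
    average of the per-stratum means.  Weighted averages are computed as
    ``sum(n_c * mean_c) / sum(n_c)``, which keeps the estimate exact when
    effects are homogeneous.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("controlled_cse requires a non-empty dataset")
    strata = [covariates(s, bins=bins, hydrophobic=hydrophobic).stratum_id
              for s in sequences]
    per_seq = _batched_scan(model, sequences, T)

    # group sequence-level effects: from-residue -> stratum -> per-target sums
    by_a: dict[str, dict] = {a: {} for a in CANONICAL}
    for sid, (st, eff) in enumerate(zip(strata, per_seq)):
        present = {a for (a, _b) in eff}
        for a in present:
            cell = by_a[a].setdefault(st, {"n": 0, "sums": {}})
            cell["n"] += 1
            for (aa, b), v in eff.items():
                if aa == a:
                    cell["sums"][b] = cell["sums"].get(b, 0.0) + v

    cse: dict[tuple[str, str], float] = {}
    weights: dict[str, dict] = {}
    missing: dict[str, int] = {}
    stratum_sizes: dict[str, dict] = {}
    for a in CANONICAL:
        cells = by_a[a]
        eligible = {st: c for st, c in cells.items() if c["n"] >= min_stratum}
        stratum_sizes[a] = {st: c["n"] for st, c in cells.items()}
        if not eligible:
            missing[a] = len(cells)
            continue
        total_n = sum(c["n"] for c in eligible.values())
        weights[a] = {st: c["n"] / total_n for st, c in eligible.items()}
        for b in CANONICAL:
            if b == a:
                continue
            num = 0.0
            for st, c in eligible.items():
                # per-stratum mean of sequence-level effects, times stratum size
                num += c["sums"].get(b, 0.0)
            cse[(a, b)] = num / total_n

    matrix = ControlledEffectMatrix(cse=cse, weights=weights,
                                    intervenability={}, missing_rows=missing,
                                    stratum_sizes=stratum_sizes)
    matrix.intervenability = intervenability(matrix)
    matrix.row_support = {
        a: sum(1 for (x, _b) in cse if x == a) for a in CANONICAL
        if any(x == a for (x, _b) in cse)
    }
    return matrix


def intervenability(matrix: ControlledEffectMatrix) -> dict[str, float]:
    """Row means over the 19 non-identity targets, per from-residue.

    Rows with missing entries yield a partial mean over the available
    targets (the support count is recorded on the matrix).
    """
    out: dict[str, float] = {}
    for a in CANONICAL:
        vals = [v for (x, _b), v in matrix.cse.items() if x == a]
        if vals:
            out[a] = float(sum(vals) / len(vals))
    return out


def effects_table(effects: list[SubstitutionEffect]) -> pd.DataFrame:
    """Long-form per-edit table with 1-based positions."""
    return pd.DataFrame([
        {"sequence": e.sequence, "position": e.position + 1,
         "from": e.from_aa, "to": e.to_aa, "delta": e.delta}
        for e in effects
    ], columns=["sequence", "position", "from", "to", "delta"])
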