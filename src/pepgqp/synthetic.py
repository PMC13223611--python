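"""Synthetic peptide libraries with planted residue-level drivers.

Generates (i) binary property datasets for three developability tasks —
hemolysis (driven by hydrophobic/aromatic content), non-fouling (driven by
adjacent mixed-charge EK/DK-type pairs) and solubility (driven by D/E/S
content) — and (ii) fixed-length 12-mer affinity libraries (excluding
cysteine and proline) with energy-like scores clipped to [-64, +12], lower
meaning stronger predicted binding.

Residues are drawn i.i.d. from a configurable composition; class separation
comes from planting a task-appropriate motif run in a fraction of peptides,
which gives separable but noisy classes.  Labels are a deterministic
threshold on the task's driver statistic, then flipped independently with a
small probability to emulate label noise.  Identical seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    AROMATIC,
    CANONICAL,
    HYDROPHOBIC,
    MIXED_CHARGE_PAIRS,
    SOLUBILIZING,
    validate_sequence,
)

TASKS = ("hemolysis", "nonfouling", "solubility")
PLASTICS = ("PE", "PP", "PET")

#: 12-mer affinity-library alphabet: canonical residues minus C and P.
AFFINITY_ALPHABET = "".join(aa for aa in CANONICAL if aa not in "CP")

#: Default label-rule thresholds on the driver statistics.
DEFAULT_THRESHOLDS = {"hemolysis": 0.5, "nonfouling": 0.15, "solubility": 0.4}

#: Per-plastic (aromatic weight alpha, hydrophobic weight beta); PET and PP
#: are more edit-sensitive than PE.
DEFAULT_AFFINITY_COEFS = {"PE": (1.0, 1.0), "PP": (2.0, 1.5), "PET": (3.0, 1.0)}

_MOTIF_POOLS = {
    "hemolysis": "LIFWVA",
    "solubility": "DES",
}
_NONFOULING_UNITS = ("EK", "DK")

_TASK_OFFSET = {t: i for i, t in enumerate(TASKS)}
_PLASTIC_OFFSET = {p: i for i, p in enumerate(PLASTICS)}


@dataclass
class SyntheticSpec:
    """Study conditions for fixture generation.

    length_range bounds the peptide lengths (uniform); thresholds hold the
    per-task label rules; flip_prob in [0, 0.5) is the label-noise rate;
    p_motif is the planting probability of a driver motif; affinity_coefs
    maps plastic -> (alpha, beta); affinity_sigma is the score noise SD and
    score_clip the hard clip range of the energy-like scores.
    """

    n_peptides: int = 1000
    length_range: tuple[int, int] = (5, 30)
    alphabet: str = CANONICAL
    composition: np.ndarray | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    flip_prob: float = 0.05
    p_motif: float = 0.45
    affinity_coefs: dict = field(default_factory=lambda: dict(DEFAULT_AFFINITY_COEFS))
    affinity_sigma: float = 2.0
    score_clip: tuple[float, float] = (-64.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_prob < 0.5):
            raise ValueError("flip_prob must lie in [0, 0.5)")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")
        if self.composition is None:
            self.composition = np.full(len(self.alphabet), 1.0 / len(self.alphabet))
        else:
            self.composition = np.asarray(self.composition, dtype=np.float64)
            self.composition = self.composition / self.composition.sum()


@dataclass
class LabeledPeptide:
    """One synthetic record; true_driver_score is the pre-noise statistic."""

    sequence: str
    task: str
    label: int
    true_driver_score: float


def driver_statistic(sequence: str, task: str) -> float:
    """The sequence statistic that defines the planted label rule.

    hemolysis : fraction of residues that are hydrophobic or aromatic.
    nonfouling : density of adjacent mixed-charge pairs (EK/KE/DK/KD/ER/RE/
        DR/RD) per residue-adjacency.
    solubility : fraction of D/E/S residues.
    """
    validate_sequence(sequence)
    L = len(sequence)
    if task == "hemolysis":
        drivers = HYDROPHOBIC | AROMATIC
        return sum(c in drivers for c in sequence) / L
    if task == "nonfouling":
        if L < 2:
            return 0.0
        pairs = sum(sequence[i:i + 2] in MIXED_CHARGE_PAIRS for i in range(L - 1))
        return pairs / (L - 1)
    if task == "solubility":
        return sum(c in SOLUBILIZING for c in sequence) / L
    raise ValueError(f"unknown task {task!r}; choose from {TASKS}")


def _plant_motif(seq: list[str], task: str, rng: np.random.Generator) -> None:
    """Overwrite a random window with a task-appropriate driver run."""
    L = len(seq)
    run = max(3, int(np.ceil(0.6 * L)))
    run = min(run, L)
    start = int(rng.integers(0, L - run + 1))
    if task == "nonfouling":
        unit = _NONFOULING_UNITS[int(rng.integers(len(_NONFOULING_UNITS)))]
        motif = (unit * (run // 2 + 1))[:run]
    else:
        pool = _MOTIF_POOLS[task]
        motif = "".join(pool[i] for i in rng.integers(len(pool), size=run))
    seq[start:start + run] = list(motif)


def generate_property_dataset(spec: SyntheticSpec, task: str,
                              ) -> list[LabeledPeptide]:
    """Draw ``spec.n_peptides`` labeled peptides for one task.

    Before noise, label = 1 iff the task's driver statistic exceeds the
    task's threshold; labels then flip independently with ``spec.flip_prob``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {TASKS}")
    rng = np.random.default_rng([spec.seed, _TASK_OFFSET[task]])
    lo, hi = spec.length_range
    threshold = spec.thresholds[task]
    letters = np.array(list(spec.alphabet))
    records = []
    for _ in range(spec.n_peptides):
        L = int(rng.integers(lo, hi + 1))
        seq = list(letters[rng.choice(len(letters), size=L, p=spec.composition)])
        if rng.random() < spec.p_motif:
            _plant_motif(seq, task, rng)
        sequence = "".join(seq)
        stat = driver_statistic(sequence, task)
        label = int(stat > threshold)
        if spec.flip_prob > 0 and rng.random() < spec.flip_prob:
            label = 1 - label
        records.append(LabeledPeptide(sequence=sequence, task=task,
                                      label=label, true_driver_score=stat))
    return records


def generate_affinity_library(spec: SyntheticSpec, plastic: str):
    """12-mer library (no C, no P) with clipped energy-like scores.

    score = -(alpha * #aromatic + beta * #hydrophobic) + Normal(0, sigma),
    clipped to ``spec.score_clip``; (alpha, beta) are plastic-specific so the
    substitution landscape differs by plastic.  Returns a DataFrame with
    columns (sequence, plastic, score).
    """
    import pandas as pd

    if plastic not in PLASTICS:
        raise ValueError(f"unknown plastic {plastic!r}; choose from {PLASTICS}")
    rng = np.random.default_rng([spec.seed, 100 + _PLASTIC_OFFSET[plastic]])
    alpha, beta = spec.affinity_coefs[plastic]
    letters = np.array(list(AFFINITY_ALPHABET))
    seqs = ["".join(letters[rng.integers(len(letters), size=12)])
            for _ in range(spec.n_peptides)]
    base = np.array([
        -(alpha * sum(c in AROMATIC for c in s)
          + beta * sum(c in HYDROPHOBIC for c in s))
        for s in seqs
    ])
    noise = (rng.standard_normal(spec.n_peptides) * spec.affinity_sigma
             if spec.affinity_sigma > 0 else np.zeros(spec.n_peptides))
    lo, hi = spec.score_clip
    scores = np.clip(base + noise, lo, hi)
    return pd.DataFrame({"sequence": seqs, "plastic": plastic, "score": scores})
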