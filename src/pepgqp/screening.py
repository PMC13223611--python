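"""Feasibility-first multi-objective peptide screening.

Developability is treated as a set of hard constraints applied sequentially
(non-fouling, then solubility, then non-hemolysis, by default) before the
affinity objective: a peptide passes a stage when its predicted positive
probability clears the stage's cutoff (for hemolysis the pass condition is
*predicted non-hemolytic*, i.e. P(hemolytic) <= 1 - cutoff), and Step 2 then
keeps survivors whose energy-like affinity score is at or below the
plastic-specific threshold (lower = stronger binding; the bound is
inclusive).  Because every stage is a pure set intersection, the final
feasible set is invariant to the filter order even though the per-stage
attrition counts are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .counterfactual import ControlledEffectMatrix, controlled_cse

TASK_ORDER_DEFAULT = ("nonfouling", "solubility", "hemolysis")

#: Default plastic-specific affinity thresholds (pass iff score <= threshold).
DEFAULT_AFFINITY_THRESHOLDS = {"PE": -56.0, "PP": -50.0, "PET": -60.0}


@dataclass
class ScreeningConfig:
    """Cutoffs and ordering of the sequential screen."""

    prob_cutoffs: dict = field(default_factory=lambda: {
        "nonfouling": 0.5, "solubility": 0.5, "hemolysis": 0.5})
    affinity_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_AFFINITY_THRESHOLDS))
    filter_order: tuple = TASK_ORDER_DEFAULT

    def __post_init__(self) -> None:
        if sorted(self.filter_order) != sorted(set(self.filter_order)) or \
                set(self.filter_order) - {"nonfouling", "solubility", "hemolysis"}:
            raise ValueError("filter_order must be a permutation of the three tasks")
        for v in self.affinity_thresholds.values():
            if not np.isfinite(v):
                raise ValueError("affinity thresholds must be finite")


@dataclass
class ScreeningReport:
    """Stage attrition and the final feasible set."""

    plastic: str
    initial_count: int
    stage_names: list[str]
    count_after_each_stage: list[int]
    final_hits: pd.DataFrame          # columns: sequence, score (affinity rank order)
    score_summary_before: dict
    score_summary_after: dict

    def to_dict(self) -> dict:
        return {
            "plastic": self.plastic,
            "initial_count": self.initial_count,
            "stages": dict(zip(self.stage_names, self.count_after_each_stage)),
            "final_hits": self.final_hits.to_dict(orient="records"),
            "score_summary_before": self.score_summary_before,
            "score_summary_after": self.score_summary_after,
        }


def _quantiles(scores: np.ndarray) -> dict:
    if scores.size == 0:
        return {"n": 0}
    qs = np.quantile(scores, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {"n": int(scores.size), "min": float(qs[0]), "q25": float(qs[1]),
            "median": float(qs[2]), "q75": float(qs[3]), "max": float(qs[4])}


def _passes(task: str, prob: np.ndarray, cutoff: float) -> np.ndarray:
    if task == "hemolysis":
        return prob <= 1.0 - cutoff     # pass = predicted non-hemolytic
    return prob >= cutoff


def apply_filters(library: pd.DataFrame, predictions: pd.DataFrame,
                  cfg: ScreeningConfig | None = None,
                  plastic: str | None = None) -> ScreeningReport:
    """Run the sequential developability + affinity screen.

    ``library`` needs columns (sequence, score) and optionally ``plastic``;
    ``predictions`` needs a ``sequence`` column plus one probability column
    per task (positive-class probability).  Raises if any library sequence
    lacks a prediction for any task.
    """
    cfg = cfg or ScreeningConfig()
    if plastic is None:
        plastic = (str(library["plastic"].iloc[0])
                   if "plastic" in library.columns and len(library) else "PE")
    lib = library.reset_index(drop=True)
    pred = predictions.set_index("sequence")
    for task in cfg.filter_order:
        if task not in pred.columns:
            raise ValueError(f"predictions table lacks a {task!r} column")
    missing = [s for s in lib["sequence"] if s not in pred.index]
    if missing:
        raise ValueError(
            f"missing predictions for sequence {missing[0]!r} "
            f"({len(missing)} sequences lack predictions)")

    alive = np.ones(len(lib), dtype=bool)
    stage_names, counts = [], []
    for task in cfg.filter_order:
        prob = pred.loc[lib["sequence"], task].to_numpy(dtype=float)
        alive &= _passes(task, prob, cfg.prob_cutoffs[task])
        stage_names.append(task)
        counts.append(int(alive.sum()))

    threshold = cfg.affinity_thresholds[plastic]
    scores = lib["score"].to_numpy(dtype=float)
    before = _quantiles(scores)
    dev_scores = scores[alive]
    final_mask = alive & (scores <= threshold)
    stage_names.append("affinity")
    counts.append(int(final_mask.sum()))

    hits = lib.loc[final_mask, ["sequence", "score"]].sort_values(
        "score", kind="mergesort").reset_index(drop=True)
    return ScreeningReport(
        plastic=plastic, initial_count=len(lib), stage_names=stage_names,
        count_after_each_stage=counts, final_hits=hits,
        score_summary_before=before,
        score_summary_after=_quantiles(dev_scores),
    )


def order_invariance_check(library: pd.DataFrame, predictions: pd.DataFrame,
                           cfg: ScreeningConfig | None = None,
                           plastic: str | None = None) -> dict:
    """Verify the final feasible set is identical under all 6 filter orders."""
    cfg = cfg or ScreeningConfig()
    results = {}
    for order in permutations(("nonfouling", "solubility", "hemolysis")):
        c = ScreeningConfig(prob_cutoffs=dict(cfg.prob_cutoffs),
                            affinity_thresholds=dict(cfg.affinity_thresholds),
                            filter_order=order)
        rep = apply_filters(library, predictions, c, plastic=plastic)
        results[order] = frozenset(rep.final_hits["sequence"])
    sets = list(results.values())
    return {"invariant": all(s == sets[0] for s in sets),
            "final_set": sorted(sets[0]),
            "per_order_counts": {"/".join(o): len(s) for o, s in results.items()}}


def threshold_sensitivity(library: pd.DataFrame, predictions: pd.DataFrame,
                          cfg: ScreeningConfig, grid,
                          plastic: str | None = None) -> pd.DataFrame:
    """Final-hit counts over a grid of affinity thresholds.

    Counts are non-decreasing as the threshold is relaxed (made less
    negative) because the developability survivor set is fixed.
    """
    cfg = cfg or ScreeningConfig()
    rows = []
    for th in grid:
        c = ScreeningConfig(prob_cutoffs=dict(cfg.prob_cutoffs),
                            affinity_thresholds={**cfg.affinity_thresholds},
                            filter_order=cfg.filter_order)
        key = plastic or (str(library["plastic"].iloc[0])
                          if "plastic" in library.columns and len(library) else "PE")
        c.affinity_thresholds[key] = float(th)
        rep = apply_filters(library, predictions, c, plastic=key)
        rows.append({"threshold": float(th),
                     "hits": rep.count_after_each_stage[-1]})
    return pd.DataFrame(rows)


def screen_cse(affinity_scorer, final_hits, T: float = 1.0,
               bins: dict | None = None, min_stratum: int = 5
               ) -> ControlledEffectMatrix | None:
    """Controlled substitution effects on the selected candidate set.

    ``affinity_scorer`` must expose ``decision_function`` (a logit-like
    output; for the synthetic stack this is the deterministic score model).
    Returns None with a warning for an empty hit set.
    """
    sequences = (list(final_hits["sequence"])
                 if isinstance(final_hits, pd.DataFrame) else list(final_hits))
    if not sequences:
        import warnings
        warnings.warn("screen_cse called with an empty hit set")
        return None
    return controlled_cse(sequences, affinity_scorer, T=T, bins=bins,
                          min_stratum=min_stratum)
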