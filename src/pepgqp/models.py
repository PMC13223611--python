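"""Peptide property classifiers over pooled toy-encoder embeddings.

:class:`PeptideClassifier` is a scikit-learn style estimator: ``fit`` takes a
list of peptide sequences and binary labels, pools the frozen toy-encoder
token embeddings with one of four heads (``gqp``, ``mean``, ``max``,
``attention``) and trains the head plus a single affine logit layer with
seeded minibatch Adam on binary cross-entropy (decoupled weight decay,
gradient clipping, and a divergence rescue that falls back to the best
end-of-epoch parameters if training collapses).  Everything is float64
NumPy with analytic gradients, so repeated fits with the same
``random_state`` are bit-identical.

Also here: evaluation metrics, the label-stratified low-data protocol, and
two simple scorers (:class:`AdditiveSequenceModel`,
:class:`AffinityScorer`) that expose the same ``decision_function`` surface
and serve as transparent references for the counterfactual machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split

from .alphabet import AROMATIC, HYDROPHOBIC
from .encoder import ToyEncoder
from .pooling import (
    AttentionState,
    GQPConfig,
    GateParams,
    QuerySet,
    backward_batch,
    forward_batch,
    masked_softmax,
    pool_peptide,
)

HEAD_KINDS = ("gqp", "mean", "max", "attention")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    """Minimal AdamW-style optimizer over a dict of numpy arrays / floats.

    Weight decay is decoupled and skipped for scalar parameters (biases and
    the shared gate gain).
    """

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay: float = 0.0,
                 decay_overrides: dict | None = None):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.decay_overrides = decay_overrides or {}
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=np.float64)) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = np.asarray(grads[k], dtype=np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if np.isscalar(params[k]) or np.ndim(params[k]) == 0:
                params[k] = float(params[k] - upd)
            else:
                wd = self.decay_overrides.get(k, self.wd)
                # multiplicative decoupled decay, stable for any lr*wd
                params[k] = (params[k] - upd) * max(0.0, 1.0 - self.lr * wd)


def _clip_gradients(grads: dict, max_norm: float | None) -> None:
    """Global-norm gradient clipping; guards the hard-floored gates against
    large steps that would zero them irrecoverably."""
    if max_norm is None:
        return
    total = np.sqrt(sum(float(np.sum(np.square(g))) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale


class PeptideClassifier(BaseEstimator, ClassifierMixin):
    """Binary peptide property classifier with a pooling readout.

    Parameters
    ----------
    head : {"gqp", "mean", "max", "attention"}
        Readout that turns per-token embeddings into a peptide vector.
    d : toy-encoder embedding dimension.
    m : number of learnable queries (gqp head only).
    tau : attention temperature (gqp head).
    epsilon : renormalization stabilizer (gqp head).
    gate_gain_init : initial shared gate gain; 0 starts gating at identity.
    learning_rate, n_epochs, batch_size : Adam settings; ``batch_size=None``
        trains full batch.
    weight_decay : decoupled multiplicative decay on vector parameters.
    attention_decay : optional stronger decay for the readout-geometry
        vectors (queries, attention score vector, gate projections); shrinks
        the readout toward uniform, identity-gated pooling so attention only
        sharpens where the data supports it.  None falls back to
        ``weight_decay``.
    encoder_seed : seed of the frozen toy encoder lookup table.
    positional_mixing : whether the encoder adds its positional signal.
    random_state : seed for head-parameter initialization.

    Fitted attributes (trailing underscore): ``classes_``, ``queries_``,
    ``gates_``, ``coef_``, ``intercept_``, ``loss_curve_``, ``encoder_``.
    """

    def __init__(self, head: str = "gqp", d: int = 16, m: int = 4,
                 tau: float = 0.5, epsilon: float = 1e-6,
                 gate_gain_init: float = 0.0, learning_rate: float = 0.1,
                 n_epochs: int = 150, batch_size: int | None = 32,
                 weight_decay: float = 0.05,
                 attention_decay: float | None = None,
                 max_grad_norm: float | None = 1.0,
                 divergence_rescue: bool = True, rescue_margin: float = 0.05,
                 encoder_seed: int = 0,
                 positional_mixing: bool = True, random_state: int = 0):
        self.head = head
        self.d = d
        self.m = m
        self.tau = tau
        self.epsilon = epsilon
        self.gate_gain_init = gate_gain_init
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.attention_decay = attention_decay
        self.max_grad_norm = max_grad_norm
        self.divergence_rescue = divergence_rescue
        self.rescue_margin = rescue_margin
        self.encoder_seed = encoder_seed
        self.positional_mixing = positional_mixing
        self.random_state = random_state

    # -- parameter plumbing -------------------------------------------------

    def _init_params(self) -> dict:
        rng = np.random.default_rng(self.random_state)
        p: dict = {"w_out": np.zeros(self.d), "b_out": 0.0}
        if self.head == "gqp":
            p["P"] = rng.standard_normal((self.m, self.d)) * 0.2
            p["w_t"] = rng.standard_normal(self.d) / np.sqrt(self.d)
            p["b_t"] = 0.0
            p["w_q"] = rng.standard_normal(self.d) / np.sqrt(self.d)
            p["b_q"] = 0.0
            p["gamma"] = float(self.gate_gain_init)
        elif self.head == "attention":
            p["w_a"] = rng.standard_normal(self.d) * 0.2
        elif self.head not in ("mean", "max"):
            raise ValueError(f"unknown head {self.head!r}; choose from {HEAD_KINDS}")
        return p

    def _gate_params(self, p: dict) -> GateParams:
        return GateParams(w_t=p["w_t"], b_t=p["b_t"], w_q=p["w_q"],
                          b_q=p["b_q"], gamma=p["gamma"])

    def _cfg(self) -> GQPConfig:
        return GQPConfig(tau=self.tau, epsilon=self.epsilon, m=self.m, d=self.d)

    # -- pooling forward/backward ------------------------------------------

    def _pool_forward(self, X: np.ndarray, mask: np.ndarray, p: dict,
                      training: bool) -> tuple[np.ndarray, dict]:
        if self.head == "gqp":
            cache = forward_batch(X, mask, p["P"], self._gate_params(p),
                                  self._cfg(), exact_identity=not training)
            return cache["z"], cache
        if self.head == "mean":
            w = mask[:, :, None].astype(np.float64)
            z = (X * w).sum(axis=1) / w.sum(axis=1)
            return z, {}
        if self.head == "max":
            Xm = np.where(mask[:, :, None], X, -np.inf)
            return Xm.max(axis=1), {}
        # attention: one learned score vector, softmax over valid tokens
        s = (X @ p["w_a"]) / np.sqrt(self.d)
        a = masked_softmax(s, mask)
        z = np.einsum("bl,bld->bd", a, X)
        return z, {"a": a, "X": X, "mask": mask}

    def _pool_backward(self, cache: dict, dz: np.ndarray, p: dict) -> dict:
        if self.head == "gqp":
            return backward_batch(cache, dz)
        if self.head == "attention":
            a, X = cache["a"], cache["X"]
            da = np.einsum("bd,bld->bl", dz, X)
            ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
            return {"w_a": np.einsum("bl,bld->d", ds, X) / np.sqrt(self.d)}
        return {}

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        sequences = list(X)
        y = np.asarray(y, dtype=np.float64)
        if len(sequences) != y.size:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        if not set(classes) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        counts = [(y == c).sum() for c in (0, 1)]
        if min(counts) < 2:
            raise ValueError("need at least 2 examples per class")
        self.classes_ = np.array([0, 1])

        self.encoder_ = ToyEncoder(d=self.d, seed=self.encoder_seed,
                                   positional_mixing=self.positional_mixing)
        Xemb, mask = self.encoder_.encode_batch_arrays(sequences)
        params = self._init_params()
        # warm-start the bias at the empirical log-odds
        pos_rate = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        params["b_out"] = float(np.log(pos_rate / (1 - pos_rate)))
        trainable = {k: v for k, v in params.items()}
        # the readout-geometry vectors (queries, attention score vector, gate
        # projections) shrink toward 0 -- i.e. toward uniform, identity-gated
        # pooling -- more strongly than the linear head, so attention only
        # sharpens where the data supports it
        ad = self.attention_decay
        overrides = ({k: ad for k in ("P", "w_a", "w_t", "w_q") if k in trainable}
                     if ad is not None else {})
        opt = _Adam(trainable, lr=self.learning_rate,
                    weight_decay=self.weight_decay, decay_overrides=overrides)
        n = len(sequences)
        bs = self.batch_size or n
        shuffle_rng = np.random.default_rng(self.random_state + 1)
        losses = []
        eps = 1e-12

        def full_loss(p):
            z, _ = self._pool_forward(Xemb, mask, p, training=True)
            prob = _sigmoid(z @ p["w_out"] + p["b_out"])
            return float(-np.mean(y * np.log(prob + eps)
                                  + (1 - y) * np.log(1 - prob + eps)))

        # hard-floored gates admit an absorbing all-zero state (every token
        # gate clamped to 0 kills the gradient permanently); track the best
        # end-of-epoch parameters and fall back to them only if the final
        # loss is clearly worse -- a divergence rescue, not model selection
        best_loss = full_loss(trainable)
        best_params = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                       for k, v in trainable.items()}
        for _ in range(self.n_epochs):
            order = shuffle_rng.permutation(n) if bs < n else np.arange(n)
            for lo in range(0, n, bs):
                sel = order[lo:lo + bs]
                z, cache = self._pool_forward(Xemb[sel], mask[sel], trainable,
                                              training=True)
                f = z @ trainable["w_out"] + trainable["b_out"]
                prob = _sigmoid(f)
                yb = y[sel]
                df = (prob - yb) / sel.size
                grads = {"w_out": z.T @ df, "b_out": float(df.sum())}
                dz = df[:, None] * trainable["w_out"][None, :]
                grads.update(self._pool_backward(cache, dz, trainable))
                _clip_gradients(grads, self.max_grad_norm)
                opt.step(trainable, grads)
            cur = full_loss(trainable)
            losses.append(cur)
            if cur < best_loss:
                best_loss = cur
                best_params = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                               for k, v in trainable.items()}
        if self.divergence_rescue and losses and \
                losses[-1] > best_loss + self.rescue_margin:
            trainable = best_params
        self.params_ = trainable
        self.coef_ = trainable["w_out"]
        self.intercept_ = float(trainable["b_out"])
        if self.head == "gqp":
            self.queries_ = QuerySet(P=trainable["P"])
            self.gates_ = self._gate_params(trainable)
            self.gamma_ = float(trainable["gamma"])
        self.loss_curve_ = np.array(losses)
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    def decision_function(self, X, chunk_size: int = 4096) -> np.ndarray:
        """Positive-class logits f(s) for a list of sequences."""
        self._check_fitted()
        sequences = list(X)
        out = np.empty(len(sequences))
        p = self.params_
        for lo in range(0, len(sequences), chunk_size):
            batch = sequences[lo:lo + chunk_size]
            Xemb, mask = self.encoder_.encode_batch_arrays(batch)
            z, _ = self._pool_forward(Xemb, mask, p, training=False)
            out[lo:lo + len(batch)] = z @ p["w_out"] + p["b_out"]
        return out

    def predict_proba(self, X) -> np.ndarray:
        f = self.decision_function(X)
        pos = _sigmoid(f)
        return np.column_stack([1 - pos, pos])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)

    def pooled_embedding(self, X) -> np.ndarray:
        """Peptide embeddings z (one row per sequence)."""
        self._check_fitted()
        Xemb, mask = self.encoder_.encode_batch_arrays(list(X))
        z, _ = self._pool_forward(Xemb, mask, self.params_, training=False)
        return z

    def attention_states(self, X, pad_to: int | None = None) -> list[AttentionState]:
        """Per-peptide attention diagnostics (gqp head only)."""
        self._check_fitted()
        if self.head != "gqp":
            raise ValueError("attention states are defined for the gqp head only")
        states = []
        for seq in X:
            tokens = self.encoder_.encode_padded(seq, pad_to=pad_to)
            _, state = pool_peptide(tokens, self.queries_, self.gates_, self._cfg())
            states.append(state)
        return states

    def to_dict(self) -> dict:
        """Serializable checkpoint (versioned JSON-safe dict)."""
        self._check_fitted()
        params = {k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
                  for k, v in self.params_.items()}
        return {"format": "pepgqp-checkpoint", "version": 1,
                "config": self.get_params(), "params": params}

    @classmethod
    def from_dict(cls, payload: dict) -> "PeptideClassifier":
        if payload.get("format") != "pepgqp-checkpoint":
            raise ValueError("not a pepgqp checkpoint")
        model = cls(**payload["config"])
        model.params_ = {
            k: (np.asarray(v, dtype=np.float64) if isinstance(v, list) else float(v))
            for k, v in payload["params"].items()
        }
        model.classes_ = np.array([0, 1])
        model.encoder_ = ToyEncoder(d=model.d, seed=model.encoder_seed,
                                    positional_mixing=model.positional_mixing)
        model.coef_ = model.params_["w_out"]
        model.intercept_ = float(model.params_["b_out"])
        if model.head == "gqp":
            model.queries_ = QuerySet(P=model.params_["P"])
            model.gates_ = model._gate_params(model.params_)
            model.gamma_ = float(model.params_["gamma"])
        return model


# ---------------------------------------------------------------------------
# Reference scorers
# ---------------------------------------------------------------------------

class AdditiveSequenceModel:
    """Position-independent additive scorer f(s) = sum_i w(s_i).

    A transparent model whose substitution effects have the closed form
    (w(a') - w(a)) / T, used as the independent reference for the controlled
    substitution-effect machinery.
    """

    def __init__(self, weights: dict[str, float]):
        self.weights = dict(weights)

    def decision_function(self, X) -> np.ndarray:
        return np.array([sum(self.weights.get(ch, 0.0) for ch in s) for s in X])


class AffinityScorer:
    """Deterministic plastic-affinity score model (lower = stronger binding).

    f(s) = -(alpha * #aromatic + beta * #hydrophobic); the logit-like output
    used when computing substitution effects on the affinity objective.
    """

    def __init__(self, alpha: float, beta: float,
                 aromatic=AROMATIC, hydrophobic=HYDROPHOBIC):
        self.alpha = alpha
        self.beta = beta
        self.aromatic = frozenset(aromatic)
        self.hydrophobic = frozenset(hydrophobic)

    def decision_function(self, X) -> np.ndarray:
        return np.array([
            -(self.alpha * sum(c in self.aromatic for c in s)
              + self.beta * sum(c in self.hydrophobic for c in s))
            for s in X
        ])


# ---------------------------------------------------------------------------
# Training / evaluation wrappers
# ---------------------------------------------------------------------------

def train(dataset, head_kind: str = "gqp", hyperparams: dict | None = None,
          seed: int = 0) -> tuple[PeptideClassifier, np.ndarray]:
    """Fit a classifier on a labeled dataset; returns (model, loss history).

    ``dataset`` is either a DataFrame with ``sequence``/``label`` columns or a
    ``(sequences, labels)`` pair.
    """
    if isinstance(dataset, pd.DataFrame):
        sequences, labels = list(dataset["sequence"]), dataset["label"].to_numpy()
    else:
        sequences, labels = list(dataset[0]), np.asarray(dataset[1])
    model = PeptideClassifier(head=head_kind, random_state=seed,
                              **(hyperparams or {}))
    model.fit(sequences, labels)
    return model, model.loss_curve_


def evaluate(model, sequences, labels) -> dict:
    """Accuracy (0.5 threshold), rank-based AUROC, and confusion counts.

    AUROC is reported as None when the test set has a single class.
    """
    labels = np.asarray(labels, dtype=int)
    prob = model.predict_proba(sequences)[:, 1]
    pred = (prob >= 0.5).astype(int)
    acc = float((pred == labels).mean())
    if np.unique(labels).size < 2:
        auroc = None
    else:
        auroc = float(roc_auc_score(labels, prob))
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    return {"accuracy": acc, "auroc": auroc,
            "confusion": {"tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp)}}


@dataclass
class LowDataProtocol:
    """Label-stratified subsampling protocol for data-efficiency curves."""

    sizes: list[int]
    repeats: int = 5
    stratified: bool = True
    seed_list: list[int] = field(default=None)

    def seeds(self, base_seed: int = 0) -> list[int]:
        if self.seed_list is not None:
            return list(self.seed_list)
        return [base_seed + r for r in range(self.repeats)]


def low_data_curve(train_sequences, train_labels, test_sequences, test_labels,
                   protocol: LowDataProtocol, heads=("gqp", "mean", "max"),
                   hyperparams: dict | None = None, base_seed: int = 0
                   ) -> pd.DataFrame:
    """Accuracy vs training-set size under matched stratified subsampling.

    For each size N and head, draws ``protocol.repeats`` label-stratified
    subsets of the training split (class balance preserved within one sample
    per class), fits with hyperparameters held fixed across all conditions,
    and evaluates on the fixed test split.  Returns a tidy DataFrame with
    columns (N, head, mean_accuracy, sd_accuracy, repeats).
    """
    train_sequences = list(train_sequences)
    y = np.asarray(train_labels, dtype=int)
    rows = []
    for N in protocol.sizes:
        if N > len(train_sequences):
            raise ValueError(f"N={N} exceeds the training split size {len(train_sequences)}")
        # a stratified draw of N needs >= 2 per class to be trainable
        n_pos = int(round(N * y.mean()))
        if min(n_pos, N - n_pos) < 2:
            warnings.warn(f"skipping N={N}: fewer than 2 expected samples per class")
            continue
        for head in heads:
            accs = []
            for seed in protocol.seeds(base_seed):
                if protocol.stratified:
                    idx, _ = train_test_split(
                        np.arange(len(train_sequences)), train_size=N,
                        stratify=y, random_state=seed)
                else:
                    rng = np.random.default_rng(seed)
                    idx = rng.choice(len(train_sequences), size=N, replace=False)
                sub_seq = [train_sequences[i] for i in idx]
                model = PeptideClassifier(head=head, random_state=seed,
                                          **(hyperparams or {}))
                model.fit(sub_seq, y[idx])
                accs.append(evaluate(model, test_sequences, test_labels)["accuracy"])
            rows.append({"N": N, "head": head,
                         "mean_accuracy": float(np.mean(accs)),
                         "sd_accuracy": float(np.std(accs, ddof=1)),
                         "repeats": len(accs)})
    return pd.DataFrame(rows)


def sequence_disjoint_split(sequences, labels, test_size: float = 0.2,
                            seed: int = 0):
    """80/20 split on unique sequence strings (no string in both sides)."""
    sequences = list(sequences)
    labels = np.asarray(labels)
    uniq = sorted(set(sequences))
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    n_test = max(1, int(round(test_size * len(uniq))))
    test_set = set(uniq[:n_test])
    tr, te = [], []
    for i, s in enumerate(sequences):
        (te if s in test_set else tr).append(i)
    tr, te = np.array(tr), np.array(te)
    return ([sequences[i] for i in tr], labels[tr],
            [sequences[i] for i in te], labels[te])
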