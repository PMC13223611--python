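"""Gated query pooling (GQP).

A small set of ``m`` learnable query vectors attends over the token
embeddings of a peptide (scaled dot-product attention with temperature
``tau``); token-wise and query-wise multiplicative gates — identity
initialized through a shared scalar gain ``gamma`` — rescale the attention
weights, which are then renormalized so each query's weights again sum to
one over valid tokens; the gated query summaries are averaged into a single
peptide embedding.

The public functions operate on a single peptide and mirror the conceptual
steps (attend -> gates -> gated renormalization -> summarize/pool); the
``forward_batch`` / ``backward_batch`` pair is the vectorized float64 path
used for training and bulk inference, with analytic gradients for every
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import TokenEmbeddings

NEG_INF = -1e30


@dataclass
class GQPConfig:
    """Configuration of the pooling head.

    tau : attention temperature (>0); logits are divided by ``tau * sqrt(d)``.
    epsilon : stabilizer added to the gated-mass denominator (>0).
    m : number of learnable queries.
    d : embedding dimension.
    gate_gain_init : initial value of the shared scalar gain (0 => gates
        start at exactly 1, i.e. the head starts as plain query attention).
    """

    tau: float = 0.5
    epsilon: float = 1e-6
    m: int = 4
    d: int = 16
    gate_gain_init: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class QuerySet:
    """The learnable query matrix P of shape (m, d)."""

    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[0] < 1:
            raise ValueError("P must be a (m, d) matrix with m >= 1")
        if not np.isfinite(self.P).all():
            raise ValueError("P must be finite")

    @property
    def m(self) -> int:
        return self.P.shape[0]

    @property
    def d(self) -> int:
        return self.P.shape[1]


@dataclass
class GateParams:
    """Affine scalar-output gate projections and the shared gain.

    Token gate:  g_t[l] = max(0, 1 + gamma * (w_t . x_l + b_t))
    Query gate:  g_q[p] = max(0, 1 + gamma * (w_q . P_p + b_q))
    """

    w_t: np.ndarray
    b_t: float
    w_q: np.ndarray
    b_q: float
    gamma: float


@dataclass
class AttentionState:
    """Pre- and post-gating attention for one peptide."""

    A: np.ndarray          # (m, L_tok) row-stochastic over valid tokens
    g_t: np.ndarray        # (L_tok,)
    g_q: np.ndarray        # (m,)
    A_tilde: np.ndarray    # (m, L_tok) gated + renormalized
    valid_mask: np.ndarray = field(default=None)
    residue_at: list[str] = field(default=None)
    special_positions: frozenset[int] = field(default=None)


@dataclass
class PooledOutput:
    H_tilde: np.ndarray    # (m, d) gated query summaries
    z: np.ndarray          # (d,) peptide embedding (mean over queries)


def head_parameter_count(d: int, m: int = 4) -> int:
    """Trainable parameter count of the pooling head itself.

    ``m`` query vectors of dimension ``d``, two scalar-output affine gate
    projections (``d`` weights + 1 bias each) and one shared scalar gain.
    """
    return m * d + 2 * (d + 1) + 1


def masked_softmax(logits: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Row softmax over the last axis restricted to ``valid`` positions.

    Invalid positions get exactly 0.  ``valid`` broadcasts against ``logits``.
    """
    z = np.where(valid, logits, NEG_INF)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    e = np.where(valid, e, 0.0)
    return e / e.sum(axis=-1, keepdims=True)


def attend(queries: QuerySet, tokens: TokenEmbeddings, cfg: GQPConfig) -> np.ndarray:
    """Scaled dot-product attention of each query over valid tokens.

    Logits are ``P X^T / (tau * sqrt(d))``; padding/invalid positions are
    masked before the softmax and carry exactly 0 in the result.
    """
    if queries.d != tokens.d:
        raise ValueError(f"query dim {queries.d} != token dim {tokens.d}")
    if not tokens.valid_mask.any():
        raise ValueError("all token positions are masked")
    logits = queries.P @ tokens.X.T / (cfg.tau * np.sqrt(queries.d))
    return masked_softmax(logits, tokens.valid_mask[None, :])


def compute_gates(tokens: TokenEmbeddings, queries: QuerySet,
                  params: GateParams) -> tuple[np.ndarray, np.ndarray]:
    """Token-wise and query-wise gates, identity-valued at gamma = 0."""
    g_t = np.maximum(0.0, 1.0 + params.gamma * (tokens.X @ params.w_t + params.b_t))
    g_q = np.maximum(0.0, 1.0 + params.gamma * (queries.P @ params.w_q + params.b_q))
    return g_t, g_q


def gate_and_renormalize(A: np.ndarray, g_t: np.ndarray, g_q: np.ndarray,
                         epsilon: float, valid: np.ndarray | None = None
                         ) -> np.ndarray:
    """Multiplicative gating of attention weights with renormalization.

    ``A_tilde[p, l] = g_q[p] g_t[l] A[p, l] / (sum_l' g_q[p] g_t[l'] A[p, l'] + eps)``

    Masked positions stay exactly 0 (they already carry 0 in ``A``).  When
    both gates are identically 1 (the identity initialization) the gated
    product equals ``A`` and each row already sums to one over valid tokens,
    so the renormalization is an exact no-op and is skipped — this keeps the
    ungated limit bit-identical to plain query attention.  A row whose gated
    mass vanishes collapses to ~0 (dominated by epsilon) rather than raising.
    """
    if np.all(g_t == 1.0) and np.all(g_q == 1.0):
        return A.copy()
    u = g_q[..., :, None] * g_t[..., None, :] * A
    den = u.sum(axis=-1, keepdims=True) + epsilon
    return u / den


def summarize_and_pool(A_tilde: np.ndarray, tokens: TokenEmbeddings) -> PooledOutput:
    """Gated query summaries ``H~ = A~ X`` and their mean ``z``."""
    H = A_tilde @ tokens.X
    return PooledOutput(H_tilde=H, z=H.mean(axis=0))


def pool_peptide(tokens: TokenEmbeddings, queries: QuerySet, gates: GateParams,
                 cfg: GQPConfig) -> tuple[PooledOutput, AttentionState]:
    """Full single-peptide GQP pass, retaining the attention state."""
    A = attend(queries, tokens, cfg)
    g_t, g_q = compute_gates(tokens, queries, gates)
    A_tilde = gate_and_renormalize(A, g_t, g_q, cfg.epsilon,
                                   valid=tokens.valid_mask)
    # masked positions must carry exactly 0 even though gates are generic
    A_tilde = np.where(tokens.valid_mask[None, :], A_tilde, 0.0)
    out = summarize_and_pool(A_tilde, tokens)
    state = AttentionState(A=A, g_t=g_t, g_q=g_q, A_tilde=A_tilde,
                           valid_mask=tokens.valid_mask.copy(),
                           residue_at=list(tokens.residue_at),
                           special_positions=tokens.special_positions)
    return out, state


# ---------------------------------------------------------------------------
# Vectorized batched path (training + bulk inference)
# ---------------------------------------------------------------------------

def forward_batch(X: np.ndarray, mask: np.ndarray, P: np.ndarray,
                  gates: GateParams, cfg: GQPConfig,
                  exact_identity: bool = False) -> dict:
    """Batched GQP forward pass.

    Parameters
    ----------
    X : (B, L, d); mask : (B, L) bool; P : (m, d).
    exact_identity : skip the renormalization no-op when both gates are
        identically one (inference path; training keeps the full formula so
        the gamma-gradient at the identity initialization is exact).

    Returns a cache dict with ``z`` (B, d), ``A``, ``A_tilde`` (B, m, L),
    ``g_t`` (B, L), ``g_q`` (m,) and intermediates for the backward pass.
    """
    d = X.shape[-1]
    scale = cfg.tau * np.sqrt(d)
    S = np.einsum("md,bld->bml", P, X) / scale
    A = masked_softmax(S, mask[:, None, :])
    a_t = X @ gates.w_t + gates.b_t                 # (B, L)
    a_q = P @ gates.w_q + gates.b_q                 # (m,)
    pre_t = 1.0 + gates.gamma * a_t
    pre_q = 1.0 + gates.gamma * a_q
    g_t = np.maximum(0.0, pre_t)
    g_q = np.maximum(0.0, pre_q)
    if exact_identity and np.all(g_t[mask] == 1.0) and np.all(g_q == 1.0):
        A_tilde = A
    else:
        u = g_q[None, :, None] * g_t[:, None, :] * A
        den = u.sum(axis=-1, keepdims=True) + cfg.epsilon
        A_tilde = u / den
    H = np.einsum("bml,bld->bmd", A_tilde, X)
    z = H.mean(axis=1)
    return {
        "X": X, "mask": mask, "P": P, "scale": scale, "A": A,
        "a_t": a_t, "a_q": a_q, "pre_t": pre_t, "pre_q": pre_q,
        "g_t": g_t, "g_q": g_q, "A_tilde": A_tilde, "H": H, "z": z,
        "cfg": cfg, "gates": gates,
    }


def backward_batch(cache: dict, dz: np.ndarray) -> dict:
    """Analytic gradients of the batched forward pass.

    ``dz`` has shape (B, d).  Returns gradients for P, w_t, b_t, w_q, b_q,
    gamma.  Token embeddings are treated as fixed (frozen encoder).
    """
    X, mask, P = cache["X"], cache["mask"], cache["P"]
    A, g_t, g_q = cache["A"], cache["g_t"], cache["g_q"]
    gates: GateParams = cache["gates"]
    cfg: GQPConfig = cache["cfg"]
    m = P.shape[0]

    dH = np.repeat(dz[:, None, :] / m, m, axis=1)          # (B, m, d)
    dA_tilde = np.einsum("bmd,bld->bml", dH, X)            # (B, m, L)

    u = g_q[None, :, None] * g_t[:, None, :] * A
    den = u.sum(axis=-1, keepdims=True) + cfg.epsilon
    du = dA_tilde / den - (dA_tilde * u).sum(axis=-1, keepdims=True) / den**2

    dg_q = np.einsum("bml,bl,bml->m", du, g_t, A)
    dg_t = np.einsum("bml,m,bml->bl", du, g_q, A)
    dA = du * g_q[None, :, None] * g_t[:, None, :]

    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dP = np.einsum("bml,bld->md", dS, X) / cache["scale"]

    # query gate path (also feeds P)
    mask_q = (cache["pre_q"] > 0).astype(np.float64)
    dpre_q = dg_q * mask_q
    dgamma = float(np.dot(dpre_q, cache["a_q"]))
    da_q = dpre_q * gates.gamma
    dP += np.outer(da_q, gates.w_q)
    dw_q = P.T @ da_q
    db_q = float(da_q.sum())

    # token gate path (only valid positions carry attention mass, and A is 0
    # elsewhere, so dg_t is already 0 at masked positions)
    mask_t = (cache["pre_t"] > 0).astype(np.float64)
    dpre_t = dg_t * mask_t
    dgamma += float((dpre_t * cache["a_t"]).sum())
    da_t = dpre_t * gates.gamma
    dw_t = np.einsum("bl,bld->d", da_t, X)
    db_t = float(da_t.sum())

    return {"P": dP, "w_t": dw_t, "b_t": db_t, "w_q": dw_q, "b_q": db_q,
            "gamma": dgamma}
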