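import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pepgqp as pg
from pepgqp.encoder import TokenEmbeddings, ToyEncoder
from pepgqp.pooling import (
    GQPConfig,
    GateParams,
    QuerySet,
    attend,
    backward_batch,
    compute_gates,
    forward_batch,
    gate_and_renormalize,
    head_parameter_count,
    pool_peptide,
    summarize_and_pool,
)

CANON = "ACDEFGHIKLMNPQRSTVWY"


def make_tokens(X, valid=None, residues=None):
    X = np.asarray(X, dtype=np.float64)
    if valid is None:
        valid = np.ones(X.shape[0], dtype=bool)
    residues = residues or ["A"] * X.shape[0]
    return TokenEmbeddings(X=X, valid_mask=np.asarray(valid, bool),
                           special_positions=frozenset(), residue_at=residues)


def random_gates(d, seed=0, gamma=0.7):
    rng = np.random.default_rng(seed)
    return GateParams(w_t=rng.standard_normal(d) * 0.4, b_t=0.1,
                      w_q=rng.standard_normal(d) * 0.4, b_q=-0.1, gamma=gamma)


class TestAttend:
    def test_identical_rows_give_uniform_weights(self):
        tokens = make_tokens(np.ones((5, 3)))
        A = attend(QuerySet(P=np.random.default_rng(0).standard_normal((2, 3))),
                   tokens, GQPConfig(d=3, m=2))
        np.testing.assert_allclose(A, 0.2)

    def test_hand_computed_softmax(self):
        # d=1, tau=1: logits (0, ln 3) -> weights (0.25, 0.75)
        tokens = make_tokens([[0.0], [np.log(3.0)]])
        A = attend(QuerySet(P=[[1.0]]), tokens, GQPConfig(tau=1.0, d=1, m=1))
        np.testing.assert_allclose(A, [[0.25, 0.75]], atol=1e-12)

    def test_high_temperature_flattens(self):
        rng = np.random.default_rng(1)
        tokens = make_tokens(rng.standard_normal((6, 4)))
        A = attend(QuerySet(P=rng.standard_normal((3, 4))), tokens,
                   GQPConfig(tau=1e6, d=4, m=3))
        np.testing.assert_allclose(A, 1 / 6, atol=1e-4)

    def test_masked_positions_are_exactly_zero(self):
        tokens = make_tokens(np.random.default_rng(2).standard_normal((5, 3)),
                             valid=[True, True, True, False, False])
        A = attend(QuerySet(P=np.eye(2, 3)), tokens, GQPConfig(d=3, m=2))
        assert (A[:, 3:] == 0.0).all()
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_all_masked_is_an_error(self):
        X = np.zeros((2, 3))
        with pytest.raises(ValueError):
            tokens = TokenEmbeddings(X=X, valid_mask=np.zeros(2, bool),
                                     special_positions=frozenset(),
                                     residue_at=["A", "A"])


class TestGates:
    def test_identity_at_zero_gain(self):
        tokens = make_tokens(np.random.default_rng(0).standard_normal((4, 3)))
        P = QuerySet(P=np.random.default_rng(1).standard_normal((2, 3)))
        g_t, g_q = compute_gates(tokens, P, random_gates(3, gamma=0.0))
        np.testing.assert_array_equal(g_t, 1.0)
        np.testing.assert_array_equal(g_q, 1.0)

    @pytest.mark.parametrize("proj,expected", [(-2.0, 0.0), (0.5, 1.5)])
    def test_affine_form_and_clamp(self, proj, expected):
        # craft w_t so that w_t . x + b_t equals `proj` for a unit token
        tokens = make_tokens([[1.0]])
        P = QuerySet(P=[[1.0]])
        params = GateParams(w_t=np.array([proj]), b_t=0.0,
                            w_q=np.array([0.0]), b_q=0.0, gamma=1.0)
        g_t, _ = compute_gates(tokens, P, params)
        assert g_t[0] == expected


class TestGateAndRenormalize:
    def test_identity_gating_returns_A_bitwise(self):
        A = np.random.default_rng(0).dirichlet(np.ones(5), size=3)
        out = gate_and_renormalize(A, np.ones(5), np.ones(3), epsilon=1e-6)
        np.testing.assert_array_equal(out, A)

    def test_constant_token_gate_cancels(self):
        A = np.random.default_rng(1).dirichlet(np.ones(4), size=2)
        out = gate_and_renormalize(A, np.full(4, 3.0), np.ones(2), epsilon=0.0)
        np.testing.assert_allclose(out, A, atol=1e-12)

    def test_hand_computed_reweighting(self):
        out = gate_and_renormalize(np.array([[0.5, 0.5]]), np.array([1.0, 3.0]),
                                   np.array([1.0]), epsilon=0.0)
        np.testing.assert_allclose(out, [[0.25, 0.75]], atol=1e-15)

    def test_zero_mass_row_collapses_without_raising(self):
        out = gate_and_renormalize(np.array([[0.5, 0.5]]), np.zeros(2),
                                   np.array([1.0]), epsilon=1e-6)
        assert np.all(out == 0.0)


class TestSummarizeAndPool:
    def test_mean_of_query_summaries(self):
        tokens = make_tokens([[0.0, 2.0], [2.0, 0.0]])
        out = summarize_and_pool(np.eye(2), tokens)
        np.testing.assert_allclose(out.H_tilde, [[0, 2], [2, 0]])
        np.testing.assert_allclose(out.z, [1.0, 1.0])

    def test_single_query_passthrough(self):
        tokens = make_tokens(np.random.default_rng(0).standard_normal((3, 4)))
        A = np.random.default_rng(1).dirichlet(np.ones(3), size=1)
        out = summarize_and_pool(A, tokens)
        np.testing.assert_allclose(out.z, out.H_tilde[0])

    def test_identical_tokens_dominate_any_gating(self):
        v = np.array([1.5, -2.0, 0.5])
        tokens = make_tokens(np.tile(v, (6, 1)))
        P = QuerySet(P=np.random.default_rng(3).standard_normal((4, 3)))
        out, _ = pool_peptide(tokens, P, random_gates(3, seed=4), GQPConfig(d=3))
        # epsilon leaves a ~1e-6 renormalization deficit
        np.testing.assert_allclose(out.z, v, atol=1e-5)


class TestHeadProperties:
    def test_parameter_count_closed_form(self):
        assert head_parameter_count(1280, 4) == 7683
        assert head_parameter_count(16, 4) == 4 * 16 + 2 * 17 + 1

    def test_z_in_convex_hull_of_valid_tokens(self):
        enc = ToyEncoder(d=6, seed=0)
        tokens = enc.encode_padded("ACDEFGHIK", pad_to=15)
        P = QuerySet(P=np.random.default_rng(1).standard_normal((4, 6)))
        out, state = pool_peptide(tokens, P, random_gates(6, seed=2),
                                  GQPConfig(d=6))
        w = state.A_tilde.mean(axis=0)
        assert (w >= 0).all()
        assert abs(w.sum() - 1.0) < 1e-5
        np.testing.assert_allclose(out.z, w @ tokens.X, atol=1e-12)

    def test_permutation_invariance_without_positions(self):
        enc = ToyEncoder(d=8, seed=3, positional_mixing=False)
        P = QuerySet(P=np.random.default_rng(4).standard_normal((4, 8)))
        gates = random_gates(8, seed=5)
        cfg = GQPConfig(d=8)
        z1 = pool_peptide(enc.encode("ACDEFGHIK"), P, gates, cfg)[0].z
        z2 = pool_peptide(enc.encode("KIHGFEDCA"), P, gates, cfg)[0].z
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_infinite_temperature_recovers_masked_mean(self):
        enc = ToyEncoder(d=16, seed=6)
        tokens = enc.encode("ACDEFGHIKLMNQRST")
        P = QuerySet(P=np.random.default_rng(7).standard_normal((4, 16)))
        cfg = GQPConfig(tau=1e4, d=16)
        out, _ = pool_peptide(tokens, P, random_gates(16, gamma=0.0), cfg)
        mean = tokens.X[tokens.valid_mask].mean(axis=0)
        assert np.abs(out.z - mean).max() < 1e-3

    def test_padded_and_unpadded_pooling_agree(self):
        enc = ToyEncoder(d=8, seed=8)
        P = QuerySet(P=np.random.default_rng(9).standard_normal((4, 8)))
        gates = random_gates(8, seed=10)
        cfg = GQPConfig(d=8)
        z1 = pool_peptide(enc.encode("WYKLM"), P, gates, cfg)[0].z
        z2 = pool_peptide(enc.encode_padded("WYKLM", pad_to=20), P, gates, cfg)[0].z
        np.testing.assert_allclose(z1, z2, atol=1e-12)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        B, L, d, m = 4, 7, 6, 3
        X = rng.standard_normal((B, L, d))
        mask = np.ones((B, L), bool)
        mask[0, 5:] = False
        X[0, 5:] = 0
        P = rng.standard_normal((m, d)) * 0.3
        gp = GateParams(w_t=rng.standard_normal(d) * 0.3, b_t=0.1,
                        w_q=rng.standard_normal(d) * 0.3, b_q=-0.2, gamma=0.7)
        cfg = GQPConfig(tau=0.5, m=m, d=d)
        w_out = rng.standard_normal(d)
        y = rng.integers(0, 2, B).astype(float)

        def loss(P_, gp_):
            c = forward_batch(X, mask, P_, gp_, cfg)
            f = c["z"] @ w_out
            p = 1 / (1 + np.exp(-f))
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)), c

        base, cache = loss(P, gp)
        prob = 1 / (1 + np.exp(-(cache["z"] @ w_out)))
        dz = ((prob - y) / B)[:, None] * w_out[None, :]
        g = backward_batch(cache, dz)

        h = 1e-6

        def fd(make):
            lp, _ = loss(*make(+h))
            lm, _ = loss(*make(-h))
            return (lp - lm) / (2 * h)

        # query matrix entry
        def dP(eps):
            P2 = P.copy(); P2[1, 2] += eps
            return P2, gp
        assert abs(fd(dP) - g["P"][1, 2]) / abs(g["P"][1, 2]) < 1e-3

        # shared gain
        def dgam(eps):
            return P, dataclasses.replace(gp, gamma=gp.gamma + eps)
        assert abs(fd(dgam) - g["gamma"]) / abs(g["gamma"]) < 1e-3

        # token-gate projection
        def dwt(eps):
            w = gp.w_t.copy(); w[3] += eps
            return P, dataclasses.replace(gp, w_t=w)
        assert abs(fd(dwt) - g["w_t"][3]) / abs(g["w_t"][3]) < 1e-3

        # query-gate projection: its true gradient is epsilon-scale (the
        # query gate nearly cancels under renormalization), so compare with
        # an absolute tolerance
        def dwq(eps):
            w = gp.w_q.copy(); w[1] += eps
            return P, dataclasses.replace(gp, w_q=w)
        assert abs(fd(dwq) - g["w_q"][1]) < 1e-6


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seq=st.text(alphabet=CANON, min_size=1, max_size=30),
       gamma=st.floats(-1.0, 1.0))
def test_row_stochasticity_property(seq, gamma):
    """A and A~ rows sum to 1 over valid tokens for arbitrary peptides/gates."""
    enc = ToyEncoder(d=6, seed=0)
    tokens = enc.encode_padded(seq, pad_to=len(seq) + 5)
    P = QuerySet(P=np.random.default_rng(1).standard_normal((3, 6)))
    _, state = pool_peptide(tokens, P, random_gates(6, seed=2, gamma=gamma),
                            GQPConfig(d=6))
    np.testing.assert_allclose(state.A.sum(axis=1), 1.0, atol=1e-6)
    # each row's renormalized mass is exactly m_p / (m_p + eps) where m_p is
    # the row's gated mass before renormalization
    row_mass = state.A_tilde.sum(axis=1)
    if np.all(state.g_t == 1.0) and np.all(state.g_q == 1.0):
        # identity gating short-circuits the (no-op) renormalization
        np.testing.assert_allclose(row_mass, 1.0, atol=1e-6)
    else:
        gated = state.g_q[:, None] * state.g_t[None, :] * state.A
        m_p = gated.sum(axis=1)
        np.testing.assert_allclose(row_mass, m_p / (m_p + 1e-6), atol=1e-9)
    assert (state.A[:, ~tokens.valid_mask] == 0).all()
    assert (state.A_tilde[:, ~tokens.valid_mask] == 0).all()
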