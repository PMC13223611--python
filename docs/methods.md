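# Methods

## The readout

A sequence encoder maps a peptide of length `L` to per-token embeddings
`X ∈ R^{L_tok × d}` (CLS prepended, EOS appended, optional right padding).
Gated query pooling (GQP) turns these into a single peptide vector in four
steps:

1. **Query attention.** `m` learnable query vectors `P ∈ R^{m×d}` attend over
   the tokens with scaled dot-product logits `P Xᵀ / (τ√d)`; padding positions
   are masked before the softmax, so each query's weights `A_p·` are a
   probability distribution over valid tokens.
2. **Gates.** A token-wise gate `gᵗ_l = max(0, 1 + γ(w_tᵀx_l + b_t))` and a
   query-wise gate `g_q^p = max(0, 1 + γ(w_qᵀP_p + b_q))`, both scalar affine
   projections through one shared gain `γ`. At `γ = 0` every gate is exactly 1,
   so gating starts from the identity and is learned gradually.
3. **Gated renormalization.**
   `Ã_pl = g_q^p gᵗ_l A_pl / (Σ_{l'} g_q^p gᵗ_{l'} A_pl' + ε)` with
   `ε = 1e-6`. Each row again sums to ~1 over valid tokens (deficit
   `m_p/(m_p+ε)` where `m_p` is the row's gated mass); masked positions stay
   exactly 0. When both gate vectors are identically 1, renormalizing an
   already row-stochastic matrix is a mathematical no-op, and the inference
   path skips it — this makes the `γ = 0` head bit-identical to plain query
   attention. Training always evaluates the full expression so the gradient
   of `γ` at the identity initialization is exact.
4. **Pooling.** `H̃ = ÃX`; the peptide embedding `z` is the mean of the `m`
   query summaries. A single affine layer maps `z` to the positive-class
   logit.

Defaults: `m = 4`, `τ = 0.5` (dividing the logits by `τ√d`, i.e. the
temperature composes with the standard scale), `ε = 1e-6`, `γ` initialized at
0, hard clamp at 0 for both gates. At `d = 1280` the head has
`m·d + 2(d+1) + 1 = 7683` trainable parameters.

The toy encoder is a seeded per-residue lookup table (unit-scale Gaussian
rows for the 20 residues plus CLS/EOS/PAD) with an additive fixed
sinusoid-like positional signal of amplitude 0.25; switching the positional
signal off makes the encoder permutation-covariant, which several invariance
tests exploit. External protein language models can plug in behind the same
`TokenEmbeddings` contract; no pretrained weights ship with the package.

## Training

The head (and only the head — the encoder is frozen) is trained with seeded
minibatch Adam (batch 32, lr 0.1, 150 epochs by default) on binary
cross-entropy, in float64 NumPy with hand-written analytic gradients
(verified against central finite differences to relative error < 1e-3 in the
test suite; the query-gate gradient is ε-scale by construction, since the
query gate nearly cancels under renormalization, and is checked with an
absolute tolerance). Three robustness measures address a failure mode
specific to hard-floored gates — an absorbing state in which every token
gate clamps to 0, the pooled embedding becomes 0, and all gradients vanish:

- decoupled multiplicative weight decay (default 0.05) on all vector
  parameters, applied as `θ ← θ·max(0, 1 − lr·λ)` so it is stable for any
  `lr·λ`;
- global gradient-norm clipping (default 1.0);
- a divergence rescue: the full-data training loss is evaluated after every
  epoch, and the final model falls back to the best end-of-epoch parameters
  only if the last epoch's loss exceeds the best by more than 0.05. This is
  a guard against collapse, not continuous model selection.

Learning rates at or above 0.3 (full batch) visibly destabilize the gates;
the defaults were chosen so that the noise-free planted-motif set (n = 200)
is fit to ≥ 0.95 training accuracy within 50 epochs.

An optional `attention_decay` applies a stronger decay to the
readout-geometry vectors (queries, attention score vector, gate
projections). Shrinking these toward 0 shrinks the readout toward uniform,
identity-gated pooling — the same inductive-bias argument as the identity
gate initialization: attention should sharpen only where the data support
it. This matters at very small training sizes, where a freely-learned
attention pattern otherwise adds variance that uniform mean pooling does not
have.

## Diagnostics

Token mass: `M_l = Σ_p Ã_pl`, zero at masked positions; totals ≈ `m` per
peptide. Class mass: for class `y`, `M_y(aa)` sums the token masses over all
residue positions carrying `aa` across class-`y` peptides and divides by
`N_y`, the total residue-position count of the class — CLS, EOS and padding
are excluded, because special tokens can attract disproportionate mass. The
contrast is `ΔM(aa) = M_1(aa) − M_0(aa)`. These are routing diagnostics;
no faithfulness claim is attached, which is why the substitution analysis
below is the primary source of edit guidance.

## Controlled substitution effects

For a fixed trained scorer `f`, the raw effect of substituting position `i`
from `a` to `a'` is `Δ = (f(s') − f(s)) / max(T, 1e-3)`, with `T = 1` by
default; every occupied position contributes all 19 non-identity targets,
and each mutant is fully re-encoded. The sequence is the unit of analysis:
per-sequence effects average over all positions carrying `a`; sequences
without `a` are excluded (not zero-filled).

Standardization: sequences are stratified by net charge
`Q = #(K,R) + 0.1·#(H) − #(D,E)`, hydrophobic fraction (default set
{A,C,F,I,L,M,V,W}, configurable everywhere), and length, with bin widths
1.0 / 0.05 / 25 and half-open bins anchored at 0 (negatives floor downward;
a hydrophobic fraction of exactly 1.0 goes to the top bin). For each
from-residue `a`, strata with fewer than five sequences containing `a` are
excluded and the remaining empirical weights renormalized; the controlled
effect CSE(a→a') is the weighted average of per-stratum means — a discrete
standardization (g-formula). Intervenability `I(a)` is the mean of the 19
entries in row `a`; rows with no eligible stratum are reported missing
rather than imputed.

Numerical choices worth noting:

- Default-width bin indices use exact integer arithmetic (charge in tenths;
  hydrophobic bins as `(20·count)//L`), so boundary values such as ten
  histidines (Q = 1.0) can never misbin through floating-point error.
  Non-default widths use `floor(value/width)` with a 1e-9 nudge.
- The weighted combination is computed as `Σ_c n_c·mean_c / Σ_c n_c`. For an
  additive scorer with dyadic weights this makes CSE(a→a') equal
  `(w(a') − w(a))/T` bit-exactly for any stratification — the unbiasedness
  property the test suite asserts.

## Screening

Developability is a set of hard feasibility constraints applied before the
affinity objective: a peptide passes non-fouling and solubility when the
predicted positive probability is at least the cutoff (default 0.5), and
passes the hemolysis stage when the predicted hemolytic probability is at
most 1 − cutoff. Step 2 keeps survivors whose energy-like affinity score is
at or below the plastic threshold (inclusive bound; defaults PE ≤ −56,
PP ≤ −50, PET ≤ −60). Stage counts are recorded in filter order; the final
feasible set is a pure intersection and therefore order-invariant, which
`order_invariance_check` verifies over all six orders. Hit counts are
non-decreasing as the affinity threshold relaxes.

## Synthetic data

The generator defines the study conditions. Property datasets draw residues
i.i.d. (uniform by default) with lengths uniform on 5–30, then plant a
driver motif with probability 0.45: a hydrophobic/aromatic run for
hemolysis, EK/DK repeats for non-fouling, a D/E/S run for solubility; run
length is ~60% of the peptide. Labels threshold the driver statistic
(hydrophobic∪aromatic fraction > 0.5; adjacent mixed-charge pair density >
0.15; D/E/S fraction > 0.4) and then flip independently with probability
0.05 by default. Affinity libraries are 12-mers over the 18-letter alphabet
excluding C and P, scored
`−(α·#aromatic + β·#hydrophobic) + N(0, σ)` with per-plastic
(α, β) = PE (1, 1), PP (2, 1.5), PET (3, 1) and σ = 2, clipped to
[−64, +12] (lower = stronger predicted binding); PET and PP are thus more
edit-sensitive than PE by construction.

What the generator does **not** emulate: real amino-acid composition biases,
the long length tail of solubility data, measurement-level label conflicts,
or any real adsorption energetics. Passing tests therefore demonstrate that
the algorithms are implemented correctly and recover planted structure under
noise — not that the models would reach any particular accuracy on
experimental data.

## Benchmark protocols and problem sizes

- Driver recovery: hemolysis, n = 2000, flip 0.05, five training seeds;
  ΔM is computed on a deterministic 500-peptide subsample, CSE on a seeded
  250-sequence subsample (the scan costs 19·L forward passes per sequence).
- Pooling comparison: the planted-motif benchmark is the non-fouling task —
  its driver is literally a planted adjacent-pair motif, whereas the other
  two tasks are purely compositional. Training sizes N ∈ {50, 100, 200},
  five label-stratified repeats, identical hyperparameters for every head
  (full batch, lr 0.05, 400 epochs, attention_decay 10, no clipping).
  With a context-free toy encoder the composition-threshold labels make
  masked-mean pooling close to a matched readout, so the GQP margins here
  are small; with contextual embeddings the gap would be expected to widen.
- The end-to-end CLI pipeline runs at n ≈ 100–500 peptides in seconds to a
  few minutes on one CPU.

## Known limitations

- The toy encoder is context-free: attention can reweight (residue,
  position) content but cannot represent neighbor interactions, which caps
  the achievable advantage of any learned readout on compositional labels.
- Hard-clamped gates can zero out tokens irrecoverably during training; the
  divergence rescue restores a healthy checkpoint but does not prevent the
  wasted epochs.
- CSE rows for rare residues are missing at small n because no stratum
  reaches five qualifying sequences; this is reported, not imputed.
- The hemolysis filter operates on the hemolytic-positive probability so one
  positive-class convention holds across the codebase.
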