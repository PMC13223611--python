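# pepgqp

Gated query pooling for peptide property prediction, with residue-level
interpretability and a feasibility-first multi-objective screening pipeline.

## The problem

Peptide candidates for applications such as microplastic capture must
satisfy *developability* constraints — low hemolysis, resistance to
nonspecific adsorption (non-fouling), and aqueous solubility — alongside the
actual binding objective. Sequence-only predictors for these properties pool
per-residue embeddings from a sequence encoder into one peptide vector, and
the pooling step is a high-leverage design choice: coarse global statistics
(mean, max) can wash out the residue-level evidence that drives a property.

**Gated query pooling (GQP)** is an evidence-selective readout. A small set
of `m` learnable query vectors attends over the token embeddings
(`A = softmax(P Xᵀ / τ√d)` over valid tokens), token-wise and query-wise
multiplicative gates — identity-initialized through a shared scalar gain —
rescale the attention weights, which are renormalized so each query's
weights again sum to one, and the gated query summaries `H̃ = ÃX` are
averaged into the peptide embedding `z`. At `d = 1280`, `m = 4` the head
adds only 7 683 parameters.

On top of the classifier the package implements:

- **Attention diagnostics** — token mass `M_l = Σ_p Ã_pl` and the
  frequency-weighted class contrast `ΔM(aa) = M_1(aa) − M_0(aa)`
  (special tokens excluded), showing where the readout routes evidence;
- **Controlled substitution effects (CSE)** — in-silico saturation
  mutagenesis `Δ = (f(s') − f(s))/max(T, 10⁻³)` over all 19 non-identity
  substitutions per position, aggregated at the sequence level and
  standardized across strata of net charge, hydrophobic fraction and length
  (the g-formula), plus per-residue *intervenability* (row means);
- **Sequential screening** — developability filters (non-fouling →
  solubility → non-hemolysis at probability cutoffs) followed by inclusive
  plastic-specific affinity thresholds (PE ≤ −56, PP ≤ −50, PET ≤ −60 on
  energy-like scores where lower is better), with stage attrition reports
  and order-invariance checking;
- **A synthetic peptide generator** with planted residue-level drivers
  (hydrophobic/aromatic → hemolytic, EK/DK mixed-charge pairs →
  non-fouling, D/E/S → soluble), label noise, and 12-mer affinity libraries
  (no C/P) with clipped energy-like scores — so the whole stack is testable
  end to end with no downloads and a deterministic toy encoder.

Everything is float64 NumPy with hand-written analytic gradients; fits are
bit-reproducible given a seed. External protein language models can plug in
behind the same token-embedding contract.

## Worked example

```python
import numpy as np
import pepgqp as pg
from pepgqp.models import sequence_disjoint_split

spec = pg.SyntheticSpec(n_peptides=2000, flip_prob=0.05, seed=0)
recs = pg.generate_property_dataset(spec, "hemolysis")
seqs = [r.sequence for r in recs]
y = np.array([r.label for r in recs])
tr_s, tr_y, te_s, te_y = sequence_disjoint_split(seqs, y, seed=0)

model = pg.PeptideClassifier(head="gqp", random_state=0).fit(tr_s, tr_y)
ev = pg.evaluate(model, te_s, te_y)
print(f"accuracy={ev['accuracy']:.3f}  auroc={ev['auroc']:.3f}")

summary = pg.model_class_mass(model, te_s, te_y)
print(f"dM(F)={summary.delta_M['F']:+.4f}  dM(K)={summary.delta_M['K']:+.4f}")

matrix = pg.controlled_cse(te_s[:250], model)
iv = matrix.intervenability_series().dropna().sort_values()
print(iv.head(5).round(3).to_string())
```

prints

```
accuracy=0.865  auroc=0.919
dM(F)=+0.0103  dM(K)=-0.0107
F   -0.616
A   -0.516
V   -0.474
L   -0.441
W   -0.341
```

Read: the classifier reaches 86.5% held-out accuracy on the noisy planted
task; phenylalanine draws more gated attention mass in the hemolytic class
while lysine draws more in the non-hemolytic class (`ΔM`); and the most
negative intervenability scores all belong to hydrophobic/aromatic residues
— substituting away from F, A, V, L or W lowers the predicted hemolysis
logit, recovering exactly the drivers the generator planted.

A command-line surface wraps the same library:

```bash
pepgqp simulate --n 500 --seed 7 --plastic PE --out-dir runs/data
pepgqp train --data runs/data/hemolysis.tsv --out runs/hemolysis.json
pepgqp explain --model runs/hemolysis.json --data runs/data/hemolysis.tsv --out-dir runs/explain
pepgqp cse --model runs/hemolysis.json --data runs/data/hemolysis.tsv --out-dir runs/cse
pepgqp screen --library runs/data/affinity_PE.tsv --predictions runs/preds.tsv --out-dir runs/screen
```

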