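import numpy as np
import pytest

import pepgqp as pg


@pytest.fixture(scope="session")
def hemolysis_small():
    """Noise-free separable planted-motif set (n=200)."""
    spec = pg.SyntheticSpec(n_peptides=200, flip_prob=0.0, seed=7)
    recs = pg.generate_property_dataset(spec, "hemolysis")
    return [r.sequence for r in recs], np.array([r.label for r in recs])


@pytest.fixture(scope="session")
def trained_gqp(hemolysis_small):
    seqs, y = hemolysis_small
    model = pg.PeptideClassifier(head="gqp", n_epochs=80, random_state=0)
    return model.fit(seqs, y)


@pytest.fixture(scope="session")
def additive_model():
    """Additive scorer with dyadic (quarter-integer) weights.

    All partial sums of these weights are exactly representable in float64,
    so substitution effects have a bit-exact closed form.
    """
    rng = np.random.default_rng(5)
    w = {aa: float(rng.integers(-32, 33)) / 4.0 for aa in pg.alphabet.CANONICAL}
    return pg.AdditiveSequenceModel(w)


@pytest.fixture()
def toy_library():
    """Six-peptide hand-traceable screening library."""
    import pandas as pd
    seqs = [f"SEQ{i}" for i in range(1, 7)]
    # screening operates on sequence strings only; use canonical 12-mers
    seqs = ["AAAAAAAAAAAG", "AAAAAAAAAAAL", "AAAAAAAAAAAK",
            "AAAAAAAAAAAD", "AAAAAAAAAAAE", "AAAAAAAAAAAS"]
    library = pd.DataFrame({"sequence": seqs, "plastic": "PE",
                            "score": [-60.0, -60.0, -60.0, -60.0, -40.0, -58.0]})
    predictions = pd.DataFrame({
        "sequence": seqs,
        "nonfouling": [0.9, 0.9, 0.2, 0.9, 0.9, 0.9],
        "solubility": [0.9, 0.4, 0.9, 0.9, 0.9, 0.9],
        "hemolysis": [0.1, 0.1, 0.1, 0.8, 0.1, 0.1],
    })
    return library, predictions
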