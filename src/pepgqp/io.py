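"""FASTA / TSV / JSON / YAML input-output and checkpoint persistence.

All user-facing tables use 1-based residue positions (internal code is
0-based); numeric columns round-trip at full float64 precision.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .alphabet import validate_sequence
from .models import PeptideClassifier


def read_fasta(path) -> list[tuple[str, str]]:
    """Read peptides from FASTA: order-preserving (id, SEQUENCE) pairs.

    Sequences are uppercased; non-canonical residues and duplicate ids are
    rejected with position-level messages; an empty file is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        validate_sequence(seq, name=f"record {rec.id!r}")
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with _atomic_open(path) as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class _atomic_open:
    """Write to a temp file in the target directory, then rename."""

    def __init__(self, path):
        self.path = Path(path)

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, self.tmp = tempfile.mkstemp(dir=self.path.parent,
                                        prefix=self.path.name + ".")
        self.fh = os.fdopen(fd, "w")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False


def write_tsv(frame: pd.DataFrame, path) -> None:
    """Full-precision TSV (round-trip delta 0 for float64 columns)."""
    with _atomic_open(path) as fh:
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_tsv(path) -> pd.DataFrame:
    # round_trip parsing so full-precision floats survive write -> read
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_json(obj, path) -> None:
    with _atomic_open(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_yaml(obj, path) -> None:
    with _atomic_open(path) as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_model(model: PeptideClassifier, path) -> None:
    """Versioned structured-text (JSON) checkpoint of a fitted classifier."""
    write_json(model.to_dict(), path)


def load_model(path) -> PeptideClassifier:
    with open(path) as fh:
        return PeptideClassifier.from_dict(json.load(fh))


def write_cse_matrix(matrix, out_dir, stem: str) -> None:
    """Export a ControlledEffectMatrix: 20x20 grid + intervenability ranking."""
    out_dir = Path(out_dir)
    grid = matrix.to_frame()
    grid.insert(0, "from", grid.index)
    write_tsv(grid.reset_index(drop=True), out_dir / f"{stem}_cse_matrix.tsv")
    iv = matrix.intervenability_series().rename("intervenability")
    iv_frame = iv.dropna().sort_values().reset_index()
    iv_frame.columns = ["residue", "intervenability"]
    write_tsv(iv_frame, out_dir / f"{stem}_intervenability.tsv")


def read_cse_matrix(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index("from")
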