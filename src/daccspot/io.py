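"""File formats: FASTA in, matrices / reports / model archives out.

Sequence input is multi-FASTA (multi-line records and CRLF endings are
handled by Biopython).  Labels arrive either as a two-column TSV
(``id<TAB>label`` with labels ``hot``/``cold`` or ``+1``/``-1``) or as two
separate FASTA files, one per class.  Feature matrices are written as CSV
(id + label + one column per feature) or sparse LIBSVM text; evaluation
reports as JSON; fitted models as a single joblib archive bundling the
encoding configuration, the optional PCA model, and the SVM state.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .encoding import EncodingConfig, FeatureMatrix
from .errors import FastaError
from .evaluation import EvaluationResult
from .pca import PcaModel
from .properties import PropertyTable
from .synthetic import SequenceRecord

LABEL_ALIASES = {
    "hot": +1, "hotspot": +1, "+1": +1, "1": +1, "pos": +1,
    "cold": -1, "coldspot": -1, "-1": -1, "neg": -1,
}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered ``(id, sequence)`` records; duplicate ids or empty records fail."""
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
            seen[rec.id] = seen.get(rec.id, 0) + 1
            records.append((rec.id, seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise FastaError(f"{path}: duplicate record ids: {', '.join(dupes)}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord | tuple[str, str]],
    path: str | Path,
    width: int = 70,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, SequenceRecord):
                header = f">{rec.id} {rec.description}".rstrip()
                seq = rec.sequence
            else:
                rec_id, seq = rec
                header = f">{rec_id}"
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_label(text: str) -> int:
    key = text.strip().lower()
    if key not in LABEL_ALIASES:
        raise FastaError(
            f"unknown label {text!r}; expected one of {sorted(LABEL_ALIASES)}"
        )
    return LABEL_ALIASES[key]


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", header=None, names=["id", "label"],
                        dtype=str, comment="#")
    return {row.id: parse_label(row.label) for row in frame.itertuples()}


def write_labels_tsv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{'hot' if rec.label > 0 else 'cold'}\n")


def load_dataset(
    fasta: str | Path | None = None,
    labels: str | Path | None = None,
    pos_fasta: str | Path | None = None,
    neg_fasta: str | Path | None = None,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Sequences plus +/-1 labels from either input style."""
    if fasta is not None:
        if labels is None:
            raise FastaError("a labels TSV is required with a single FASTA")
        records = read_fasta(fasta)
        label_map = read_labels_tsv(labels)
        missing = [rid for rid, _ in records if rid not in label_map]
        if missing:
            raise FastaError(
                f"no label for record(s): {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
        y = np.array([label_map[rid] for rid, _ in records])
        return records, y
    if pos_fasta is None or neg_fasta is None:
        raise FastaError(
            "provide either --fasta with --labels, or both --pos and --neg"
        )
    pos = read_fasta(pos_fasta)
    neg = read_fasta(neg_fasta)
    overlap = {r for r, _ in pos} & {r for r, _ in neg}
    if overlap:
        raise FastaError(f"ids present in both classes: {sorted(overlap)[:5]}")
    y = np.array([+1] * len(pos) + [-1] * len(neg))
    return pos + neg, y


def write_matrix_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(matrix.values, columns=list(matrix.names))
    frame.insert(0, "id", list(matrix.ids))
    if matrix.labels is not None:
        frame.insert(1, "label", ["hot" if l > 0 else "cold" for l in matrix.labels])
    frame.to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> FeatureMatrix:
    frame = pd.read_csv(path)
    ids = tuple(frame.pop("id").astype(str))
    labels = None
    if "label" in frame.columns:
        labels = np.array([parse_label(l) for l in frame.pop("label")])
    return FeatureMatrix(
        names=tuple(frame.columns),
        values=frame.to_numpy(dtype=float),
        ids=ids,
        labels=labels,
    )


def write_matrix_libsvm(matrix: FeatureMatrix, path: str | Path) -> None:
    from sklearn.datasets import dump_svmlight_file

    y = matrix.labels if matrix.labels is not None else np.zeros(matrix.n_samples)
    dump_svmlight_file(matrix.values, y, str(path), zero_based=False)


def write_report_json(
    result: EvaluationResult, path: str | Path, extra: dict | None = None
) -> None:
    payload = result.to_dict()
    payload["tool_version"] = __version__
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def save_model(
    path: str | Path,
    model,
    encoding: EncodingConfig,
    pca: PcaModel | None = None,
) -> None:
    """Single-file archive of the full prediction chain."""
    joblib.dump(
        {
            "tool_version": __version__,
            "encoding": {
                "lag": encoding.lag,
                "standardize_properties": encoding.table.standardized,
                "property_table": encoding.table.table,
            },
            "pca": pca,
            "model": model,
            "label_convention": {"+1": "hot", "-1": "cold"},
        },
        path,
    )


def load_model(path: str | Path):
    """Returns (TrainedModel, EncodingConfig, PcaModel | None)."""
    payload = joblib.load(path)
    enc = payload["encoding"]
    table = PropertyTable(enc["property_table"],
                          standardized=enc["standardize_properties"])
    config = EncodingConfig(lag=enc["lag"], table=table)
    return payload["model"], config, payload["pca"]
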