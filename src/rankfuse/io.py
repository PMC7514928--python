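"""File formats: rank matrices, sample batches, and consensus reports.

Canonical dialect is TSV (tab-separated, UTF-8, header row); CSV is accepted
on read, chosen by extension and overridable.  A rank-matrix file has the
class label in the first column and one integer column per classifier, the
header carrying the classifier labels.  A batch file is long-format with
columns (sample_id, class, classifier, rank); a labels file has
(sample_id, true_class).

Consensus reports are written as a TSV (class label + one consensus-rank
column per metric) plus a JSON sidecar carrying objectives, scores, optimum
counts, tie-break flags, agreement coefficients, the package version and the
SHA-256 digest of the input — enough to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import ConsensusResult, RankMatrix
from .exceptions import ValidationError
from .pipeline import SampleBatch

__all__ = [
    "read_rank_matrix",
    "write_rank_matrix",
    "read_sample_batch",
    "write_sample_batch",
    "write_consensus_report",
]


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_rank_matrix(path: str | Path, delimiter: str | None = None) -> RankMatrix:
    """Read and validate a rank-matrix file.

    Errors carry row/column coordinates: ragged rows and non-integer cells
    are reported by position, non-permutation columns by classifier label.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = _sep_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    except pd.errors.ParserError as e:
        raise ValidationError(f"{path}: ragged or unparseable table: {e}") from e
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a class-label column plus >= 1 classifier column")
    class_labels = tuple(str(v) for v in df.iloc[:, 0])
    classifier_labels = tuple(str(c) for c in df.columns[1:])
    cells = df.iloc[:, 1:]
    ranks = np.empty(cells.shape, dtype=np.int64)
    for j, col in enumerate(cells.columns):
        for i, raw in enumerate(cells[col]):
            try:
                ranks[i, j] = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-integer cell {raw!r} at row {i + 2}, column {col!r}"
                ) from None
    try:
        return RankMatrix(ranks, class_labels, classifier_labels)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_rank_matrix(R: RankMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write a rank matrix in the canonical dialect; read/write round-trips exactly."""
    path = Path(path)
    sep = _sep_for(path, delimiter)
    df = pd.DataFrame(R.ranks, columns=list(R.classifier_labels))
    df.insert(0, "class", list(R.class_labels))
    df.to_csv(path, sep=sep, index=False)


def read_sample_batch(
    batch_path: str | Path,
    labels_path: str | Path | None = None,
    positive_class: int | None = None,
    delimiter: str | None = None,
) -> SampleBatch:
    """Read a long-format batch file (sample_id, class, classifier, rank) [+ labels]."""
    batch_path = Path(batch_path)
    if not batch_path.exists():
        raise ValidationError(f"no such file: {batch_path}")
    sep = _sep_for(batch_path, delimiter)
    df = pd.read_csv(batch_path, sep=sep)
    required = {"sample_id", "class", "classifier", "rank"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{batch_path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    class_labels = tuple(str(v) for v in pd.unique(df["class"]))
    classifier_labels = tuple(str(v) for v in pd.unique(df["classifier"]))
    sample_ids = list(pd.unique(df["sample_id"]))
    K, M, n = len(class_labels), len(classifier_labels), len(sample_ids)
    cls_idx = {c: i for i, c in enumerate(class_labels)}
    clf_idx = {c: i for i, c in enumerate(classifier_labels)}
    sid_idx = {s: i for i, s in enumerate(sample_ids)}
    tensor = np.zeros((n, K, M), dtype=np.int64)
    seen = np.zeros((n, K, M), dtype=bool)
    for sid, cls, clf, rank in zip(df["sample_id"], df["class"], df["classifier"], df["rank"]):
        s, i, m = sid_idx[sid], cls_idx[str(cls)], clf_idx[str(clf)]
        tensor[s, i, m] = int(rank)
        seen[s, i, m] = True
    if not seen.all():
        s, i, m = (int(v[0]) for v in np.nonzero(~seen))
        raise ValidationError(
            f"{batch_path}: missing rank for sample {sample_ids[s]!r}, "
            f"class {class_labels[i]!r}, classifier {classifier_labels[m]!r}"
        )
    true_labels = None
    if labels_path is not None:
        ldf = pd.read_csv(Path(labels_path), sep=_sep_for(Path(labels_path), delimiter))
        if not {"sample_id", "true_class"}.issubset(ldf.columns):
            raise ValidationError(f"{labels_path}: need columns ['sample_id', 'true_class']")
        lmap = {row.sample_id: str(row.true_class) for row in ldf.itertuples(index=False)}
        missing = [s for s in sample_ids if s not in lmap]
        if missing:
            raise ValidationError(f"{labels_path}: no true class for sample(s) {missing[:5]}")
        true_labels = np.array([cls_idx[lmap[s]] for s in sample_ids], dtype=np.int64)
    return SampleBatch(tensor, true_labels, positive_class, class_labels, classifier_labels)


def write_sample_batch(
    B: SampleBatch, batch_path: str | Path, labels_path: str | Path | None = None
) -> None:
    """Write a batch (and optionally its labels) in long TSV format."""
    rows = []
    for s in range(B.n):
        for i, cls in enumerate(B.class_labels):
            for m, clf in enumerate(B.classifier_labels):
                rows.append((s, cls, clf, int(B.rank_tensor[s, i, m])))
    pd.DataFrame(rows, columns=["sample_id", "class", "classifier", "rank"]).to_csv(
        Path(batch_path), sep="\t", index=False
    )
    if labels_path is not None:
        if B.true_labels is None:
            raise ValidationError("batch has no true labels to write")
        pd.DataFrame(
            {
                "sample_id": np.arange(B.n),
                "true_class": [B.class_labels[i] for i in B.true_labels],
            }
        ).to_csv(Path(labels_path), sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_consensus_report(
    results: Mapping[str, ConsensusResult],
    path: str | Path,
    input_path: str | Path | None = None,
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> Path:
    """Write consensus rankings as TSV plus a JSON sidecar; returns the sidecar path.

    ``results`` maps metric name to its :class:`ConsensusResult`; all results
    must share the same class labels.
    """
    if not results:
        raise ValidationError("no consensus results to write")
    path = Path(path)
    metrics = list(results)
    labels = results[metrics[0]].class_labels
    for m in metrics:
        if results[m].class_labels != labels:
            raise ValidationError("consensus results disagree on class labels")
    df = pd.DataFrame({"class": list(labels)})
    for m in metrics:
        df[f"rank_{m}"] = results[m].ranks
    df.to_csv(path, sep="\t", index=False)

    sidecar = {
        "version": __version__,
        "input_sha256": _sha256(Path(input_path)) if input_path else None,
        "seed": seed,
        "metrics": {
            m: {
                "objective": int(r.objective),
                "score": int(r.score),
                "optimum_count": r.optimum_count,
                "tiebreak_applied": bool(r.tiebreak_applied),
                "ranks": [int(v) for v in r.ranks],
            }
            for m, r in results.items()
        },
        "coefficients": {k: dict(v) for k, v in (coefficients or {}).items()},
    }
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return sidecar_path
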