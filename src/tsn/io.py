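"""Readers and writers for expression matrices, label files, and model files.

Expression matrices are tab-delimited text: first row sample ids, first
column feature ids, numeric body.  Labels are two-column tab-delimited
``sample<TAB>label`` files with exactly two distinct labels.  Fitted
classifiers round-trip through JSON model files that preserve the raw
class histograms, so a reloaded model predicts identically.

Missing or non-numeric values are rejected rather than imputed: within-
sample ranks are undefined under missingness.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import PermutationHistogram, TsnClassifier

FORMAT_VERSION = 1


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited features-x-samples matrix.

    Rejects duplicate feature or sample ids, ragged rows, and non-numeric
    or missing cells, reporting offending identifiers and line numbers
    (1-based, header is line 1).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, engine="python")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from None
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids: {dupes}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        cells = [
            f"feature {frame.index[i]!r}, sample {frame.columns[j]!r} (line {i + 2})"
            for i, j in zip(*np.nonzero(bad.to_numpy()))
        ][:10]
        raise ValueError(f"{path}: non-numeric or missing cells: {'; '.join(cells)}")
    numeric = numeric.astype(float)
    numeric.index.name = None
    return numeric


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature")


def read_labels(path: str | Path, samples=None) -> pd.Series:
    """Read a two-column sample/label file; exactly two distinct labels.

    When ``samples`` is given, every listed sample must be covered.
    """
    path = Path(path)
    table = pd.read_csv(
        path, sep="\t", header=None, names=["sample", "label"], dtype=str,
        comment="#", skip_blank_lines=True,
    )
    # Tolerate an optional header line
    if len(table) and tuple(table.iloc[0]) == ("sample", "label"):
        table = table.iloc[1:]
    if table["label"].isna().any():
        rows = table.index[table["label"].isna()].tolist()
        raise ValueError(f"{path}: rows without a label: lines {[r + 1 for r in rows]}")
    if table["sample"].duplicated().any():
        dupes = table["sample"][table["sample"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicated sample ids: {dupes}")
    labels = pd.Series(
        table["label"].to_numpy(), index=table["sample"].to_numpy(), name="label"
    )
    distinct = labels.unique().tolist()
    if len(distinct) != 2:
        raise ValueError(
            f"{path}: exactly two distinct labels required, found {distinct}"
        )
    if samples is not None:
        missing = [s for s in samples if s not in labels.index]
        if missing:
            raise ValueError(f"{path}: labels missing for samples: {missing[:10]}")
        labels = labels.reindex(list(samples))
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", header=False)


def read_feature_list(path: str | Path) -> list[str]:
    """One feature id per line (an externally computed keep-list)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    feats = [ln for ln in lines if ln and not ln.startswith("#")]
    if not feats:
        raise ValueError(f"{path}: no feature ids found")
    return feats


def save_model(
    model: TsnClassifier, path: str | Path, config_echo: Mapping | None = None
) -> None:
    """Serialise a fitted classifier to JSON (raw counts, losslessly)."""
    from . import __version__

    payload = {
        "format_version": FORMAT_VERSION,
        "tool_version": __version__,
        "n": model.n,
        "features": list(model.features),
        "class_labels": list(model.class_labels),
        "hist1_counts": [int(c) for c in model.hist1.counts],
        "hist2_counts": [int(c) for c in model.hist2.counts],
        "n_samples_class1": model.hist1.n_samples,
        "n_samples_class2": model.hist2.n_samples,
        "delta": model.delta,
        "gamma": model.gamma,
        "config": dict(config_echo) if config_echo else {},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> TsnClassifier:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version")
    n = int(payload["n"])
    if len(payload["hist1_counts"]) != math.factorial(n):
        raise ValueError(f"{path}: histogram length does not match n={n}")
    return TsnClassifier(
        features=tuple(payload["features"]),
        n=n,
        hist1=PermutationHistogram(
            np.array(payload["hist1_counts"], dtype=np.int64),
            int(payload["n_samples_class1"]),
        ),
        hist2=PermutationHistogram(
            np.array(payload["hist2_counts"], dtype=np.int64),
            int(payload["n_samples_class2"]),
        ),
        class_labels=tuple(payload["class_labels"]),
        delta=float(payload["delta"]),
        gamma=int(payload["gamma"]),
    )


def write_predictions(predictions, path: str | Path) -> None:
    """Tab-delimited prediction table (sample_id, predicted_label, resolution_depth)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tpredicted_label\tresolution_depth\n")
        for p in predictions:
            fh.write(f"{p.sample_id}\t{p.label}\t{p.resolution_depth}\n")


def read_predictions(path: str | Path):
    """Read a prediction table written by :func:`write_predictions`."""
    from .classify import Prediction

    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "predicted_label", "resolution_depth"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        Prediction(str(r.sample_id), str(r.predicted_label), int(r.resolution_depth))
        for r in table.itertuples()
    ]


def write_fold_table(report, path: str | Path) -> None:
    """Per-fold cross-validation table: one row per test-fold sample."""
    with open(path, "w") as fh:
        fh.write(
            "repeat\tfold\tchosen_n\tfeatures\tdelta\tgamma\t"
            "sample_id\ttrue_label\tpredicted_label\tresolution_depth\n"
        )
        for rec in report.folds:
            feats = ",".join(rec.features)
            for sample, truth, pred in zip(
                rec.test_samples, rec.true_labels, rec.predictions
            ):
                fh.write(
                    f"{rec.repeat}\t{rec.fold}\t{rec.chosen_n}\t{feats}\t"
                    f"{rec.delta:.10g}\t{rec.gamma}\t{sample}\t{truth}\t"
                    f"{pred.label}\t{pred.resolution_depth}\n"
                )
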