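"""File formats: probability CSVs, label CSVs, weight/report JSON.

One strict dialect: comma-separated UTF-8 with a required header and ``.``
decimals.  Probability files carry ``sample_id,class_0,...,class_{C-1}``;
label files carry ``sample_id,label``.  Alignment across files is always by
``sample_id`` — a mismatch is an error, never a silent reorder.  JSON
artifacts round-trip losslessly and are written atomically (temp file +
rename) with sorted keys so identical runs produce identical bytes.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import PredictionSet, ROW_SUM_TOL, WeightVector
from .errors import ValidationError


def _class_columns(df: pd.DataFrame, path: str) -> list[str]:
    cols = list(df.columns)
    if not cols or cols[0] != "sample_id":
        raise ValidationError(f"{path}: first column must be 'sample_id', got {cols[:1]}")
    expected = [f"class_{i}" for i in range(len(cols) - 1)]
    if cols[1:] != expected:
        raise ValidationError(
            f"{path}: probability columns must be class_0..class_{len(cols) - 2} "
            f"in order, got {cols[1:]}"
        )
    return expected


def _model_id(path: str | Path) -> str:
    return Path(path).stem


def read_predictions(paths: Sequence[str | Path]) -> PredictionSet:
    """Load one probability CSV per model into an aligned PredictionSet.

    Sample order follows the first file; every other file must contain
    exactly the same sample_id set (any order).  Rows whose probabilities
    sum within 1e-6 of 1 are renormalized; anything further off is rejected
    with its row number.
    """
    if not paths:
        raise ValidationError("need at least one predictions CSV")
    matrices = []
    ref_ids: pd.Index | None = None
    class_cols: list[str] | None = None
    for path in paths:
        df = pd.read_csv(path, dtype={"sample_id": str})
        cols = _class_columns(df, str(path))
        if class_cols is None:
            class_cols = cols
        elif cols != class_cols:
            raise ValidationError(
                f"{path}: {len(cols)} classes, expected {len(class_cols)}"
            )
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
            raise ValidationError(f"{path}: duplicated sample_id values {dupes}")
        df = df.set_index("sample_id")
        if ref_ids is None:
            ref_ids = df.index
        else:
            missing = ref_ids.difference(df.index).tolist()
            extra = df.index.difference(ref_ids).tolist()
            if missing or extra:
                raise ValidationError(
                    f"{path}: sample_id mismatch with {paths[0]} "
                    f"(missing {missing[:5]}, unexpected {extra[:5]})"
                )
            df = df.loc[ref_ids]
        values = df[class_cols].to_numpy(dtype=float)
        sums = values.sum(axis=1)
        bad = np.abs(sums - 1.0) > ROW_SUM_TOL
        if bad.any():
            row = int(np.argmax(bad))
            raise ValidationError(
                f"{path}: row {row} (sample_id {df.index[row]!r}) sums to "
                f"{sums[row]:.8f}, outside 1 +/- {ROW_SUM_TOL}"
            )
        matrices.append(values / sums[:, None])
    return PredictionSet(
        tuple(_model_id(p) for p in paths),
        np.stack(matrices),
        tuple(ref_ids),
    )


def read_labels(
    path: str | Path,
    class_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Load a ``sample_id,label`` CSV.

    Labels may be integer class indices, or class names mapped through the
    declared ``class_names`` list (index = position in the list).  Returns
    (labels, sample_ids) in file order.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if list(df.columns) != ["sample_id", "label"]:
        raise ValidationError(f"{path}: columns must be sample_id,label, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise ValidationError(f"{path}: duplicated sample_id values {dupes}")
    raw = df["label"]
    if class_names is not None:
        mapping = {name: i for i, name in enumerate(class_names)}
        unknown = sorted(set(raw.astype(str)) - set(mapping))
        if unknown:
            raise ValidationError(f"{path}: labels {unknown[:5]} not in declared classes {list(class_names)}")
        labels = raw.astype(str).map(mapping).to_numpy()
    else:
        try:
            labels = raw.astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-integer labels require a declared class list"
            ) from exc
    return labels, tuple(df["sample_id"])


def align_labels(
    labels: np.ndarray,
    label_ids: Sequence[str],
    preds: PredictionSet,
) -> np.ndarray:
    """Reorder labels to the PredictionSet's sample order, by sample_id."""
    if preds.sample_ids is None:
        if len(labels) != preds.n_samples:
            raise ValidationError(f"{len(labels)} labels for {preds.n_samples} samples")
        return np.asarray(labels)
    pos = {sid: i for i, sid in enumerate(label_ids)}
    missing = [sid for sid in preds.sample_ids if sid not in pos]
    if missing or len(label_ids) != preds.n_samples:
        extra = sorted(set(label_ids) - set(preds.sample_ids))
        raise ValidationError(
            f"label sample_ids do not match predictions "
            f"(missing {missing[:5]}, unexpected {extra[:5]})"
        )
    order = np.array([pos[sid] for sid in preds.sample_ids])
    return np.asarray(labels)[order]


def _atomic_json(path: str | Path, payload: dict) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def write_weights(
    path: str | Path,
    model_ids: Sequence[str],
    weights: WeightVector,
    loss: float | None = None,
    extra: dict | None = None,
) -> None:
    payload = {"model_ids": list(model_ids), "weights": [float(w) for w in weights.weights]}
    if loss is not None:
        payload["loss"] = float(loss)
    if extra:
        payload.update(extra)
    _atomic_json(path, payload)


def read_weights(path: str | Path) -> tuple[tuple[str, ...], WeightVector, dict]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        model_ids = tuple(payload["model_ids"])
        w = WeightVector(np.asarray(payload["weights"], dtype=float))
    except KeyError as exc:
        raise ValidationError(f"{path}: missing key {exc}") from exc
    meta = {k: v for k, v in payload.items() if k not in ("model_ids", "weights")}
    return model_ids, w, meta


def write_report(path: str | Path, report: dict) -> None:
    _atomic_json(path, report)


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_predictions_csv(
    path: str | Path,
    sample_ids: Sequence[str],
    probs: np.ndarray,
) -> None:
    """Write an (N, C) probability matrix in the package's CSV dialect."""
    probs = np.asarray(probs, dtype=float)
    df = pd.DataFrame(probs, columns=[f"class_{i}" for i in range(probs.shape[1])])
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False)


def write_labels_csv(path: str | Path, sample_ids: Sequence[str], labels: np.ndarray) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": np.asarray(labels)}).to_csv(
        path, index=False
    )
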