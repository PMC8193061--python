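"""Feature-table I/O and model persistence.

Feature tables are plain delimited text (CSV or TSV) with a header row, one
row per sample, reserved columns ``label`` and ``domain`` (``source`` or
``target``) and numeric feature columns — human-inspectable at the
boundary.  Fitted models are stored as a directory archive: a JSON manifest
(format version, config, class names, shapes) plus one ``.npy`` file per
matrix, lossless to 1e-12 and validated on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .dict_core import ClassifierParams, Dictionary
from .graphs import SOURCE, TARGET, LabelVector
from .model import TSMDLConfig, TSMDLModel

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "save_model",
    "load_model",
    "load_gray_image",
]

FORMAT_VERSION = 1
RESERVED_COLUMNS = ("label", "domain")


def read_feature_table(path) -> Tuple[np.ndarray, LabelVector]:
    """Read a delimited feature table into a column-per-sample matrix.

    Sample order is preserved.  The delimiter is inferred from the suffix
    (``.tsv`` is tab, anything else comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if len(set(df.columns)) != len(df.columns):
        raise ValueError("header names must be unique")
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing reserved column {col!r}")
    if df.shape[0] == 0:
        raise ValueError("no samples")
    bad = set(df["domain"].astype(str)) - {SOURCE, TARGET}
    if bad:
        raise ValueError(
            f"invalid domain value(s) {sorted(bad)!r}; expected 'source' or 'target'"
        )
    feat_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    feats = df[feat_cols]
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        row = int(mask.any(axis=1).idxmax())
        col = mask.loc[row].idxmax()
        raise ValueError(
            f"non-numeric feature value at row {row}, column {col!r}: {feats.loc[row, col]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature values must be finite")
    # rows = samples on disk -> columns = samples in memory
    X = values.T
    labels = LabelVector(list(df["label"].astype(str)), list(df["domain"].astype(str)))
    return X, labels


def write_feature_table(path, X: np.ndarray, labels: LabelVector, feature_names: Sequence[str] = None) -> None:
    """Write a column-per-sample matrix plus labels as a delimited table."""
    path = Path(path)
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    if len(labels) != n:
        raise ValueError("label count must match sample count")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(d)]
    df = pd.DataFrame(X.T, columns=list(feature_names))
    df.insert(0, "domain", list(labels.domains))
    df.insert(0, "label", list(labels.labels))
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False)


def save_model(model: TSMDLModel, path) -> None:
    """Persist a fitted model as a directory archive (manifest + matrices)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    matrices = {}
    for l, D in enumerate(model.dicts):
        matrices[f"D{l}"] = D.atoms
    for l, T in enumerate(model.thetas):
        matrices[f"Theta{l}"] = T
    matrices["w"] = model.classifier.weights
    matrices["b"] = model.classifier.biases
    manifest = {
        "format_version": FORMAT_VERSION,
        "config": model.config.to_dict(),
        "classes": [str(c) for c in model.classifier.classes],
        "svm_cost": model.classifier.cost,
        "clf_weight": model.classifier.clf_weight,
        "training_log": [float(v) for v in model.training_log],
        "matrices": {k: list(v.shape) for k, v in matrices.items()},
    }
    for name, mat in matrices.items():
        np.save(path / f"{name}.npy", np.asarray(mat, dtype=float))
    # manifest written last so a crash mid-save never yields a loadable archive
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> TSMDLModel:
    """Load a model archive; any inconsistency raises without a partial model."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt manifest: {e}") from e
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} (expected {FORMAT_VERSION})"
        )
    matrices = {}
    for name, shape in manifest["matrices"].items():
        f = path / f"{name}.npy"
        if not f.exists():
            raise ValueError(f"archive missing matrix file {name}.npy")
        try:
            mat = np.load(f)
        except Exception as e:
            raise ValueError(f"corrupt matrix file {name}.npy: {e}") from e
        if list(mat.shape) != list(shape):
            raise ValueError(
                f"shape mismatch for {name}: manifest says {shape}, file has {list(mat.shape)}"
            )
        matrices[name] = mat
    cfg = TSMDLConfig.from_dict(manifest["config"])
    L = cfg.n_layers
    dicts = [Dictionary(atoms=matrices[f"D{l}"], layer_index=l) for l in range(L)]
    thetas = [matrices[f"Theta{l}"] for l in range(L)]
    clf = ClassifierParams(
        weights=matrices["w"],
        biases=matrices["b"],
        classes=tuple(manifest["classes"]),
        cost=float(manifest.get("svm_cost", 1.0)),
        clf_weight=float(manifest.get("clf_weight", 0.0)),
    )
    return TSMDLModel(
        dicts=dicts,
        thetas=thetas,
        classifier=clf,
        config=cfg,
        training_log=list(manifest.get("training_log", [])),
    )


def load_gray_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a nonnegative grayscale float array.

    Multichannel images are converted by the standard luminance weights.
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(Path(path)), dtype=float)
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[:, :, :3]
        img = img @ np.array([0.2126, 0.7152, 0.0722])
    if img.ndim != 2:
        raise ValueError(f"cannot interpret {path} as a grayscale image")
    return img
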