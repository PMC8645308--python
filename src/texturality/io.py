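"""Raster, ratings and table input/output.

Column names and orders written here are part of the public contract:

* feature CSV: ``image_id`` then the 34 canonical labels; a ``.json``
  sidecar records configuration and label order
* ratings CSV (input): ``image_id, observer_id, task, response`` with
  ``task`` in {texturality, similarity} and ``response`` in {0, 1}; an
  aggregated dialect with ``proportion`` (and optional ``n_trials``)
  columns is also accepted
* correlation CSV: ``feature, correlation``
* prediction CSV: ``image_id, label, decision_value``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ImageReadError, RatingsFormatError, SizeError
from .summary_features import SummaryFeatureVector

__all__ = [
    "read_image",
    "write_image",
    "read_ratings",
    "write_feature_table",
    "read_feature_table",
]

#: Rec.709 luma weights for RGB -> luminance
_LUMA = np.array([0.2126, 0.7152, 0.0722])

TASKS = ("texturality", "similarity")


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def read_image(path, expected_size: int | None = None, linearize: bool = False):
    """Read a PNG/TIFF/JPEG as a luminance map in [0, 1].

    8- and 16-bit gray and RGB(A) inputs are supported; RGB converts to
    luminance with Rec.709 weights.  ``linearize`` applies the sRGB-to-linear
    transfer before the luminance weighting (for photographs; calibrated
    stimuli are assumed linear already).
    """
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc

    if mode in ("L", "P"):
        lum = arr.astype(float) / 255.0
    elif mode in ("I;16", "I"):
        lum = arr.astype(float) / 65535.0
    elif mode == "F":
        lum = arr.astype(float)
    elif mode in ("RGB", "RGBA"):
        rgb = arr[..., :3].astype(float) / 255.0
        if linearize:
            rgb = _srgb_to_linear(rgb)
        lum = rgb @ _LUMA
    else:
        raise ImageReadError(f"unsupported image mode {mode!r} in {path}")

    if lum.ndim != 2 or lum.shape[0] != lum.shape[1]:
        raise SizeError(f"{path}: image must be square, got shape {lum.shape}")
    if expected_size is not None and lum.shape[0] != expected_size:
        raise SizeError(
            f"{path}: expected side {expected_size}, got {lum.shape[0]}"
        )
    return np.clip(lum, 0.0, 1.0)


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] luminance map as a 16-bit grayscale PNG."""
    arr = np.round(np.clip(np.asarray(image, dtype=float), 0.0, 1.0) * 65535.0)
    Image.fromarray(arr.astype(np.uint16)).save(path)


def read_ratings(path, min_trials: int = 4) -> pd.DataFrame:
    """Aggregate a ratings CSV into per-image, per-task response proportions.

    Returns a frame with columns ``image_id, task, proportion, n_trials,
    low_count``; ``low_count`` flags images with fewer than ``min_trials``
    pooled responses.  Duplicate trial rows are deliberately kept as distinct
    trials.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise RatingsFormatError(f"cannot read ratings {path}: {exc}") from exc
    if df.empty:
        import warnings

        warnings.warn(f"ratings file {path} is empty", stacklevel=2)
        return pd.DataFrame(
            columns=["image_id", "task", "proportion", "n_trials", "low_count"]
        )

    if "proportion" in df.columns:
        required = {"image_id", "task", "proportion"}
        missing = required - set(df.columns)
        if missing:
            raise RatingsFormatError(f"{path}: missing columns {sorted(missing)}")
        bad = df[(df["proportion"] < 0) | (df["proportion"] > 1)]
        if len(bad):
            lines = (bad.index + 2).tolist()
            raise RatingsFormatError(
                f"{path}: proportion outside [0, 1] at lines {lines}"
            )
        out = df[["image_id", "task", "proportion"]].copy()
        out["n_trials"] = (
            df["n_trials"].astype(int) if "n_trials" in df.columns else min_trials
        )
    else:
        required = {"image_id", "observer_id", "task", "response"}
        missing = required - set(df.columns)
        if missing:
            raise RatingsFormatError(f"{path}: missing columns {sorted(missing)}")
        bad = df[~df["response"].isin([0, 1])]
        if len(bad):
            lines = (bad.index + 2).tolist()
            raise RatingsFormatError(
                f"{path}: response must be 0 or 1 at lines {lines}"
            )
        grouped = df.groupby(["image_id", "task"], sort=True)["response"]
        out = grouped.agg(proportion="mean", n_trials="count").reset_index()

    bad_task = out[~out["task"].isin(TASKS)]
    if len(bad_task):
        raise RatingsFormatError(
            f"{path}: unknown task values {sorted(bad_task['task'].unique())}; "
            f"expected one of {list(TASKS)}"
        )
    out["low_count"] = out["n_trials"] < min_trials
    return out


def write_feature_table(
    path,
    image_ids: Sequence,
    vectors: Sequence[SummaryFeatureVector],
    config: dict | None = None,
) -> None:
    """Write one row per image: ``image_id`` then the canonical labels.

    A sidecar ``<path>.json`` records the label order and any config given.
    """
    if not vectors:
        raise RatingsFormatError("no feature vectors to write")
    labels = vectors[0].labels
    for v in vectors:
        if v.labels != labels:
            raise RatingsFormatError("feature vectors have inconsistent labels")
    df = pd.DataFrame([v.values for v in vectors], columns=list(labels))
    df.insert(0, "image_id", list(image_ids))
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {"labels": list(labels), "config": config or {}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path):
    """Read a feature CSV back into ``(image_ids, X, feature_labels)``."""
    df = pd.read_csv(path)
    if "image_id" not in df.columns:
        raise RatingsFormatError(f"{path}: missing image_id column")
    labels = tuple(c for c in df.columns if c != "image_id")
    return list(df["image_id"]), df[list(labels)].to_numpy(dtype=float), labels
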