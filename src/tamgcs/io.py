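"""Format readers/writers shared by the library and the CLI.

Labeled datasets round-trip through CSV (columns ``f1..fN,label``) and
NPZ; reports are JSON; images are 8/16-bit grayscale PNG or NPZ; volumes
are NIfTI (via nibabel) or NPZ.  Numeric outputs always go to NPZ/JSON;
PNG export is min-max scaled for visualization only.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .gcs import LabeledDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_report",
    "write_report",
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
]


def read_dataset(path: str | Path) -> LabeledDataset:
    """Load a labeled point set from ``.csv`` (``f1..fN,label``) or ``.npz``."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing required 'label' column (found {list(df.columns)})")
        features = [c for c in df.columns if c != "label"]
        if not features:
            raise ValueError(f"{path}: no feature columns")
        return LabeledDataset(points=df[features].to_numpy(dtype=float), labels=df["label"].to_numpy())
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            if "points" not in z or "labels" not in z:
                raise ValueError(f"{path}: NPZ must contain 'points' and 'labels' arrays")
            return LabeledDataset(points=z["points"], labels=z["labels"])
    raise ValueError(f"unsupported dataset extension {path.suffix!r} (expected .csv or .npz)")


def write_dataset(data: LabeledDataset, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        cols = {f"f{i + 1}": data.points[:, i] for i in range(data.n_features)}
        cols["label"] = data.labels
        pd.DataFrame(cols).to_csv(path, index=False)
    elif path.suffix == ".npz":
        np.savez(path, points=data.points, labels=data.labels)
    else:
        raise ValueError(f"unsupported dataset extension {path.suffix!r}")


def write_report(report, path: str | Path) -> None:
    """Serialize a report (dataclass with ``to_dict`` or plain dict) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG (8/16-bit) or an NPZ with an ``image`` array."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            if "image" not in z:
                raise ValueError(f"{path}: NPZ must contain an 'image' array")
            return np.asarray(z["image"], dtype=float)
    img = Image.open(path)
    if img.mode in ("I;16", "I"):
        return np.asarray(img, dtype=float)
    if img.mode == "L":
        return np.asarray(img, dtype=float)
    raise ValueError(f"{path}: only grayscale images are supported, got mode {img.mode!r}")


def write_image(arr: np.ndarray, path: str | Path) -> None:
    """NPZ keeps exact values; PNG is min-max scaled to 8-bit for viewing."""
    path = Path(path)
    arr = np.asarray(arr, dtype=float)
    if path.suffix == ".npz":
        np.savez(path, image=arr)
        return
    if path.suffix == ".png":
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 255.0
        Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)
        return
    raise ValueError(f"unsupported image extension {path.suffix!r}")


def read_volume(path: str | Path) -> np.ndarray:
    """Read a 3-D volume from NIfTI (.nii/.nii.gz) or NPZ (``volume`` array)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            if "volume" not in z:
                raise ValueError(f"{path}: NPZ must contain a 'volume' array")
            vol = np.asarray(z["volume"], dtype=float)
    elif path.name.endswith((".nii", ".nii.gz")):
        vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    else:
        raise ValueError(f"unsupported volume extension for {path.name!r}")
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {vol.shape}")
    return vol


def write_volume(vol: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    vol = np.asarray(vol, dtype=float)
    if path.suffix == ".npz":
        np.savez(path, volume=vol)
    elif path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported volume extension for {path.name!r}")
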