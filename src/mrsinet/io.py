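"""Dataset containers, checkpoints and provenance.

Datasets are stored one HDF5 file per split (``train.h5``,
``validation.h5``, ``test.h5``) with datasets ``fids`` and ``targets``
(N x n_points x 2 float32), optional ``labels`` (int8), ``ppm_axis``
(float64) and a JSON ``provenance`` attribute carrying seeds, config
hash and schema version.  An NPZ fallback uses identical keys.
Checkpoints are NPZ archives of a model state dict plus a JSON header.
"""

from __future__ import annotations

import hashlib
import json
import os
import zipfile
from typing import Dict, Optional, Tuple

import h5py
import numpy as np

from .errors import DataIntegrityError, SchemaError
from .records import DatasetSplit, N_POINTS_DEFAULT, SplitArrays

SCHEMA_VERSION = 1
SPLIT_NAMES = ("train", "validation", "test")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_json(split: SplitArrays, extra: Optional[Dict]) -> str:
    from . import __version__
    prov = dict(split.provenance)
    prov.update(extra or {})
    prov.setdefault("schema_version", SCHEMA_VERSION)
    prov.setdefault("software_version", __version__)
    return json.dumps(prov, sort_keys=True, default=str)


def _write_split_h5(split: SplitArrays, path: str, extra: Optional[Dict]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=split.fids.astype(np.float32))
        f.create_dataset("targets", data=split.targets.astype(np.float32))
        f.create_dataset("ppm_axis", data=split.ppm_axis.astype(np.float64))
        if split.labels is not None:
            f.create_dataset("labels", data=split.labels.astype(np.int8))
        f.attrs["provenance"] = _provenance_json(split, extra)


def _write_split_npz(split: SplitArrays, path: str, extra: Optional[Dict]) -> None:
    arrays = {"fids": split.fids.astype(np.float32),
              "targets": split.targets.astype(np.float32),
              "ppm_axis": split.ppm_axis.astype(np.float64),
              "provenance": np.array(_provenance_json(split, extra))}
    if split.labels is not None:
        arrays["labels"] = split.labels.astype(np.int8)
    np.savez(path, **arrays)


def write_dataset(dataset: DatasetSplit, out_dir: str,
                  fmt: str = "hdf5", extra_provenance: Optional[Dict] = None
                  ) -> Dict[str, str]:
    """Write all three splits; returns the mapping split -> file path."""
    os.makedirs(out_dir, exist_ok=True)
    ext = {"hdf5": "h5", "npz": "npz"}.get(fmt)
    if ext is None:
        raise SchemaError(f"unknown dataset format {fmt!r}")
    paths = {}
    for name, split in dataset.splits().items():
        path = os.path.join(out_dir, f"{name}.{ext}")
        if fmt == "hdf5":
            _write_split_h5(split, path, extra_provenance)
        else:
            _write_split_npz(split, path, extra_provenance)
        paths[name] = path
    return paths


def _validate_split(name: str, fids, targets, ppm_axis, labels,
                    provenance: Dict) -> SplitArrays:
    if provenance.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"{name}: unsupported schema version "
            f"{provenance.get('schema_version')!r}")
    for label, arr, nd in (("fids", fids, 3), ("targets", targets, 3)):
        if arr.ndim != nd or arr.shape[1] != N_POINTS_DEFAULT or arr.shape[2] != 2:
            raise SchemaError(
                f"{name}: {label} has shape {arr.shape}, expected "
                f"(N, {N_POINTS_DEFAULT}, 2)")
        if not np.all(np.isfinite(arr)):
            raise DataIntegrityError(f"{name}: {label} contains non-finite values")
    if len(fids) != len(targets):
        raise SchemaError(f"{name}: fids/targets length mismatch")
    if labels is not None and len(labels) != len(fids):
        raise SchemaError(f"{name}: labels length mismatch")
    if len(ppm_axis) != N_POINTS_DEFAULT:
        raise SchemaError(f"{name}: ppm_axis length {len(ppm_axis)}")
    return SplitArrays(fids=fids, targets=targets, ppm_axis=ppm_axis,
                       labels=labels, provenance=provenance)


def _read_split(path: str) -> SplitArrays:
    name = os.path.basename(path)
    try:
        if path.endswith(".h5"):
            with h5py.File(path, "r") as f:
                fids = f["fids"][...]
                targets = f["targets"][...]
                ppm_axis = f["ppm_axis"][...]
                labels = f["labels"][...] if "labels" in f else None
                provenance = json.loads(f.attrs.get("provenance", "{}"))
        else:
            with np.load(path) as z:
                fids = z["fids"]
                targets = z["targets"]
                ppm_axis = z["ppm_axis"]
                labels = z["labels"] if "labels" in z.files else None
                provenance = json.loads(str(z["provenance"]))
    except (OSError, KeyError, json.JSONDecodeError,
            zipfile.BadZipFile) as exc:
        raise DataIntegrityError(f"{name}: unreadable or truncated ({exc})")
    return _validate_split(name, fids, targets, ppm_axis, labels, provenance)


def read_dataset(path: str) -> DatasetSplit:
    """Read a dataset directory (or a single split file) back.

    Validates shapes, finiteness and schema version before returning.
    """
    if os.path.isfile(path):
        split = _read_split(path)
        empty = SplitArrays(fids=split.fids[:0], targets=split.targets[:0],
                            ppm_axis=split.ppm_axis, provenance=split.provenance)
        return DatasetSplit(train=split, validation=empty, test=empty)
    splits = {}
    for name in SPLIT_NAMES:
        for ext in ("h5", "npz"):
            candidate = os.path.join(path, f"{name}.{ext}")
            if os.path.exists(candidate):
                splits[name] = _read_split(candidate)
                break
        else:
            raise SchemaError(f"missing split file {name}.h5/.npz in {path}")
    prov = splits["train"].provenance
    return DatasetSplit(train=splits["train"], validation=splits["validation"],
                        test=splits["test"],
                        split_fractions=tuple(prov.get("split_fractions",
                                                       (0.8, 0.1, 0.1))),
                        master_seed=int(prov.get("master_seed", 0)))


def save_checkpoint(state: Dict[str, np.ndarray], path: str,
                    header: Optional[Dict] = None) -> None:
    """Save a model state dict plus a JSON header to an NPZ archive."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    from . import __version__
    meta = dict(header or {})
    meta.setdefault("software_version", __version__)
    arrays = {f"param::{k}": v for k, v in state.items()}
    arrays["header"] = np.array(json.dumps(meta, sort_keys=True, default=str))
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> Tuple[Dict[str, np.ndarray], Dict]:
    """Load (state dict, header) from an NPZ checkpoint."""
    try:
        with np.load(path) as z:
            header = json.loads(str(z["header"]))
            state = {k[len("param::"):]: z[k] for k in z.files
                     if k.startswith("param::")}
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise DataIntegrityError(f"unreadable checkpoint {path}: {exc}")
    return state, header
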