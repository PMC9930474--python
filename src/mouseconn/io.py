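"""File formats: wide TSV time series with JSON censoring sidecars, square
CSV matrices, long-form CSV measure tables, NIfTI-1 label volumes, BrainNet
``.node``/``.edge`` text exports, YAML configuration, and checksum
manifests. All round-trips reproduce values to 1e-12 and metadata exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    ConnectivityMatrix,
    RoiTimeSeries,
    ValidationError,
    WeightedGraph,
    validate_measure_table,
)

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_matrix", "read_matrix",
    "write_measure_table", "read_measure_table",
    "write_atlas_nifti", "read_atlas_nifti",
    "write_brainnet", "read_edge_file",
    "load_yaml", "sha256_file", "write_manifest",
]


# ------------------------------------------------------------- time series

def write_timeseries(series: RoiTimeSeries, path: str | Path) -> Path:
    """Wide TSV (first column node name, then t0..tN-1) + JSON sidecar."""
    path = Path(path)
    cols = [f"t{k}" for k in range(series.n_timepoints)]
    frame = pd.DataFrame(series.data, columns=cols)
    frame.insert(0, "node", series.node_names)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "subject_id": series.subject_id,
        "group": series.group,
        "session": series.session,
        "sample_interval": series.sample_interval,
        "censored_frames": sorted(series.censored_frames),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - message context only
        raise ValidationError(f"cannot parse time-series TSV {path}: {exc}")
    if frame.columns[0] != "node":
        raise ValidationError(f"{path}: first column must be 'node'")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {"subject_id": path.stem, "group": "placebo", "session": "chronic",
            "sample_interval": 1.0, "censored_frames": []}
    if sidecar_path.exists():
        meta.update(json.loads(sidecar_path.read_text()))
    return RoiTimeSeries(
        subject_id=meta["subject_id"], group=meta["group"],
        session=meta["session"], node_names=frame["node"].tolist(),
        data=frame.iloc[:, 1:].to_numpy(dtype=float),
        sample_interval=meta["sample_interval"],
        censored_frames=set(meta["censored_frames"]))


def timeseries_filename(series: RoiTimeSeries) -> str:
    return f"{series.subject_id}_{series.session}.tsv"


# ---------------------------------------------------------------- matrices

def write_matrix(matrix: np.ndarray, node_names: list[str],
                 path: str | Path) -> Path:
    """Square CSV with a header row and leading column of node names."""
    path = Path(path)
    frame = pd.DataFrame(matrix, index=node_names, columns=node_names)
    frame.to_csv(path, float_format="%.17g")
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValidationError(f"{path}: row and column names differ")
    return frame.to_numpy(dtype=float), list(frame.index)


def write_connectivity(cm: ConnectivityMatrix, stem: str | Path) -> list[Path]:
    stem = Path(stem)
    out = [write_matrix(cm.r, cm.node_names, stem.with_suffix(".r.csv")),
           write_matrix(cm.z, cm.node_names, stem.with_suffix(".z.csv"))]
    if cm.sig_mask is not None:
        out.append(write_matrix(cm.sig_mask.astype(int), cm.node_names,
                                stem.with_suffix(".sig.csv")))
    return out


# ----------------------------------------------------------- measure table

def write_measure_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_measure_table(table)
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_measure_table(path: str | Path) -> pd.DataFrame:
    return validate_measure_table(pd.read_csv(path))


# ------------------------------------------------------------------- NIfTI

def write_atlas_nifti(image: np.ndarray,
                      voxel_dims: tuple[float, float, float],
                      path: str | Path,
                      name_table: pd.DataFrame | None = None) -> Path:
    """Integer label volume as NIfTI-1 with a diagonal mm affine; the ROI
    name table is written alongside as TSV."""
    path = Path(path)
    affine = np.diag([*voxel_dims, 1.0])
    img = nib.Nifti1Image(np.asarray(image, dtype=np.int32), affine)
    img.header.set_zooms(voxel_dims)
    nib.save(img, str(path))
    if name_table is not None:
        name_table.to_csv(path.with_suffix(".labels.tsv"), sep="\t",
                          index=False)
    return path


def read_atlas_nifti(path: str | Path) -> tuple[
        np.ndarray, tuple[float, float, float], pd.DataFrame | None]:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels_path = path.with_suffix(".labels.tsv")
    names = pd.read_csv(labels_path, sep="\t") if labels_path.exists() else None
    return data, dims, names


# ---------------------------------------------------------------- BrainNet

def write_brainnet(g: WeightedGraph, stem: str | Path,
                   coords: np.ndarray | None = None,
                   color: np.ndarray | None = None,
                   size: np.ndarray | None = None) -> tuple[Path, Path]:
    """BrainNet-compatible ``.node`` (x y z color size label) and ``.edge``
    (square matrix) text files.

    Coordinates default to a deterministic layout on a unit-spaced grid in
    atlas-corner millimeter convention; ``size`` typically carries a scaled
    node metric (e.g., strength AUC).
    """
    stem = Path(stem)
    n = g.n_nodes
    if coords is None:
        side = int(np.ceil(np.cbrt(n)))
        idx = np.arange(n)
        coords = np.column_stack([idx % side, (idx // side) % side,
                                  idx // (side * side)]).astype(float)
    color = np.ones(n) if color is None else np.asarray(color, dtype=float)
    size = np.ones(n) if size is None else np.asarray(size, dtype=float)
    node_path = stem.with_suffix(".node")
    with node_path.open("w") as fh:
        for k in range(n):
            x, y, z = coords[k]
            fh.write(f"{x:.6g}\t{y:.6g}\t{z:.6g}\t{color[k]:.6g}\t"
                     f"{size[k]:.6g}\t{g.node_names[k]}\n")
    edge_path = stem.with_suffix(".edge")
    np.savetxt(edge_path, g.weights, fmt="%.17g", delimiter="\t")
    return node_path, edge_path


def read_edge_file(path: str | Path) -> np.ndarray:
    mat = np.loadtxt(path)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"{path}: .edge file must be a square matrix")
    return mat


# ------------------------------------------------------------------ config

def load_yaml(path: str | Path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: YAML config must be a mapping")
    return data


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: list[Path], out: str | Path, seed: int,
                   complete: bool = True, extra: dict | None = None) -> Path:
    """JSON manifest of every output file with content checksums."""
    out = Path(out)
    entries = [{"path": str(p.relative_to(out.parent)) if p.is_relative_to(
        out.parent) else str(p), "sha256": sha256_file(p)} for p in paths]
    manifest = {"seed": seed, "complete": complete,
                "files": sorted(entries, key=lambda e: e["path"])}
    if extra:
        manifest.update(extra)
    out.write_text(json.dumps(manifest, indent=1))
    return out
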