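"""File codecs: per-subject time series (TSV or 4-D NIfTI), participants,
network definitions, rating curves, maps and configs.

TSV dialect throughout: tab-separated, header row, UTF-8, '.' decimal.
Subject time-series TSVs carry metadata in leading ``#`` comment lines.
NIfTI subjects are stored as 4-D images with the units arranged on a 3-D
grid in RAS orientation (row-major unit order, documented affine); the TR
is carried in the header zooms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datasets import BehavioralTable, NetworkDefinition, RatingCurve, SubjectTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_dataset_dir",
    "write_map",
    "read_participants",
    "write_participants",
    "read_networks",
    "write_networks",
    "read_rating",
    "write_rating",
    "read_config",
]

#: default voxel size (mm) of the synthetic NIfTI grid
_VOX_MM = 3.0


def _grid_shape(n_units: int) -> tuple[int, int, int]:
    """Smallest cubic-ish RAS grid holding n_units (row-major order)."""
    nx = int(np.ceil(n_units ** (1 / 3)))
    ny = int(np.ceil(np.sqrt(n_units / nx)))
    nz = int(np.ceil(n_units / (nx * ny)))
    return nx, ny, nz


def write_timeseries(path: str | Path, subject: SubjectTimeSeries,
                     affine: np.ndarray | None = None) -> Path:
    """Write one subject to TSV (``.tsv``) or NIfTI (``.nii``/``.nii.gz``)."""
    path = Path(path)
    if path.suffix == ".tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# subject_id={subject.subject_id}\n")
            fh.write(f"# group={subject.group}\n")
            fh.write(f"# tr_seconds={subject.tr_seconds!r}\n")
            pd.DataFrame(
                subject.data,
                columns=[f"tr{t}" for t in range(subject.n_tr)],
            ).to_csv(fh, sep="\t", index=False, float_format="%.10g")
        return path
    if path.name.endswith((".nii", ".nii.gz")):
        nx, ny, nz = _grid_shape(subject.n_units)
        vol = np.zeros((nx, ny, nz, subject.n_tr), dtype=np.float64)
        flat = vol.reshape(-1, subject.n_tr)
        flat[: subject.n_units] = subject.data
        if affine is None:
            affine = np.diag([_VOX_MM, _VOX_MM, _VOX_MM, 1.0])
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms(
            tuple(np.abs(np.diag(affine))[:3]) + (subject.tr_seconds,)
        )
        img.header["descrip"] = (
            f"id={subject.subject_id};group={subject.group};"
            f"units={subject.n_units}".encode()[:79]
        )
        nib.save(img, str(path))
        return path
    raise ValueError(f"unsupported time-series format: {path.name}")


def read_timeseries(
    path: str | Path,
    subject_id: str | None = None,
    group: str | None = None,
    n_units: int | None = None,
) -> SubjectTimeSeries:
    """Read a subject time series written by :func:`write_timeseries`.

    For NIfTI, ``subject_id``/``group``/``n_units`` override (or supply, if
    the header's descrip field is absent) the embedded metadata.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        meta: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        return SubjectTimeSeries(
            subject_id=subject_id or meta.get("subject_id", path.stem),
            group=group or meta.get("group", "unknown"),
            data=df.to_numpy(dtype=float),
            tr_seconds=float(meta.get("tr_seconds", 3.0)),
        )
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise ValueError(f"{path.name}: expected a 4-D image")
        desc = img.header["descrip"].item().decode(errors="ignore")
        meta = dict(
            kv.split("=", 1) for kv in desc.split(";") if "=" in kv
        )
        nu = n_units if n_units is not None else int(meta.get("units", 0)) or None
        flat = vol.reshape(-1, vol.shape[-1])
        data = flat[:nu] if nu else flat
        zooms = img.header.get_zooms()
        return SubjectTimeSeries(
            subject_id=subject_id or meta.get("id", path.name.split(".")[0]),
            group=group or meta.get("group", "unknown"),
            data=data,
            tr_seconds=float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 3.0,
        )
    raise ValueError(f"unsupported time-series format: {path.name}")


def read_dataset_dir(
    data_dir: str | Path, participants: BehavioralTable | None = None
) -> list[SubjectTimeSeries]:
    """Read every subject file in a directory (sorted by filename).

    When a participants table is given, group labels are taken from it and
    files are matched to rows by subject id.
    """
    data_dir = Path(data_dir)
    files = sorted(
        p
        for p in data_dir.iterdir()
        if p.suffix == ".tsv" or p.name.endswith((".nii", ".nii.gz"))
    )
    if not files:
        raise FileNotFoundError(f"no time-series files in {data_dir}")
    group_of = {}
    if participants is not None:
        group_of = dict(
            zip(participants.table["subject_id"], participants.table["group"])
        )
    subjects = []
    for p in files:
        s = read_timeseries(p)
        if s.subject_id in group_of:
            s.group = group_of[s.subject_id]
        subjects.append(s)
    return subjects


def write_map(path: str | Path, values: np.ndarray,
              affine: np.ndarray | None = None,
              n_units: int | None = None) -> Path:
    """Write a per-unit map (e.g. an ISC map) as TSV or 3-D NIfTI."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if path.suffix == ".tsv":
        pd.DataFrame({"unit": np.arange(values.size), "value": values}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        return path
    if path.name.endswith((".nii", ".nii.gz")):
        n = n_units or values.size
        nx, ny, nz = _grid_shape(n)
        vol = np.full(nx * ny * nz, np.nan)
        vol[: values.size] = values
        if affine is None:
            affine = np.diag([_VOX_MM, _VOX_MM, _VOX_MM, 1.0])
        nib.save(nib.Nifti1Image(vol.reshape(nx, ny, nz), affine), str(path))
        return path
    raise ValueError(f"unsupported map format: {path.name}")


def write_participants(path: str | Path, behavior: BehavioralTable) -> Path:
    path = Path(path)
    behavior.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_participants(path: str | Path) -> BehavioralTable:
    return BehavioralTable(pd.read_csv(path, sep="\t"))


def write_networks(path: str | Path, networks: Sequence[NetworkDefinition],
                   pool: np.ndarray | None = None) -> Path:
    """Write the network-definition table.

    Columns: node_label, x, y, z, network, unit_index. Pool nodes (the
    whole-brain node pool for specificity nulls) carry network = 'pool'.
    """
    rows = []
    for net in networks:
        for k, idx in enumerate(net.indices):
            label = net.labels[k] if net.labels else f"{net.name}_{k}"
            xyz = net.coords[k] if net.coords is not None else (np.nan,) * 3
            rows.append((label, *xyz, net.name, int(idx)))
    if pool is not None:
        for idx in pool:
            rows.append((f"pool_{idx}", np.nan, np.nan, np.nan, "pool", int(idx)))
    pd.DataFrame(
        rows, columns=["node_label", "x", "y", "z", "network", "unit_index"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def read_networks(
    path: str | Path,
) -> tuple[dict[str, NetworkDefinition], np.ndarray]:
    """Read the network table; returns ({name: NetworkDefinition}, pool).

    If the ``unit_index`` column is absent, row order defines unit indices.
    """
    df = pd.read_csv(path, sep="\t")
    if "unit_index" not in df.columns:
        df["unit_index"] = np.arange(len(df))
    nets: dict[str, NetworkDefinition] = {}
    pool = df.loc[df["network"] == "pool", "unit_index"].to_numpy(int)
    for name, sub in df[df["network"] != "pool"].groupby("network", sort=False):
        nets[name] = NetworkDefinition(
            name=name,
            indices=sub["unit_index"].to_numpy(int),
            labels=sub["node_label"].tolist(),
            coords=sub[["x", "y", "z"]].to_numpy(float),
        )
    return nets, pool


def write_rating(path: str | Path, rating: RatingCurve) -> Path:
    pd.DataFrame(
        {
            "tr_index": np.arange(rating.n_tr),
            "median": rating.median,
            "mad": rating.mad,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def read_rating(path: str | Path, scale_max: float = 6.0) -> RatingCurve:
    df = pd.read_csv(path, sep="\t")
    return RatingCurve(
        median=df["median"].to_numpy(float),
        mad=df["mad"].to_numpy(float),
        scale_max=scale_max,
    )


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON run/simulation configuration into a dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format: {path.name}")
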