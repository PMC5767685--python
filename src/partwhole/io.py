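"""Serialization of datasets and result tables.

Pattern datasets travel as one wide CSV (a row per subject/run/ROI/condition,
voxels as columns) plus a JSON provenance snapshot.  Time-series and volume
datasets use a compressed ``.npz`` with a JSON sidecar for designs and labels.
A minimal NIfTI export (voxels along x, time along the 4th axis) is offered
for interoperability with neuroimaging viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DesignSpec
from .datasets import PatternDataset, TimeSeriesDataset, VolumePatternSet


def save_patterns(ds: PatternDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.to_frame().to_csv(outdir / "patterns.csv", index=False)
    meta = {
        "roi_names": list(ds.roi_names),
        "n_subjects": ds.n_subjects,
        "n_runs": ds.n_runs,
        "provenance": ds.provenance,
    }
    (outdir / "patterns.json").write_text(json.dumps(meta, indent=2, default=str))
    return outdir


def load_patterns(indir: str | Path) -> PatternDataset:
    indir = Path(indir)
    df = pd.read_csv(indir / "patterns.csv")
    meta = json.loads((indir / "patterns.json").read_text())
    ds = PatternDataset.from_frame(df, provenance=meta.get("provenance", {}))
    ds.roi_names = tuple(meta["roi_names"])
    ds.n_subjects = meta["n_subjects"]
    ds.n_runs = meta["n_runs"]
    return ds


def _key_str(key: tuple) -> str:
    return "|".join(str(k) for k in key)


def save_timeseries(ts: TimeSeriesDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {f"vol::{_key_str(k)}": v for k, v in ts.volumes.items()}
    arrays.update({f"nuis::{_key_str(k)}": v for k, v in ts.nuisance.items()})
    np.savez_compressed(outdir / "timeseries.npz", **arrays)
    meta = {
        "roi_names": list(ts.roi_names),
        "n_subjects": ts.n_subjects,
        "n_runs": ts.n_runs,
        "provenance": ts.provenance,
        "designs": {_key_str(k): d.to_dict() for k, d in ts.designs.items()},
    }
    (outdir / "timeseries.json").write_text(json.dumps(meta, indent=2, default=str))
    return outdir


def load_timeseries(indir: str | Path) -> TimeSeriesDataset:
    indir = Path(indir)
    meta = json.loads((indir / "timeseries.json").read_text())
    with np.load(indir / "timeseries.npz") as npz:
        volumes, nuisance = {}, {}
        for name in npz.files:
            kind, key = name.split("::", 1)
            parts = key.split("|")
            if kind == "vol":
                volumes[(int(parts[0]), int(parts[1]), parts[2])] = npz[name]
            else:
                nuisance[(int(parts[0]), int(parts[1]))] = npz[name]
    designs = {
        (int(k.split("|")[0]), int(k.split("|")[1])): DesignSpec.from_dict(d)
        for k, d in meta["designs"].items()
    }
    return TimeSeriesDataset(
        volumes=volumes,
        nuisance=nuisance,
        designs=designs,
        roi_names=tuple(meta["roi_names"]),
        n_subjects=meta["n_subjects"],
        n_runs=meta["n_runs"],
        provenance=meta.get("provenance", {}),
    )


def save_volume_set(vols: VolumePatternSet, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {f"vol::{_key_str(k)}": v for k, v in vols.volumes.items()}
    np.savez_compressed(outdir / "volumes.npz", **arrays)
    meta = {
        "roi_names": list(vols.roi_names),
        "n_subjects": vols.n_subjects,
        "n_runs": vols.n_runs,
        "provenance": vols.provenance,
    }
    (outdir / "volumes.json").write_text(json.dumps(meta, indent=2, default=str))
    return outdir


def load_volume_set(indir: str | Path) -> VolumePatternSet:
    indir = Path(indir)
    meta = json.loads((indir / "volumes.json").read_text())
    with np.load(indir / "volumes.npz") as npz:
        volumes = {}
        for name in npz.files:
            _, key = name.split("::", 1)
            s, r, roi, bt, emo = key.split("|")
            volumes[(int(s), int(r), roi, bt, emo)] = npz[name]
    return VolumePatternSet(
        volumes=volumes,
        roi_names=tuple(meta["roi_names"]),
        n_subjects=meta["n_subjects"],
        n_runs=meta["n_runs"],
        provenance=meta.get("provenance", {}),
    )


def export_run_nifti(
    ts: TimeSeriesDataset, subject: int, run: int, roi: str, path: str | Path
) -> Path:
    """Write one run's (time × voxel) matrix as a 4D NIfTI (V, 1, 1, T) with a
    JSON sidecar carrying the design and condition order."""
    import nibabel as nib

    path = Path(path)
    mat = ts.get(subject, run, roi)  # (T, V)
    img = nib.Nifti1Image(mat.T[:, None, None, :].astype(np.float32), affine=np.eye(4))
    img.header["pixdim"][4] = ts.designs[(subject, run)].tr_s
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "subject": subject,
                "run": run,
                "roi": roi,
                "design": ts.designs[(subject, run)].to_dict(),
            },
            indent=2,
        )
    )
    return path
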