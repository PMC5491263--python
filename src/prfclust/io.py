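"""File formats: array containers with JSON sidecars, CSV tables, NIfTI runs.

Conventions: apertures, sheets and coverage maps are stored as ``.npz``
array containers next to a ``.json`` sidecar holding geometry and run
metadata; per-site tables are CSV; 4D volumes are NIfTI (the optional
real-data path).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .dataset import Run, SheetDataset
from .fitting import PRFFit
from .map_metrics import CoverageMap
from .prf_model import PRFParams
from .stimulus import ApertureSequence, FieldSpec


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_apertures(seq: ApertureSequence, path: str | Path) -> None:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(
        path, masks=seq.masks, bar_centers_deg=seq.bar_centers_deg
    )
    meta = {
        "field": asdict(seq.field),
        "step_size_deg": seq.step_size_deg,
        "bar_width_deg": seq.bar_width_deg,
        "sweep_direction": seq.sweep_direction,
        "tr_s": seq.tr_s,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_apertures(path: str | Path) -> ApertureSequence:
    path = Path(path).with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return ApertureSequence(
        masks=arrays["masks"],
        field=FieldSpec(**meta["field"]),
        step_size_deg=meta["step_size_deg"],
        bar_width_deg=meta["bar_width_deg"],
        sweep_direction=meta["sweep_direction"],
        tr_s=meta["tr_s"],
        bar_centers_deg=arrays["bar_centers_deg"],
    )


def save_sheet_dataset(ds: SheetDataset, path: str | Path) -> None:
    path = Path(path).with_suffix(".npz")
    arrays = {"coords_mm": ds.coords_mm, "site_ids": ds.site_ids}
    for i, r in enumerate(ds.runs):
        arrays[f"run{i}"] = r.series
    np.savez_compressed(path, **arrays)
    meta = {
        "tr_s": ds.tr_s,
        "hemisphere": ds.hemisphere,
        "runs": [
            {"width_deg": r.width_deg, "run_id": r.run_id} for r in ds.runs
        ],
        "ground_truth": None
        if ds.ground_truth is None
        else [asdict(p) for p in ds.ground_truth],
        "region_labels": None
        if ds.region_labels is None
        else [str(x) for x in ds.region_labels],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_sheet_dataset(path: str | Path) -> SheetDataset:
    path = Path(path).with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    runs = tuple(
        Run(width_deg=m["width_deg"], series=arrays[f"run{i}"], run_id=m["run_id"])
        for i, m in enumerate(meta["runs"])
    )
    gt = meta["ground_truth"]
    labels = meta.get("region_labels")
    return SheetDataset(
        coords_mm=arrays["coords_mm"],
        runs=runs,
        tr_s=meta["tr_s"],
        hemisphere=meta["hemisphere"],
        site_ids=arrays["site_ids"],
        ground_truth=None if gt is None else tuple(PRFParams(**p) for p in gt),
        region_labels=None if labels is None else np.array(labels, dtype=object),
    )


def fits_to_frame(fits: Sequence[PRFFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        p = f.params
        rows.append(
            {
                "site_id": f.site_id,
                "x0": p.x0,
                "y0": p.y0,
                "sigma": p.sigma,
                "n": p.n,
                "beta": p.beta,
                "eccentricity": p.eccentricity,
                "effective_size": f.effective_size_deg,
                "ve": f.variance_explained,
                "retained": f.retained,
                "fit_stage": f.fit_stage,
            }
        )
    return pd.DataFrame(rows)


def save_coverage_map(cov: CoverageMap, path: str | Path) -> None:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, density=cov.density)
    meta = {"field": asdict(cov.field), "roi": cov.roi, "n_sites": cov.n_sites}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_coverage_map(path: str | Path) -> CoverageMap:
    path = Path(path).with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return CoverageMap(
        density=arrays["density"],
        field=FieldSpec(**meta["field"]),
        roi=meta["roi"],
        n_sites=meta["n_sites"],
    )


# ---------------------------------------------------------------------------
# NIfTI (optional real-data path)
# ---------------------------------------------------------------------------

def write_nifti_runs(
    ds: SheetDataset, directory: str | Path, prefix: str = "run"
) -> dict:
    """Write each run as a 4D NIfTI volume (sites laid out along the first
    axis) plus a JSON run manifest; returns the manifest dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"tr_s": ds.tr_s, "hemisphere": ds.hemisphere, "runs": []}
    affine = np.eye(4)
    for i, r in enumerate(ds.runs):
        vol = r.series.reshape(ds.n_sites, 1, 1, -1).astype(np.float64)
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((1.0, 1.0, 1.0, ds.tr_s))
        fname = f"{prefix}{i:02d}.nii"
        nib.save(img, directory / fname)
        manifest["runs"].append(
            {"file": fname, "width_deg": r.width_deg, "run_id": r.run_id}
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_nifti_runs(
    directory: str | Path,
    manifest: dict | None = None,
    mask: np.ndarray | None = None,
) -> SheetDataset:
    """Extract voxel time series from 4D NIfTI runs listed in a manifest.

    ``mask`` is a boolean 3D array selecting voxels (all nonzero-variance
    handling is left to the fitter); sheet coordinates come from the voxel
    grid of the first two axes, scaled by the voxel size.  Runs must agree
    on TR with the manifest.
    """
    directory = Path(directory)
    if manifest is None:
        manifest = json.loads((directory / "manifest.json").read_text())
    tr = float(manifest["tr_s"])
    runs = []
    coords = None
    for entry in manifest["runs"]:
        if "width_deg" not in entry:
            raise ValueError(f"run manifest entry missing a bar width label: {entry}")
        img = nib.load(directory / entry["file"])
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0 and abs(zooms[3] - tr) > 1e-6:
            raise ValueError(
                f"TR mismatch: manifest says {tr}s, {entry['file']} says {zooms[3]}s"
            )
        m = np.ones(data.shape[:3], dtype=bool) if mask is None else mask.astype(bool)
        if not m.any():
            raise ValueError("mask excludes every voxel")
        series = data[m]  # (n_voxels, T)
        if coords is None:
            idx = np.array(np.nonzero(m)).T
            coords = idx[:, :2] * np.array(zooms[:2])
        runs.append(
            Run(width_deg=entry["width_deg"], series=series, run_id=entry.get("run_id", entry["file"]))
        )
    return SheetDataset(
        coords_mm=coords,
        runs=tuple(runs),
        tr_s=tr,
        hemisphere=manifest.get("hemisphere", "left"),
    )
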