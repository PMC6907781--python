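"""On-disk formats: CSI bundles (HDF5), maps and masks (NIfTI), cohort
tables (CSV), reports (JSON).

Schemas:

* CSI HDF5: datasets ``/kspace_real`` and ``/kspace_imag`` (N x N x T
  float64), every acquisition parameter as a root attribute, session
  metadata (``animal_id``, ``timepoint``, ``seed``), optional ``/truth``
  group holding the phantom label map and per-metabolite amplitudes.
* Metabolite maps: one single-slice NIfTI per metabolite with the
  interpolated in-plane resolution in the affine, plus a JSON sidecar
  carrying provenance (applied line broadening, zero-fill, flags).
* Cohort CSV columns: id, group, pre/post Lac/Bic for tumor and normal
  ROIs, tumor Lac/Pyr pre/post, volumes, survival_day, event.

Every loader validates against its schema and raises
:class:`~hpflux.exceptions.SchemaError` naming the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .phantom import AcqParams, AnimalRecord, CsiDataset
from .quantify import RoiMask
from .recon import MetaboliteMapSet

__all__ = [
    "save_csi",
    "load_csi",
    "save_maps",
    "load_maps",
    "save_mask",
    "load_mask",
    "cohort_to_csv",
    "cohort_from_csv",
    "save_report",
    "load_report",
]

_ACQ_FIELDS = (
    "matrix", "tr_ms", "flip_deg", "bw_hz", "n_samples",
    "fov_mm", "slice_mm", "carrier_ppm", "f0_mhz",
)

COHORT_COLUMNS = [
    "id", "group",
    "pre_lacbic_tumor", "post_lacbic_tumor",
    "pre_lacbic_normal", "post_lacbic_normal",
    "pre_lacpyr_tumor", "post_lacpyr_tumor",
    "vol_pre_mm3", "vol_post_mm3",
    "survival_day", "event",
]


def save_csi(ds: CsiDataset, path) -> None:
    """Write a CSI dataset to HDF5 (kspace split into real/imag)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace_real", data=ds.kspace.real)
        f.create_dataset("kspace_imag", data=ds.kspace.imag)
        for name in _ACQ_FIELDS:
            f.attrs[name] = getattr(ds.params, name)
        f.attrs["animal_id"] = ds.animal_id
        f.attrs["timepoint"] = ds.timepoint
        f.attrs["seed"] = ds.seed
        if ds.truth is not None:
            g = f.create_group("truth")
            g.create_dataset("labels", data=ds.truth.labels)
            for met, amp in ds.truth.amplitudes.items():
                g.create_dataset(f"amplitude_{met}", data=amp)
            g.create_dataset("phases_rad", data=ds.truth.phases_rad)


def load_csi(path) -> CsiDataset:
    """Read a CSI dataset, validating the HDF5 schema."""
    with h5py.File(path, "r") as f:
        for name in ("kspace_real", "kspace_imag"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset /{name}")
        for name in _ACQ_FIELDS:
            if name not in f.attrs:
                raise SchemaError(f"{path}: missing attribute '{name}'")
        k = np.asarray(f["kspace_real"]) + 1j * np.asarray(f["kspace_imag"])
        params = AcqParams(
            matrix=int(f.attrs["matrix"]),
            tr_ms=float(f.attrs["tr_ms"]),
            flip_deg=float(f.attrs["flip_deg"]),
            bw_hz=float(f.attrs["bw_hz"]),
            n_samples=int(f.attrs["n_samples"]),
            fov_mm=float(f.attrs["fov_mm"]),
            slice_mm=float(f.attrs["slice_mm"]),
            carrier_ppm=float(f.attrs["carrier_ppm"]),
            f0_mhz=float(f.attrs["f0_mhz"]),
        )
        return CsiDataset(
            kspace=k,
            params=params,
            animal_id=str(f.attrs.get("animal_id", "unknown")),
            timepoint=str(f.attrs.get("timepoint", "baseline")),
            seed=int(f.attrs.get("seed", 0)),
        )


def _map_affine(res_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([res_mm, res_mm, slice_mm, 1.0])


def save_maps(
    maps: MetaboliteMapSet, out_dir, res_mm: float = 1.0, slice_mm: float = 5.0
) -> dict[str, Path]:
    """Write one NIfTI per metabolite plus a provenance JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, m in maps.maps.items():
        img = nib.Nifti1Image(
            m[:, :, None].astype(np.float64), _map_affine(res_mm, slice_mm)
        )
        p = out_dir / f"map_{name}.nii.gz"
        nib.save(img, p)
        paths[name] = p
    sidecar = out_dir / "maps.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {"interp_factor": maps.interp_factor, "provenance": maps.provenance},
            fh, indent=2, sort_keys=True,
        )
    paths["sidecar"] = sidecar
    return paths


def load_maps(out_dir) -> MetaboliteMapSet:
    out_dir = Path(out_dir)
    sidecar = out_dir / "maps.json"
    if not sidecar.exists():
        raise SchemaError(f"{out_dir}: missing maps.json sidecar")
    with open(sidecar) as fh:
        meta = json.load(fh)
    maps = {}
    for p in sorted(out_dir.glob("map_*.nii.gz")):
        name = p.name[len("map_"):-len(".nii.gz")]
        maps[name] = np.asarray(nib.load(p).dataobj)[:, :, 0]
    if not maps:
        raise SchemaError(f"{out_dir}: no map_*.nii.gz files")
    return MetaboliteMapSet(
        maps=maps,
        interp_factor=int(meta["interp_factor"]),
        provenance=meta["provenance"],
    )


def save_mask(mask: RoiMask, path, res_mm: float = 1.0, slice_mm: float = 5.0) -> None:
    img = nib.Nifti1Image(
        mask.mask[:, :, None].astype(np.uint8), _map_affine(res_mm, slice_mm)
    )
    nib.save(img, path)


def load_mask(path, label: str = "tumor") -> RoiMask:
    data = np.asarray(nib.load(path).dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if not np.isin(np.unique(data), [0, 1]).all():
        raise SchemaError(f"{path}: mask voxels must be 0 or 1")
    return RoiMask(mask=data.astype(bool), label=label)


def cohort_to_csv(records: Sequence[AnimalRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records])[COHORT_COLUMNS]
    df.to_csv(path, index=False)  # full repr precision: round-trips exactly


def cohort_from_csv(path) -> list[AnimalRecord]:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        if row["event"] not in (0, 1):
            raise SchemaError(f"{path}: row {i} column 'event' must be 0 or 1")
        if row["group"] not in ("deceased", "survivor", "control"):
            raise SchemaError(f"{path}: row {i} column 'group' invalid: {row['group']}")
        records.append(
            AnimalRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                pre_lacbic_tumor=float(row["pre_lacbic_tumor"]),
                post_lacbic_tumor=float(row["post_lacbic_tumor"]),
                pre_lacbic_normal=float(row["pre_lacbic_normal"]),
                post_lacbic_normal=float(row["post_lacbic_normal"]),
                pre_lacpyr_tumor=float(row["pre_lacpyr_tumor"]),
                post_lacpyr_tumor=float(row["post_lacpyr_tumor"]),
                vol_pre_mm3=float(row["vol_pre_mm3"]),
                vol_post_mm3=float(row["vol_post_mm3"]),
                survival_day=int(row["survival_day"]),
                event=int(row["event"]),
            )
        )
    return records


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
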