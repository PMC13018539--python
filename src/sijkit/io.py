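"""Readers and writers: volumes (NPZ, NIfTI, optionally DICOM series),
contour annotation JSON, label tables, model checkpoints and YAML run
configuration.  All writes are atomic (temp file + rename) and annotation
JSON is canonical (sorted keys) so re-writes are byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import ClassifierConfig, SIJClassifier
from .contour import Polyline
from .delineation import DelineatorConfig, UNet, build_baseline, build_delineator

log = logging.getLogger("sijkit")


# ---------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------


def atomic_write_bytes(path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as f:
            f.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


# ---------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------


@dataclass
class VolumeBundle:
    """A scan volume as (slices, H, W) with in-plane spacing in mm/px."""

    data: np.ndarray
    spacing: float = 1.0
    sequence: str = "other"  # T1 | STIR | other
    patient_id: str = ""
    scan_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be (slices, H, W)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def read_volume(path) -> VolumeBundle:
    """Read NPZ (keys: data, spacing, sequence, patient_id, scan_id) or
    NIfTI (slice axis last in the file, returned slice-first).  A missing
    spacing defaults to 1.0 mm/px with a logged warning."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            if "data" not in z:
                raise ValueError(f"{path}: NPZ volume must contain a 'data' array")
            data = z["data"]
            if "spacing" in z:
                spacing = float(z["spacing"])
            else:
                log.warning("%s: no pixel spacing; defaulting to 1.0 mm/px", path)
                spacing = 1.0
            meta = {
                k: str(z[k]) for k in ("sequence", "patient_id", "scan_id") if k in z
            }
        return VolumeBundle(data, spacing, **meta)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI volume")
        data = np.moveaxis(arr, 2, 0)  # (X, Y, Z) -> slice-first (Z, X, Y)
        zooms = img.header.get_zooms()[:2]
        spacing = float(np.mean(zooms)) if all(z > 0 for z in zooms) else 1.0
        return VolumeBundle(data, spacing)
    raise ValueError(f"unsupported volume format: {path}")


def read_dicom_series(directory) -> VolumeBundle:
    """Read a directory of single-frame DICOM files as one volume (sorted
    by InstanceNumber); requires pydicom."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    dsets = sorted(
        (pydicom.dcmread(str(f)) for f in files),
        key=lambda d: int(getattr(d, "InstanceNumber", 0)),
    )
    data = np.stack([d.pixel_array.astype(float) for d in dsets])
    ps = getattr(dsets[0], "PixelSpacing", None)
    spacing = float(np.mean([float(v) for v in ps])) if ps else 1.0
    return VolumeBundle(data, spacing)


def write_volume(path, bundle: VolumeBundle) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        path.parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".npz")
        os.close(fd)
        try:
            np.savez(
                tmp,
                data=bundle.data,
                spacing=bundle.spacing,
                sequence=bundle.sequence,
                patient_id=bundle.patient_id,
                scan_id=bundle.scan_id,
            )
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([bundle.spacing, bundle.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.moveaxis(bundle.data, 0, 2), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path}")


# ---------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------

_SIDES = ("left", "right")


def _check_vertices(v, where: str, for_annotation: bool = True):
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
        raise ValueError(f"{where}: vertices must be a finite Nx2 [x, y] list")
    if for_annotation and not (2 <= arr.shape[0] <= 21):
        raise ValueError(
            f"{where}: annotation vertex count {arr.shape[0]} outside [2, 21]"
        )
    return arr


def contours_to_records(
    per_slice: list[dict], spacing: float = 1.0, validate_counts: bool = False
) -> dict:
    slices = []
    for cdict in per_slice:
        rec = {}
        for side_name in _SIDES:
            poly = cdict.get(side_name)
            if poly is None or not poly.present or len(poly) == 0:
                rec[side_name] = None
            else:
                v = _check_vertices(poly.vertices, side_name, validate_counts)
                rec[side_name] = [[float(x), float(y)] for x, y in v]
        slices.append(rec)
    return {"spacing_mm": float(spacing), "slices": slices}


def records_to_contours(record: dict, validate_counts: bool = True):
    if "slices" not in record:
        raise ValueError("annotation record: missing field 'slices'")
    spacing = float(record.get("spacing_mm", 1.0))
    out = []
    for i, rec in enumerate(record["slices"]):
        cdict = {}
        for side_name in _SIDES:
            v = rec.get(side_name)
            if v is None:
                cdict[side_name] = Polyline.absent(side_name)
            else:
                arr = _check_vertices(v, f"slice {i}/{side_name}", validate_counts)
                cdict[side_name] = Polyline(arr, side=side_name)
        out.append(cdict)
    return out, spacing


def write_annotations(path, record: dict) -> None:
    """Canonical JSON (sorted keys, fixed separators) for diffability."""
    atomic_write_text(path, json.dumps(record, sort_keys=True, indent=1) + "\n")


def read_annotations(path) -> dict:
    with open(path) as f:
        return json.load(f)


# ---------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------


@dataclass
class RunConfig:
    """Stage configurations plus the single root seed of an invocation."""

    seed: int = 0
    profile: str = "desk"  # desk | full
    delineator: dict = field(default_factory=dict)
    walker: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    lam: float = 1.0
    threshold: float = 0.5

    def delineator_config(self) -> DelineatorConfig:
        base = (
            DelineatorConfig.desk(seed=self.seed)
            if self.profile == "desk"
            else DelineatorConfig(seed=self.seed)
        )
        return dataclasses.replace(base, **self.delineator)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            **{"seed": self.seed, "lam": self.lam, "threshold": self.threshold,
               **self.classifier}
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        return cls(**data)


def load_run_config(path) -> RunConfig:
    with open(path) as f:
        return RunConfig.from_yaml(f.read())


# ---------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------


def save_model(path, model) -> None:
    """Checkpoint a delineator/baseline/classifier with its config."""
    if isinstance(model, UNet):
        kind = "baseline" if model.config.out_planes != 8 else "delineator"
        meta = dataclasses.asdict(model.config)
    elif isinstance(model, SIJClassifier):
        kind = "classifier"
        meta = dataclasses.asdict(model.config)
        meta["_n_readers"] = model.trees[model.task_ids[0]].n_readers
        meta["_n_sessions"] = model.trees[model.task_ids[0]].n_sessions
    else:
        raise ValueError(f"cannot checkpoint {type(model).__name__}")
    state = model.state_dict()
    arrays = {f"p{i}": a for i, a in enumerate(state)}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".npz")
    os.close(fd)
    try:
        np.savez(tmp, kind=kind, meta=json.dumps(meta), n=len(state), **arrays)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_model(path):
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        meta = json.loads(str(z["meta"]))
        state = [z[f"p{i}"] for i in range(int(z["n"]))]
    if kind == "classifier":
        n_readers = meta.pop("_n_readers", 2)
        n_sessions = meta.pop("_n_sessions", 3)
        model = SIJClassifier(
            ClassifierConfig(**meta), n_readers=n_readers, n_sessions=n_sessions
        )
    else:
        cfg = DelineatorConfig(**{**meta, "out_planes": 8})
        if kind == "baseline":
            model = build_baseline(cfg, n_landmarks=meta["out_planes"] // 2)
        else:
            model = build_delineator(cfg)
    model.load_state_dict(state)
    return model
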