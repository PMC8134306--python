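"""Standard-format I/O: NIfTI volumes, JSON electrode cases, run configs.

A labeled volume is stored as two NIfTI files sharing one voxel->world
affine: ``<prefix>.t1.nii.gz`` (float intensity in [0, 1]) and
``<prefix>.cwd.nii.gz`` (integer tissue codes).  Electrode cases use a
small JSON schema (``seegbend-cases-v1``) in which every trajectory
record carries ``case_id``, ``electrode_id``, ``kind``, ``space`` and a
``points`` list in world mm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import AffineTransform, Trajectory
from .phantom import (
    BendingModel, CaseSet, ElectrodeCase, LabeledVolume, PhantomCase,
    PhantomConfig,
)

__all__ = [
    "read_volume", "write_volume", "read_cases", "write_cases",
    "trajectories_to_csv", "RunConfig", "write_dataset", "read_dataset",
]

CASES_SCHEMA = "seegbend-cases-v1"
SPACES = ("patient", "common")


class FormatError(ValueError):
    """Malformed file or schema violation."""


# ---------------------------------------------------------------------------
# volumes


def write_volume(volume: LabeledVolume, prefix) -> tuple:
    """Write intensity + tissue NIfTIs; returns the two paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = volume.affine.matrix
    t1_path = prefix.with_suffix(".t1.nii.gz")
    cwd_path = prefix.with_suffix(".cwd.nii.gz")
    nib.save(nib.Nifti1Image(np.asarray(volume.intensity, dtype=np.float32),
                             aff), t1_path)
    nib.save(nib.Nifti1Image(np.asarray(volume.tissue, dtype=np.int16), aff),
             cwd_path)
    return t1_path, cwd_path


def read_volume(prefix, check_normalized: bool = True,
                tolerance: float = 1e-3) -> LabeledVolume:
    """Read a labeled volume written by :func:`write_volume`."""
    prefix = Path(prefix)
    t1_path = prefix.with_suffix(".t1.nii.gz")
    cwd_path = prefix.with_suffix(".cwd.nii.gz")
    try:
        t1 = nib.load(t1_path)
        cwd = nib.load(cwd_path)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI pair at {prefix}: {exc}") from exc
    intensity = np.asarray(t1.dataobj, dtype=np.float32)
    tissue = np.asarray(cwd.dataobj, dtype=np.int8)
    if check_normalized and (
        intensity.min() < -tolerance or intensity.max() > 1 + tolerance
    ):
        raise FormatError(
            f"intensity volume declared normalized but spans "
            f"[{intensity.min():.3f}, {intensity.max():.3f}]"
        )
    if not np.all(np.isin(np.unique(tissue), [0, 1, 2, 3])):
        raise FormatError("tissue volume contains codes outside {0, 1, 2, 3}")
    if not np.allclose(t1.affine, cwd.affine, atol=1e-6):
        raise FormatError("intensity and tissue affines disagree")
    affine = AffineTransform(np.asarray(t1.affine, dtype=float))
    voxel_size = float(np.cbrt(abs(np.linalg.det(affine.linear))))
    return LabeledVolume(intensity=intensity, tissue=tissue, affine=affine,
                         voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# cases


def _traj_record(case_id, electrode_id, traj: Trajectory, space: str) -> dict:
    return {
        "case_id": case_id,
        "electrode_id": electrode_id,
        "kind": traj.kind,
        "space": space,
        "points": traj.points.tolist(),
    }


def _traj_from_record(rec: dict) -> Trajectory:
    for key in ("case_id", "electrode_id", "kind", "space", "points"):
        if key not in rec:
            raise FormatError(f"trajectory record missing field {key!r}")
    if rec["space"] not in SPACES:
        raise FormatError(f"space must be one of {SPACES}, got {rec['space']!r}")
    return Trajectory(np.asarray(rec["points"], dtype=float), kind=rec["kind"])


def write_cases(caseset: CaseSet, path, space: str = "common") -> None:
    """Serialize all electrode records (trajectories + metadata) to JSON."""
    doc = {"schema": CASES_SCHEMA, "seed": caseset.seed, "cases": []}
    for case in caseset.cases:
        cd = {"case_id": case.case_id, "seed": case.seed, "electrodes": []}
        for e in case.electrodes:
            cd["electrodes"].append({
                "electrode_id": e.electrode_id,
                "group": e.group,
                "stylet": e.stylet,
                "entry_lobe": e.entry_lobe,
                "target_region": e.target_region,
                "rigid": _traj_record(e.case_id, e.electrode_id, e.rigid, space),
                "implanted": _traj_record(e.case_id, e.electrode_id,
                                          e.implanted, space),
            })
        doc["cases"].append(cd)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_cases(path) -> CaseSet:
    """Parse a cases JSON file; raises :class:`FormatError` naming the field.

    Volumes are not stored in the JSON; the returned cases carry
    ``volume=None`` until paired with their NIfTIs (see
    :func:`read_dataset`).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != CASES_SCHEMA:
        raise FormatError(
            f"unexpected schema {doc.get('schema')!r}; expected {CASES_SCHEMA!r}"
        )
    if "cases" not in doc:
        raise FormatError("document missing field 'cases'")
    cases = []
    for cd in doc["cases"]:
        if "case_id" not in cd:
            raise FormatError("case record missing field 'case_id'")
        electrodes = []
        for ed in cd.get("electrodes", []):
            for key in ("electrode_id", "group", "rigid", "implanted"):
                if key not in ed:
                    raise FormatError(
                        f"electrode record in {cd['case_id']} missing "
                        f"field {key!r}"
                    )
            electrodes.append(ElectrodeCase(
                case_id=cd["case_id"],
                electrode_id=ed["electrode_id"],
                rigid=_traj_from_record(ed["rigid"]),
                implanted=_traj_from_record(ed["implanted"]),
                group=ed["group"],
                stylet=ed.get("stylet", "no-information"),
                entry_lobe=ed.get("entry_lobe", "frontal"),
                target_region=ed.get("target_region", "frontal"),
            ))
        cases.append(PhantomCase(case_id=cd["case_id"], volume=None,
                                 electrodes=electrodes,
                                 seed=cd.get("seed", 0)))
    return CaseSet(cases=cases, seed=doc.get("seed", 0))


def trajectories_to_csv(caseset: CaseSet, path) -> None:
    """Flat CSV export: case_id, electrode_id, kind, index, x, y, z."""
    rows = []
    for case, e in caseset.iter_electrodes():
        for kind, traj in (("rigid", e.rigid), ("implanted", e.implanted)):
            for idx, (x, y, z) in enumerate(traj.points):
                rows.append({"case_id": case.case_id,
                             "electrode_id": e.electrode_id, "kind": kind,
                             "index": idx, "x": x, "y": y, "z": z})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# whole datasets (volumes + cases + manifest)


def write_dataset(caseset: CaseSet, out_dir) -> None:
    """Write volumes, the cases JSON, and a manifest into a run directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": caseset.seed, "cases": []}
    for case in caseset.cases:
        write_volume(case.volume, out_dir / case.case_id)
        manifest["cases"].append({
            "case_id": case.case_id,
            "seed": case.seed,
            "groups": sorted({e.group for e in case.electrodes}),
            "n_electrodes": len(case.electrodes),
        })
    write_cases(caseset, out_dir / "cases.json")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_dataset(in_dir) -> CaseSet:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    caseset = read_cases(in_dir / "cases.json")
    for case in caseset.cases:
        case.volume = read_volume(in_dir / case.case_id)
    return caseset


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All pipeline tunables with their protocol defaults.

    Unknown keys in a config file are rejected; the resolved config is
    logged by every CLI command.
    """

    spacing_mm: float = 1.0
    window_size: int = 9
    dropout_p: float = 0.1
    mc_passes: int = 200
    lr: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 200
    validate_every: int = 5
    batch_size: int = 64
    seed: int = 0
    n_folds: int = 10
    holdout_frac: float = 0.10
    n_cases: int = 10
    electrodes_per_case: int = 10
    conv_channels: int = 8
    phantom: dict = field(default_factory=dict)
    bending: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.spacing_mm <= 0 or self.lr <= 0 or self.epochs < 1:
            raise ValueError("rates and counts must be positive")
        if self.window_size % 2 != 1:
            raise ValueError("window_size must be odd")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError("config file must contain a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise FormatError(
                f"unknown config keys: {sorted(unknown)}; valid keys: "
                f"{sorted(valid)}"
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(**self.phantom) if self.phantom else PhantomConfig()

    def bending_model(self) -> BendingModel:
        return BendingModel(**self.bending) if self.bending else BendingModel()
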