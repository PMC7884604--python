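"""File formats: NIfTI-1 volumes, motion traces, phenotype and feature tables.

Conventions
-----------
* Volumetric data (4D runs, 3D masks, stat maps) are NIfTI-1 via nibabel.
* Motion traces are whitespace-delimited text, one row per volume, six
  columns: three translations (mm) then three rotations (rad).
* Phenotypes travel as TSV with the column set documented in
  ``PHENOTYPE_COLUMNS``; lean records leave obese-only cells empty.
* Censor flags are a single 0/1 text column (1 = retained).
* Configs are YAML or JSON mappings.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityFeature
from .synthetic import ParticipantRecord

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_motion",
    "write_motion",
    "read_censor_flags",
    "write_censor_flags",
    "read_phenotypes",
    "write_phenotypes",
    "read_features",
    "write_features",
    "load_config_file",
    "write_summary_json",
]

PHENOTYPE_COLUMNS = [
    "participant", "group", "height_m",
    "weight_T0_kg", "weight_T8_kg",
    "leptin_T0_ngml", "leptin_T8_ngml",
    "body_fat_T0_kg", "body_fat_T8_kg",
    "insulin_T0_mUl", "insulin_T8_mUl",
    "excluded", "exclusion_reason",
]


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    np.savetxt(path, motion, fmt="%.10g")
    return Path(path)


def read_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns of motion parameters")
    return motion


def write_censor_flags(retained: np.ndarray, path: str | Path) -> Path:
    np.savetxt(path, np.asarray(retained, dtype=int), fmt="%d")
    return Path(path)


def read_censor_flags(path: str | Path) -> np.ndarray:
    return np.loadtxt(path).astype(bool)


def write_phenotypes(records: Sequence[ParticipantRecord],
                     path: str | Path) -> Path:
    """Phenotype table as TSV; planted ground truth is not serialized."""
    rows = []
    for rec in records:
        rows.append({
            "participant": rec.id, "group": rec.group, "height_m": rec.height_m,
            "weight_T0_kg": rec.weight_T0_kg, "weight_T8_kg": rec.weight_T8_kg,
            "leptin_T0_ngml": rec.leptin_T0, "leptin_T8_ngml": rec.leptin_T8,
            "body_fat_T0_kg": rec.body_fat_T0_kg,
            "body_fat_T8_kg": rec.body_fat_T8_kg,
            "insulin_T0_mUl": rec.insulin_T0, "insulin_T8_mUl": rec.insulin_T8,
            "excluded": rec.excluded,
            "exclusion_reason": rec.exclusion_reason or "",
        })
    df = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return Path(path)


def read_phenotypes(path: str | Path) -> list[ParticipantRecord]:
    """Read and validate a phenotype TSV into participant records.

    Unknown columns raise; malformed numeric cells raise with the row
    and column named; a lean record carrying T8 leptin is retained with
    a warning (documented leniency for shared-assay tables).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(PHENOTYPE_COLUMNS)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if unknown or missing:
        raise ValueError(f"{path}: unknown columns {sorted(unknown)}, "
                         f"missing columns {sorted(missing)}")
    numeric = [c for c in PHENOTYPE_COLUMNS
               if c not in ("participant", "group", "excluded", "exclusion_reason")]
    records = []
    for row_idx, row in df.iterrows():
        values = {}
        for col in numeric:
            cell = row[col].strip()
            if cell == "":
                values[col] = None
                continue
            try:
                values[col] = float(cell)
            except ValueError:
                raise ValueError(f"{path}: malformed numeric cell at row "
                                 f"{row_idx + 2}, column {col!r}: {cell!r}") from None
        if row["group"] == "lean" and values["leptin_T8_ngml"] is not None:
            warnings.warn(f"lean participant {row['participant']} carries T8 "
                          "leptin; value retained")
        records.append(ParticipantRecord(
            id=row["participant"], group=row["group"],
            height_m=values["height_m"],
            weight_T0_kg=values["weight_T0_kg"],
            weight_T8_kg=values["weight_T8_kg"],
            leptin_T0=values["leptin_T0_ngml"],
            leptin_T8=values["leptin_T8_ngml"],
            body_fat_T0_kg=values["body_fat_T0_kg"],
            body_fat_T8_kg=values["body_fat_T8_kg"],
            insulin_T0=values["insulin_T0_mUl"],
            insulin_T8=values["insulin_T8_mUl"],
            excluded=row["excluded"].strip().lower() in ("true", "1"),
            exclusion_reason=row["exclusion_reason"].strip() or None,
        ))
    return records


def write_features(features: Sequence[ConnectivityFeature],
                   path: str | Path) -> Path:
    df = pd.DataFrame([{"participant": f.participant, "session": f.session,
                        "roi": f.roi, "z": f.value} for f in features],
                      columns=["participant", "session", "roi", "z"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_features(path: str | Path) -> list[ConnectivityFeature]:
    df = pd.read_csv(path, sep="\t")
    return [ConnectivityFeature(value=float(r.z), roi=str(r.roi),
                                participant=str(r.participant),
                                session=str(r.session))
            for r in df.itertuples()]


def load_config_file(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_summary_json(payload: dict, path: str | Path) -> Path:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
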