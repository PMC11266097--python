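"""NIfTI + TSV dataset persistence.

Layout: one ``.nii.gz`` per volume plus a single ``covariates.tsv`` keyed by
filename, columns ``file sex age ventricle_volume brain_size pathology``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .spec import CovariateRecord, Volume

COVARIATE_COLUMNS = ["file", "sex", "age", "ventricle_volume", "brain_size", "pathology"]
TABLE_NAME = "covariates.tsv"


def write_dataset(volumes: list[Volume], path: str | Path) -> list[Path]:
    """Write volumes as .nii.gz with spacing in the header plus a TSV table."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    files = []
    for i, v in enumerate(volumes):
        name = f"vol_{i:05d}.nii.gz"
        affine = np.diag(list(v.spacing) + [1.0])
        img = nib.Nifti1Image(v.data.astype(np.float32), affine)
        img.header.set_zooms(v.spacing)
        nib.save(img, path / name)
        files.append(path / name)
        c = v.covariates
        if c is None:
            raise ValueError(f"volume {i} has no covariates")
        rows.append(
            {
                "file": name,
                "sex": c.sex,
                "age": repr(c.age),
                "ventricle_volume": repr(c.ventricle_volume),
                "brain_size": repr(c.brain_size),
                "pathology": c.pathology,
            }
        )
    pd.DataFrame(rows, columns=COVARIATE_COLUMNS).to_csv(
        path / TABLE_NAME, sep="\t", index=False
    )
    return files


def read_covariate_table(path: str | Path) -> pd.DataFrame:
    table = Path(path)
    if table.is_dir():
        table = table / TABLE_NAME
    df = pd.read_csv(table, sep="\t", dtype={"file": str, "pathology": str},
                     float_precision="round_trip")
    missing = [c for c in COVARIATE_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing required column(s): {missing}")
    return df


def record_from_row(row) -> CovariateRecord:
    return CovariateRecord(
        sex=int(row["sex"]),
        age=float(row["age"]),
        ventricle_volume=float(row["ventricle_volume"]),
        brain_size=float(row["brain_size"]),
        pathology=str(row["pathology"]),
    )


def read_dataset(path: str | Path) -> list[Volume]:
    """Read a dataset directory back into Volume objects.

    A volume file without a covariate row is an explicit error naming the
    orphan file.
    """
    path = Path(path)
    df = read_covariate_table(path)
    by_file = {row["file"]: row for _, row in df.iterrows()}
    volumes = []
    for f in sorted(path.glob("*.nii.gz")):
        if f.name not in by_file:
            raise ValueError(f"no covariate row for volume file {f.name!r}")
        img = nib.load(f)
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        volumes.append(
            Volume(data=data, spacing=spacing,
                   covariates=record_from_row(by_file[f.name]))
        )
    return volumes
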