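"""File formats: NIfTI volumes, FSL-style bval/bvec tables, TSV tables, config.

The bvec dialect follows FSL: three whitespace-separated rows (x, y, z),
one column per volume.  A ``dialect="column"`` flag on the readers accepts
the transposed (one row per volume) layout.  Diffusivities on disk are in
1e-3 mm^2/s and b-values in s/mm^2; no unit conversion happens here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from renodiff.exceptions import FormatError, ValidationError

log = logging.getLogger(__name__)

_UNIT_TOL = 1e-6


@dataclass
class AcquisitionScheme:
    """b-values and unit gradient directions of a DWI protocol.

    One entry per 4D volume.  Directions at b = 0 may be zero-vectors;
    every direction at b > 0 must have unit Euclidean norm.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise ValidationError(
                f"directions must be (n, 3), got shape {self.directions.shape}"
            )
        self.validate()

    def validate(self):
        if len(self.bvalues) != len(self.directions):
            raise ValidationError(
                f"{len(self.bvalues)} b-values but {len(self.directions)} directions"
            )
        if np.any(self.bvalues < 0):
            raise ValidationError("b-values must be non-negative")
        if self.n_b0 == 0:
            raise ValidationError("scheme must contain at least one b=0 volume")
        norms = np.linalg.norm(self.directions, axis=1)
        bad = (self.bvalues > 0) & (np.abs(norms - 1.0) > _UNIT_TOL)
        if np.any(bad):
            idx = np.flatnonzero(bad)
            raise ValidationError(
                f"non-unit gradient directions at b > 0 for volumes {idx.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    @property
    def unique_bvalues(self) -> np.ndarray:
        return np.unique(self.bvalues)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AcquisitionScheme):
            return NotImplemented
        return np.array_equal(self.bvalues, other.bvalues) and np.allclose(
            self.directions, other.directions, atol=1e-9
        )


@dataclass
class LabeledVolume:
    """3D integer label map with voxel size and a label dictionary.

    Label 0 is background by convention and never appears in the
    dictionary; every nonzero label present in the array must be named.
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"label map must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError("label map must hold integers")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if 0 in self.labels:
            raise ValidationError("label 0 is reserved for background")
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from dictionary")

    def mask(self, label=None) -> np.ndarray:
        """Boolean mask of one label, or of all nonzero labels."""
        if label is None:
            return self.data > 0
        return self.data == label


# ---------------------------------------------------------------------------
# bval / bvec


def read_bval_bvec(path_bval, path_bvec, dialect: str = "fsl") -> AcquisitionScheme:
    """Read FSL-style bval/bvec text files into an AcquisitionScheme."""
    bvals = np.loadtxt(path_bval, ndmin=1).ravel()
    bvecs = np.loadtxt(path_bvec, ndmin=2)
    if dialect == "fsl":
        if bvecs.shape[0] != 3:
            raise FormatError(
                f"FSL bvec needs 3 rows, found {bvecs.shape[0]} in {path_bvec}"
            )
        bvecs = bvecs.T
    elif dialect == "column":
        if bvecs.shape[1] != 3:
            raise FormatError(
                f"column bvec needs 3 columns, found {bvecs.shape[1]} in {path_bvec}"
            )
    else:
        raise ValueError(f"unknown bvec dialect {dialect!r}")
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"bval lists {len(bvals)} volumes but bvec lists {len(bvecs)}"
        )
    return AcquisitionScheme(bvals, bvecs)


def write_bval_bvec(scheme: AcquisitionScheme, path_bval, path_bvec):
    np.savetxt(path_bval, scheme.bvalues[None, :], fmt="%.17g")
    np.savetxt(path_bvec, scheme.directions.T, fmt="%.17g")


# ---------------------------------------------------------------------------
# NIfTI


def read_dwi(path_nifti, path_bval, path_bvec, dialect: str = "fsl"):
    """Load a 4D DWI NIfTI together with its validated acquisition scheme.

    Returns ``(volume, scheme)`` with the volume in native voxel order
    (no reorientation is ever applied).
    """
    img = nib.load(str(path_nifti))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D NIfTI, got {data.ndim}D in {path_nifti}")
    scheme = read_bval_bvec(path_bval, path_bvec, dialect=dialect)
    if len(scheme) != data.shape[3]:
        raise FormatError(
            f"NIfTI holds {data.shape[3]} volumes but the scheme lists {len(scheme)}"
        )
    return data, scheme


def write_dwi(volume, scheme: AcquisitionScheme, path_nifti, voxel_size=(1.0, 1.0, 1.0)):
    """Write a 4D volume plus sibling .bval/.bvec files.

    The bval/bvec paths are derived from ``path_nifti`` by swapping the
    extension, matching the FSL convention.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 4 or volume.size == 0:
        raise ValidationError("volume must be 4D and non-empty")
    if volume.shape[3] != len(scheme):
        raise ValidationError(
            f"volume has {volume.shape[3]} frames but the scheme lists {len(scheme)}"
        )
    path_nifti = Path(path_nifti)
    stem = path_nifti.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(volume, affine), str(path_nifti))
    write_bval_bvec(
        scheme,
        path_nifti.with_name(stem + ".bval"),
        path_nifti.with_name(stem + ".bvec"),
    )


def read_volume(path) -> np.ndarray:
    """Load a 3D or 4D NIfTI as a float array."""
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def write_volume(volume, path, voxel_size=(1.0, 1.0, 1.0)):
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def _label_sidecar(path) -> Path:
    path = Path(path)
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".labels.json")


def read_labels(path, labels: dict | None = None) -> LabeledVolume:
    """Load an integer label map; names come from ``labels``, from a
    ``<stem>.labels.json`` sidecar if present, or fall back to
    ``label_<id>``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.rint(data).astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if labels is None:
        sidecar = _label_sidecar(path)
        if sidecar.exists():
            labels = {int(k): str(v) for k, v in json.loads(sidecar.read_text()).items()}
        else:
            labels = {int(v): f"label_{int(v)}" for v in np.unique(data) if v != 0}
    return LabeledVolume(data, voxel_size, labels)


def write_labels(labeled: LabeledVolume, path):
    """Write the label map plus a ``.labels.json`` name sidecar."""
    affine = np.diag(list(labeled.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(labeled.data.astype(np.int16), affine), str(path))
    _label_sidecar(path).write_text(
        json.dumps({str(k): v for k, v in labeled.labels.items()}, indent=2) + "\n"
    )


# ---------------------------------------------------------------------------
# Tables


def write_table(table, path, sep: str = "\t"):
    """Write an ROI summary or stats result to TSV/CSV.

    Accepts a pandas DataFrame or any object exposing ``to_frame()``
    (ROISummary, ComparisonResult collections).  Numeric columns keep
    full precision; display columns of the form ``mean (sd)`` are added
    by the summary objects themselves.
    """
    if hasattr(table, "to_frame") and not isinstance(table, pd.DataFrame):
        table = table.to_frame()
    if not isinstance(table, pd.DataFrame):
        raise ValidationError(f"cannot write object of type {type(table).__name__}")
    if table.empty:
        raise ValidationError("refusing to write an empty table")
    table.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Run configuration


def read_config(path) -> dict:
    """Read a JSON or YAML run-configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise FormatError(f"config file {path} must hold a mapping")
    return out


def write_config(config: dict, path):
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
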