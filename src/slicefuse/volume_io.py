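"""Volume and manifest I/O, intensity normalization, and view reorientation.

A stored brain volume is a single-channel 3D array (the PET volumes this
package was designed around are 96 x 160 x 160). Classification fuses the
volume along one anatomical axis — axial, coronal or sagittal — so the
central reshaping step here is :func:`reorient_for_view`, which moves the
chosen fusion axis to position 0 without any interpolation.

The default axis mapping for a stored (96, 160, 160) array is
axis 0 = axial, axis 1 = coronal, axis 2 = sagittal, which reproduces the
standard fused-image shapes: 160x160 (axial), 96x160 (coronal), 96x160
(sagittal). The mapping is configurable because stored orientations vary
between archives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VolumeSample",
    "ViewAxis",
    "SliceStack",
    "Manifest",
    "DEFAULT_AXIS_MAPPING",
    "load_volume",
    "save_volume",
    "normalize_volume",
    "reorient_for_view",
    "inverse_reorient",
    "load_manifest",
]

#: stored-array axis for each anatomical view of a canonically oriented volume
DEFAULT_AXIS_MAPPING: dict[str, int] = {"axial": 0, "coronal": 1, "sagittal": 2}

VIEW_NAMES = ("axial", "coronal", "sagittal")


@dataclass(frozen=True)
class ViewAxis:
    """One anatomical view and the stored-array axis it corresponds to."""

    name: str
    axis_index: int

    def __post_init__(self):
        if self.name not in VIEW_NAMES:
            raise ValueError(f"unknown view {self.name!r}; expected one of {VIEW_NAMES}")
        if self.axis_index not in (0, 1, 2):
            raise ValueError("axis_index must be 0, 1 or 2")

    @classmethod
    def from_name(cls, name: str, mapping: dict[str, int] | None = None) -> "ViewAxis":
        mapping = mapping or DEFAULT_AXIS_MAPPING
        if sorted(mapping.values()) != [0, 1, 2]:
            raise ValueError("axis mapping must be a bijection onto {0, 1, 2}")
        if name not in mapping:
            raise ValueError(f"unknown view {name!r}")
        return cls(name, mapping[name])


@dataclass
class VolumeSample:
    """One single-channel 3D volume with a binary diagnosis label.

    label 0 = negative (cognitively unimpaired), 1 = positive (disease).
    """

    id: str
    voxels: np.ndarray
    label: int

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"non-3D data: volume {self.id!r} has ndim {self.voxels.ndim}")
        if any(d < 2 for d in self.voxels.shape):
            raise ValueError(f"volume {self.id!r}: every dimension must be >= 2")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError(f"volume {self.id!r} contains NaN/Inf voxels")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class SliceStack:
    """A volume permuted so axis 0 is the fusion axis: T slices of H x W."""

    slices: np.ndarray
    view: ViewAxis

    def __post_init__(self):
        if self.slices.ndim != 3:
            raise ValueError("slice stack must be 3D")

    @property
    def T(self) -> int:
        return self.slices.shape[0]

    @property
    def H(self) -> int:
        return self.slices.shape[1]

    @property
    def W(self) -> int:
        return self.slices.shape[2]


@dataclass
class Manifest:
    """(id, path, label) records driving training and evaluation."""

    records: list[tuple[str, str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r[2] for r in self.records], dtype=int)


def load_volume(path: str | Path, expected_shape: tuple[int, int, int] | None = None,
                label: int = 0, sample_id: str | None = None) -> VolumeSample:
    """Read a volume from a NIfTI (.nii/.nii.gz) or raw .npy file.

    ``expected_shape``, when given, is validated against the stored array —
    useful to catch mis-exported archives (e.g. expecting 96 x 160 x 160).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"non-3D data in {path.name}: ndim={data.ndim}")
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(
            f"shape mismatch in {path.name}: got {data.shape}, expected {tuple(expected_shape)}"
        )
    return VolumeSample(id=sample_id or path.stem.replace(".nii", ""), voxels=data, label=label)


def save_volume(v: VolumeSample, path: str | Path) -> Path:
    """Write a volume as .npy or NIfTI, by extension."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, v.voxels)
    else:
        import nibabel as nib

        nib.save(nib.Nifti1Image(v.voxels, affine=np.eye(4)), str(path))
    return path


def normalize_volume(v: VolumeSample, method: str = "minmax") -> VolumeSample:
    """Rescale intensities: per-volume min-max to [0, 1] or z-score.

    A constant volume maps to all zeros under either method (degenerate-case
    convention: there is no scale to recover).
    """
    x = v.voxels
    if method == "minmax":
        lo, hi = x.min(), x.max()
        out = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    elif method == "zscore":
        mu, sd = x.mean(), x.std()
        out = np.zeros_like(x) if sd == 0 else (x - mu) / sd
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return VolumeSample(id=v.id, voxels=out, label=v.label)


def reorient_for_view(v: VolumeSample, view: ViewAxis | str,
                      mapping: dict[str, int] | None = None) -> SliceStack:
    """Move the view's axis to position 0. Pure axis permutation, no resampling."""
    if isinstance(view, str):
        view = ViewAxis.from_name(view, mapping)
    return SliceStack(slices=np.moveaxis(v.voxels, view.axis_index, 0), view=view)


def inverse_reorient(stack: SliceStack) -> np.ndarray:
    """Undo :func:`reorient_for_view`, returning the original voxel layout."""
    return np.moveaxis(stack.slices, 0, stack.view.axis_index)


def load_manifest(path: str | Path) -> Manifest:
    """Read a CSV manifest with columns id, path, label (labels in {0, 1})."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no records in manifest {path}") from None
    for col in ("id", "path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"no records in manifest {path}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in manifest: {dupes}")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        bad = sorted(set(labels) - {0, 1})
        raise ValueError(f"labels outside {{0, 1}}: {bad}")
    return Manifest(records=[(str(r.id), str(r.path), int(r.label)) for r in df.itertuples()])
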