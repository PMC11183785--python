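"""Readers/writers for 4D flow datasets and segmentation masks.

A 4D flow acquisition is held as a :class:`FlowVolume4D`: one magnitude
series and a 3-component velocity series over N cardiac phases on a common
voxel grid, plus the acquisition metadata needed downstream (voxel spacing,
temporal resolution TR, and the low/high velocity-encoding limits of a
dual-VENC protocol).

Canonical on-disk layout is a single HDF5 bundle (datasets ``/magnitude``
and ``/velocity``, metadata as root attributes).  NIfTI import/export is
provided for interoperability: one file per component plus a YAML metadata
sidecar.  Axis order is fixed internally to phase x (component x) z x y x x;
NIfTI's x-fastest order is converted on read.  World coordinates are
``index * spacing`` (scanner affines are out of scope here).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "FlowVolume4D",
    "SegmentationMask",
    "load_flow_dataset",
    "save_flow_dataset",
    "load_mask",
    "save_mask",
    "estimate_heart_rate",
]

#: Integer phase-difference encodings map [-PHASE_INT_SCALE, PHASE_INT_SCALE-1]
#: onto [-VENC, VENC); 12-bit signed is the convention adopted here.
PHASE_INT_SCALE = 4096

_VELOCITY_COMPONENTS = ("velocity_x", "velocity_y", "velocity_z")


class IncompleteDatasetError(FileNotFoundError):
    """A required component of a 4D flow dataset is missing on disk."""


@dataclasses.dataclass
class FlowVolume4D:
    """Magnitude + 3-component velocity over cardiac phases on one grid.

    Parameters
    ----------
    magnitude : ndarray, shape (n_phases, nz, ny, nx)
        Signal magnitude per cardiac phase, arbitrary units, >= 0.
    velocity : ndarray, shape (n_phases, 3, nz, ny, nx)
        Velocity in m/s; component axis ordered (x, y, z).
    spacing : ndarray, shape (3,)
        Voxel spacing in mm, (z, y, x) order.
    tr_ms : float
        Temporal resolution per cardiac phase in ms.
    venc_low, venc_high : float
        Velocity-encoding limits in m/s; velocities beyond +/-VENC alias.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    spacing: np.ndarray
    tr_ms: float
    venc_low: float
    venc_high: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.magnitude.ndim != 4:
            raise ValueError("magnitude must be 4D (phase, z, y, x)")
        if self.velocity.ndim != 5 or self.velocity.shape[1] != 3:
            raise ValueError("velocity must be 5D (phase, component, z, y, x)")
        if self.velocity.shape[0] != self.magnitude.shape[0]:
            raise ValueError("magnitude and velocity disagree on phase count")
        if self.velocity.shape[2:] != self.magnitude.shape[1:]:
            raise ValueError("magnitude and velocity disagree on spatial dims")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be a positive 3-vector (z, y, x)")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if not 0 < self.venc_low <= self.venc_high:
            raise ValueError("require 0 < venc_low <= venc_high")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude values must be >= 0")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[1:]

    @property
    def heart_rate_bpm(self) -> float:
        return estimate_heart_rate(self.tr_ms, self.n_phases)

    def replace(self, **kwargs) -> "FlowVolume4D":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass
class SegmentationMask:
    """Binary 3D vessel mask (1 = vessel) aligned to a flow volume grid."""

    labels: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        vals = np.unique(self.labels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        self.labels = self.labels.astype(np.uint8)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be a positive 3-vector (z, y, x)")

    @property
    def n_foreground(self) -> int:
        return int(self.labels.sum())


def estimate_heart_rate(tr_ms: float, n_phases: int) -> float:
    """Heart rate (bpm) from temporal resolution and cardiac phase count.

    The cardiac period is estimated as ``(n_phases + 1) * tr_ms``: the
    reconstructed phases tile the cycle but the trigger window discards
    roughly one TR at end-diastole, so the period exceeds ``n_phases * TR``
    by one TR.
    """
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    period_ms = (n_phases + 1) * tr_ms
    return 60000.0 / period_ms


# ---------------------------------------------------------------------------
# HDF5 bundle


def save_flow_dataset(vol: FlowVolume4D, path: str | Path) -> Path:
    """Write a flow volume; HDF5 bundle if *path* ends in .h5/.hdf5, else a
    directory of NIfTI components with a YAML sidecar."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _save_hdf5(vol, path)
    return _save_nifti_dir(vol, path)


def load_flow_dataset(path: str | Path) -> FlowVolume4D:
    """Read a flow volume saved by :func:`save_flow_dataset`.

    Velocities are returned in m/s whatever the on-disk representation:
    integer-encoded phase data are rescaled by ``venc_high`` using the
    12-bit convention ``v = stored / 4096 * VENC``.
    """
    path = Path(path)
    if path.is_file() and path.suffix in {".h5", ".hdf5"}:
        return _load_hdf5(path)
    if path.is_dir():
        return _load_nifti_dir(path)
    raise IncompleteDatasetError(f"no flow dataset at {path}")


def _save_hdf5(vol: FlowVolume4D, path: Path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=vol.magnitude)
        f.create_dataset("velocity", data=vol.velocity)
        f.attrs["spacing"] = vol.spacing
        f.attrs["tr_ms"] = float(vol.tr_ms)
        f.attrs["venc_low"] = float(vol.venc_low)
        f.attrs["venc_high"] = float(vol.venc_high)
    return path


def _load_hdf5(path: Path) -> FlowVolume4D:
    with h5py.File(path, "r") as f:
        for name in ("magnitude", "velocity"):
            if name not in f:
                raise IncompleteDatasetError(f"incomplete dataset: {name}")
        magnitude = f["magnitude"][()]
        velocity = f["velocity"][()]
        attrs = dict(f.attrs)
    venc_high = float(attrs["venc_high"])
    if np.issubdtype(velocity.dtype, np.integer):
        velocity = velocity.astype(np.float64) / PHASE_INT_SCALE * venc_high
    return FlowVolume4D(
        magnitude=magnitude,
        velocity=velocity,
        spacing=np.asarray(attrs["spacing"]),
        tr_ms=float(attrs["tr_ms"]),
        venc_low=float(attrs["venc_low"]),
        venc_high=venc_high,
    )


# ---------------------------------------------------------------------------
# NIfTI directory mode

# internal (z, y, x) -> NIfTI (x, y, z): reverse spatial axes


def _to_nifti_array(arr_zyx: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(arr_zyx.T)


def _from_nifti_array(arr_xyz: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(arr_xyz.T)


def _nifti_affine(spacing_zyx: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_zyx[::-1]
    return aff


def _save_nifti_dir(vol: FlowVolume4D, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    aff = _nifti_affine(vol.spacing)
    # 4D NIfTI: (x, y, z, phase)
    mag = np.moveaxis(_to_nifti_array_4d(vol.magnitude), 0, -1)
    nib.save(nib.Nifti1Image(mag, aff), path / "magnitude.nii.gz")
    for ci, name in enumerate(_VELOCITY_COMPONENTS):
        comp = np.moveaxis(_to_nifti_array_4d(vol.velocity[:, ci]), 0, -1)
        nib.save(nib.Nifti1Image(comp, aff), path / f"{name}.nii.gz")
    meta = {
        "spacing": [float(s) for s in vol.spacing],
        "tr_ms": float(vol.tr_ms),
        "venc_low": float(vol.venc_low),
        "venc_high": float(vol.venc_high),
        "n_phases": int(vol.n_phases),
    }
    (path / "meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True), encoding="utf-8"
    )
    return path


def _to_nifti_array_4d(arr: np.ndarray) -> np.ndarray:
    # (phase, z, y, x) -> (phase, x, y, z)
    return np.ascontiguousarray(np.transpose(arr, (0, 3, 2, 1)))


def _load_nifti_dir(path: Path) -> FlowVolume4D:
    sidecar = path / "meta.yaml"
    if not sidecar.exists():
        raise IncompleteDatasetError("incomplete dataset: meta.yaml")
    meta = yaml.safe_load(sidecar.read_text(encoding="utf-8"))
    venc_high = float(meta["venc_high"])

    def read4d(name: str) -> np.ndarray:
        f = path / f"{name}.nii.gz"
        if not f.exists():
            f = path / f"{name}.nii"
        if not f.exists():
            raise IncompleteDatasetError(f"incomplete dataset: {name}")
        data = np.asarray(nib.load(f).dataobj)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        # (x, y, z, phase) -> (phase, z, y, x)
        data = np.transpose(data, (3, 2, 1, 0))
        if np.issubdtype(data.dtype, np.integer) and name != "magnitude":
            data = data.astype(np.float64) / PHASE_INT_SCALE * venc_high
        return np.ascontiguousarray(data)

    magnitude = read4d("magnitude")
    velocity = np.stack([read4d(n) for n in _VELOCITY_COMPONENTS], axis=1)
    return FlowVolume4D(
        magnitude=magnitude,
        velocity=velocity,
        spacing=np.asarray(meta["spacing"], dtype=float),
        tr_ms=float(meta["tr_ms"]),
        venc_low=float(meta["venc_low"]),
        venc_high=venc_high,
    )


# ---------------------------------------------------------------------------
# Masks


def save_mask(mask: SegmentationMask, path: str | Path) -> Path:
    path = Path(path)
    aff = _nifti_affine(mask.spacing)
    nib.save(nib.Nifti1Image(_to_nifti_array(mask.labels).astype(np.uint8), aff), path)
    return path


def load_mask(
    path: str | Path,
    *,
    expected_spacing: np.ndarray | None = None,
    atol: float = 1e-4,
) -> SegmentationMask:
    """Read a NIfTI label volume as a binary mask.

    Any nonzero integer label is coerced to 1 (with a warning when labels
    other than {0, 1} occur).  Non-integer voxel values beyond *atol* raise.
    If *expected_spacing* is given, header spacing must match it within
    tolerance (alignment check against a paired flow volume).
    """
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    rounded = np.rint(data)
    if np.max(np.abs(data - rounded)) > atol:
        raise ValueError(f"non-integer voxel values in mask {path}")
    labels_xyz = rounded.astype(np.int64)
    vals = np.unique(labels_xyz)
    if not np.isin(vals, (0, 1)).all():
        warnings.warn(
            f"mask {path} has labels {vals.tolist()}; coercing nonzero to 1",
            stacklevel=2,
        )
        labels_xyz = (labels_xyz != 0).astype(np.int64)
    spacing_xyz = np.asarray(img.header.get_zooms()[:3], dtype=float)
    spacing = spacing_xyz[::-1].copy()
    if expected_spacing is not None and not np.allclose(
        spacing, expected_spacing, atol=atol
    ):
        raise ValueError(
            f"mask spacing {spacing.tolist()} does not match paired flow "
            f"volume spacing {np.asarray(expected_spacing).tolist()}"
        )
    return SegmentationMask(labels=_from_nifti_array(labels_xyz), spacing=spacing)
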