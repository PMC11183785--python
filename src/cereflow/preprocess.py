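"""Velocity-field corrections applied before angiogram computation.

Three standard phase-contrast preprocessing steps, each kept deliberately
simple and fully property-testable:

* **Noise masking** — a quantile threshold on the time-averaged magnitude
  separates signal-bearing voxels (tissue + vessel) from air/noise;
  background velocities are zeroed.
* **Eddy-current correction** — residual gradient-induced phase offsets
  appear as a smooth, temporally constant velocity bias.  A low-order
  spatial polynomial is least-squares fitted to the temporal-mean velocity
  of static tissue and subtracted from every phase.
* **Dual-VENC anti-aliasing** — velocities beyond the low VENC wrap by
  multiples of 2*VENC_low; the alias-free (noisier) high-VENC measurement
  selects the correct replica per voxel.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import FlowVolume4D, SegmentationMask

__all__ = [
    "StaticTissueMask",
    "compute_noise_mask",
    "static_tissue_mask",
    "eddy_current_correct",
    "dualvenc_unwrap",
]

DEFAULT_NOISE_QUANTILE = 0.35
DEFAULT_EDDY_POLY_ORDER = 2
DEFAULT_STATIC_STD_FRAC = 0.05


@dataclasses.dataclass
class StaticTissueMask:
    """Binary grid marking voxels assumed to contain non-moving tissue."""

    labels: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not np.isin(np.unique(self.labels), (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")


def compute_noise_mask(
    vol: FlowVolume4D, magnitude_quantile: float = DEFAULT_NOISE_QUANTILE
) -> SegmentationMask:
    """Mask of signal-bearing voxels from a magnitude quantile threshold.

    A voxel is kept when its time-averaged magnitude exceeds the given
    quantile of the whole-volume time-averaged magnitude distribution.
    A constant magnitude volume makes the threshold degenerate; the mask
    is then all-ones with a warning.
    """
    if not 0 < magnitude_quantile < 1:
        raise ValueError("magnitude_quantile must lie strictly in (0, 1)")
    tavg = vol.magnitude.mean(axis=0)
    thr = np.quantile(tavg, magnitude_quantile)
    if np.isclose(tavg.max(), tavg.min()):
        warnings.warn(
            "constant magnitude volume: noise threshold degenerate, "
            "returning all-ones mask",
            stacklevel=2,
        )
        labels = np.ones_like(tavg, dtype=np.uint8)
    else:
        labels = (tavg > thr).astype(np.uint8)
    return SegmentationMask(labels=labels, spacing=vol.spacing.copy())


def apply_noise_mask(vol: FlowVolume4D, mask: SegmentationMask) -> FlowVolume4D:
    """Zero velocities outside the noise mask; magnitude untouched."""
    v = vol.velocity * mask.labels[np.newaxis, np.newaxis]
    return vol.replace(velocity=v)


def static_tissue_mask(
    vol: FlowVolume4D,
    noise_mask: SegmentationMask | None = None,
    std_frac: float = DEFAULT_STATIC_STD_FRAC,
) -> StaticTissueMask:
    """Identify static tissue: signal-bearing voxels with low temporal
    velocity variation (std below ``std_frac * venc_high`` in every
    component)."""
    if noise_mask is None:
        noise_mask = compute_noise_mask(vol)
    vstd = vol.velocity.std(axis=0)  # (3, z, y, x)
    quiet = (vstd < std_frac * vol.venc_high).all(axis=0)
    labels = (noise_mask.labels.astype(bool) & quiet).astype(np.uint8)
    return StaticTissueMask(labels=labels, spacing=vol.spacing.copy())


def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Design matrix of all monomials x^a y^b z^c with a+b+c <= order.

    *coords* is (n, 3) in normalized [-1, 1] coordinates (conditioning).
    """
    n = coords.shape[0]
    cols = []
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                cols.append(
                    coords[:, 0] ** a * coords[:, 1] ** b * coords[:, 2] ** c
                )
    return np.stack(cols, axis=1) if cols else np.ones((n, 1))


def n_poly_coeffs(order: int) -> int:
    return (order + 1) * (order + 2) * (order + 3) // 6


def eddy_current_correct(
    vol: FlowVolume4D,
    static: StaticTissueMask,
    poly_order: int = DEFAULT_EDDY_POLY_ORDER,
) -> FlowVolume4D:
    """Remove a smooth spatial velocity offset fitted on static tissue.

    Per velocity component, a polynomial of total degree *poly_order* in the
    voxel coordinates is least-squares fitted to the temporal-mean velocity
    inside the static mask, then subtracted from every cardiac phase.
    Requires at least 10x as many static voxels as fitted coefficients.
    The operation is idempotent up to numerical precision: after one pass
    the static-tissue temporal-mean velocity has no polynomial component
    left to fit.
    """
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    ncoef = n_poly_coeffs(poly_order)
    static_idx = np.argwhere(static.labels.astype(bool))
    if static_idx.shape[0] < 10 * ncoef:
        raise ValueError(
            f"static mask has {static_idx.shape[0]} voxels; need >= "
            f"{10 * ncoef} for a degree-{poly_order} fit"
        )
    shape = vol.spatial_shape
    # normalize coordinates to [-1, 1] per axis for conditioning
    scale = np.maximum(np.asarray(shape) - 1, 1)
    norm = static_idx / scale * 2.0 - 1.0
    design = _poly_design(norm, poly_order)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"eddy-current fit rank-deficient ({rank} < {design.shape[1]})"
        )

    grid_idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    grid_norm = grid_idx / scale * 2.0 - 1.0
    grid_design = _poly_design(grid_norm, poly_order)

    vmean = vol.velocity.mean(axis=0)  # (3, z, y, x)
    corrected = vol.velocity.copy()
    flat_static = vmean.reshape(3, -1)[
        :, np.ravel_multi_index(static_idx.T, shape)
    ]
    for c in range(3):
        coef, *_ = np.linalg.lstsq(design, flat_static[c], rcond=None)
        offset = (grid_design @ coef).reshape(shape)
        corrected[:, c] -= offset
    return vol.replace(velocity=corrected)


def dualvenc_unwrap(
    v_low: np.ndarray, v_high: np.ndarray, venc_low: float
) -> np.ndarray:
    """Resolve velocity aliasing in the low-VENC data using the high-VENC
    measurement as replica selector.

    Per value the output is ``v_low + 2*venc_low*k`` with the integer k that
    brings it closest to ``v_high``; ties break toward smaller ``|k|``.  The
    output is always congruent to ``v_low`` modulo ``2*venc_low``, so the
    low-VENC noise level is preserved while the high-VENC range is gained.
    """
    v_low = np.asarray(v_low, dtype=np.float64)
    v_high = np.asarray(v_high, dtype=np.float64)
    if v_low.shape != v_high.shape:
        raise ValueError("v_low and v_high must have identical shapes")
    if venc_low <= 0:
        raise ValueError("venc_low must be positive")
    period = 2.0 * venc_low
    kf = (v_high - v_low) / period
    k_lo = np.floor(kf)
    k_hi = k_lo + 1.0
    r_lo = np.abs(v_low + period * k_lo - v_high)
    r_hi = np.abs(v_low + period * k_hi - v_high)
    use_hi = r_hi < r_lo
    tie = r_hi == r_lo
    use_hi |= tie & (np.abs(k_hi) < np.abs(k_lo))
    k = np.where(use_hi, k_hi, k_lo)
    return v_low + period * k
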