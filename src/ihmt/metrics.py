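r"""Voxelwise semi-quantitative magnetization-transfer ratios.

Five ratios are computed from the six weighted volumes of one scan:

.. math::

    MTR        &= 1 - (S_+ + S_-) / (2 S_0) \\
    eMTR       &= 1 - (S_{+/-} + S_{-/+}) / (2 S_0) \\
    MT_{asym}  &= (S_+ - S_-) / S_0 \\
    ihMTR      &= 2\,(eMTR - MTR) \\
    ihMTR_{inv}&= 2 S_{T1} (1/S_{+/-} + 1/S_{-/+} - 1/S_+ - 1/S_-)

where :math:`S_0` is the unsaturated reference, :math:`S_\pm` the
single-sided saturated signals, :math:`S_{\pm/\mp}` the dual-sided
(frequency-alternating) signals and :math:`S_{T1}` the T1-prepared
signal.  All ratios are dimensionless fractions and invariant under a
global rescaling of the six signals (receive-gain independence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .volumes import Volume3D

__all__ = [
    "WeightedVolumeSet",
    "RatioMaps",
    "compute_mtr",
    "compute_emtr",
    "compute_mtasym",
    "compute_ihmtr",
    "compute_ihmtr_inv",
    "compute_ratio_maps",
]

#: Default background threshold as a fraction of max(S0).
DEFAULT_S0_THRESHOLD = 0.05

METRIC_NAMES = ("mtr", "emtr", "mtasym", "ihmtr", "ihmtr_inv")


@dataclass
class WeightedVolumeSet:
    """The six co-registered weighted volumes of one ihMT scan."""

    s0: Volume3D        # no saturation (PD-weighted reference)
    splus: Volume3D     # single-sided, positive offset
    sminus: Volume3D    # single-sided, negative offset
    spm: Volume3D       # dual-sided, starting positive (+/-)
    smp: Volume3D       # dual-sided, starting negative (-/+)
    st1: Volume3D       # T1-prepared

    def __post_init__(self) -> None:
        ref = self.s0
        for f in fields(self):
            v = getattr(self, f.name)
            if not ref.same_grid(v):
                raise ValueError(f"grid mismatch: volume '{f.name}' differs from s0")

    def volumes(self) -> dict[str, Volume3D]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class RatioMaps:
    """The five derived ratio maps plus the brain mask (1 inside, 0 outside)."""

    mtr: Volume3D
    emtr: Volume3D
    mtasym: Volume3D
    ihmtr: Volume3D
    ihmtr_inv: Volume3D
    mask: Volume3D

    def as_dict(self) -> dict[str, Volume3D]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _mask_from_s0(ws: WeightedVolumeSet, s0_threshold: float) -> np.ndarray:
    s0 = ws.s0.data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmax(s0) if np.isfinite(s0).any() else 0.0
    if not np.isfinite(mx) or mx <= 0:
        warnings.warn("all-masked input: S0 has no positive voxels", stacklevel=3)
        return np.zeros(s0.shape, dtype=bool)
    mask = s0 > s0_threshold * mx
    if not mask.any():
        warnings.warn("all-masked input: no voxel exceeds the S0 threshold", stacklevel=3)
    return mask


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with non-positive denominators mapped to NaN."""
    bad = ~(den > 0)
    out = np.divide(num, np.where(bad, 1.0, den))
    out[bad] = np.nan
    return out


def _apply_mask(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.where(mask, arr, np.nan)
    return out


def compute_mtr(
    ws: WeightedVolumeSet, s0_threshold: float = DEFAULT_S0_THRESHOLD
) -> Volume3D:
    """MTR = 1 - (S+ + S-)/(2 S0)."""
    mask = _mask_from_s0(ws, s0_threshold)
    mtr = 1.0 - _safe_div(ws.splus.data + ws.sminus.data, 2.0 * ws.s0.data)
    return Volume3D(_apply_mask(mtr, mask), ws.s0.voxel_to_mm.copy())


def compute_emtr(
    ws: WeightedVolumeSet, s0_threshold: float = DEFAULT_S0_THRESHOLD
) -> Volume3D:
    """eMTR = 1 - (S+/- + S-/+)/(2 S0)."""
    mask = _mask_from_s0(ws, s0_threshold)
    emtr = 1.0 - _safe_div(ws.spm.data + ws.smp.data, 2.0 * ws.s0.data)
    return Volume3D(_apply_mask(emtr, mask), ws.s0.voxel_to_mm.copy())


def compute_mtasym(
    ws: WeightedVolumeSet, s0_threshold: float = DEFAULT_S0_THRESHOLD
) -> Volume3D:
    """MTasym = (S+ - S-)/S0; positive when negative-offset saturation is stronger."""
    mask = _mask_from_s0(ws, s0_threshold)
    asym = _safe_div(ws.splus.data - ws.sminus.data, ws.s0.data)
    return Volume3D(_apply_mask(asym, mask), ws.s0.voxel_to_mm.copy())


def compute_ihmtr(
    ws: WeightedVolumeSet, s0_threshold: float = DEFAULT_S0_THRESHOLD
) -> Volume3D:
    """ihMTR = 2 (eMTR - MTR) = (S+ + S- - S+/- - S-/+)/S0."""
    mask = _mask_from_s0(ws, s0_threshold)
    emtr = 1.0 - _safe_div(ws.spm.data + ws.smp.data, 2.0 * ws.s0.data)
    mtr = 1.0 - _safe_div(ws.splus.data + ws.sminus.data, 2.0 * ws.s0.data)
    return Volume3D(_apply_mask(2.0 * (emtr - mtr), mask), ws.s0.voxel_to_mm.copy())


def compute_ihmtr_inv(
    ws: WeightedVolumeSet, s0_threshold: float = DEFAULT_S0_THRESHOLD
) -> Volume3D:
    """ihMTRinv = 2 ST1 (1/S+/- + 1/S-/+ - 1/S+ - 1/S-).

    The reciprocal form scales each term by the T1-prepared signal, which
    reduces T1- and B1-related confounds of the plain ihMTR.  Any voxel in
    which one of the four saturated signals is below the S0 threshold (in
    absolute units) is masked, since its reciprocal would be unstable.
    """
    s0 = ws.s0.data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmax(s0) if np.isfinite(s0).any() else 0.0
    thresh = s0_threshold * mx if np.isfinite(mx) and mx > 0 else np.inf
    mask = _mask_from_s0(ws, s0_threshold)
    for arr in (ws.splus.data, ws.sminus.data, ws.spm.data, ws.smp.data):
        mask = mask & (arr > thresh)
    inv = 2.0 * ws.st1.data * (
        _safe_div(1.0, ws.spm.data)
        + _safe_div(1.0, ws.smp.data)
        - _safe_div(1.0, ws.splus.data)
        - _safe_div(1.0, ws.sminus.data)
    )
    return Volume3D(_apply_mask(inv, mask), ws.s0.voxel_to_mm.copy())


def compute_ratio_maps(
    ws: WeightedVolumeSet,
    s0_threshold: float = DEFAULT_S0_THRESHOLD,
    mask: Volume3D | None = None,
) -> RatioMaps:
    """Compute all five ratio maps and the mask in one pass.

    Parameters
    ----------
    ws
        The six co-registered weighted volumes.
    s0_threshold
        Background cut as a fraction of max(S0); voxels with
        ``S0 <= s0_threshold * max(S0)`` are masked.  Ignored when an
        explicit ``mask`` volume is supplied.
    mask
        Optional explicit brain mask (non-zero = keep) overriding the
        S0 threshold.
    """
    if mask is not None:
        if not ws.s0.same_grid(mask):
            raise ValueError("grid mismatch: mask differs from s0")
        keep = np.nan_to_num(mask.data) > 0
        if not keep.any():
            warnings.warn("all-masked input: explicit mask is empty", stacklevel=2)
    else:
        keep = _mask_from_s0(ws, s0_threshold)

    affine = ws.s0.voxel_to_mm.copy()
    mtr = 1.0 - _safe_div(ws.splus.data + ws.sminus.data, 2.0 * ws.s0.data)
    emtr = 1.0 - _safe_div(ws.spm.data + ws.smp.data, 2.0 * ws.s0.data)
    asym = _safe_div(ws.splus.data - ws.sminus.data, ws.s0.data)
    ihmtr = 2.0 * (emtr - mtr)
    inv = 2.0 * ws.st1.data * (
        _safe_div(1.0, ws.spm.data)
        + _safe_div(1.0, ws.smp.data)
        - _safe_div(1.0, ws.splus.data)
        - _safe_div(1.0, ws.sminus.data)
    )
    return RatioMaps(
        mtr=Volume3D(_apply_mask(mtr, keep), affine),
        emtr=Volume3D(_apply_mask(emtr, keep), affine),
        mtasym=Volume3D(_apply_mask(asym, keep), affine),
        ihmtr=Volume3D(_apply_mask(ihmtr, keep), affine),
        ihmtr_inv=Volume3D(_apply_mask(inv, keep), affine),
        mask=Volume3D(keep.astype(np.float64), affine),
    )
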