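"""ROI summary statistics and coefficient-of-variation analysis.

Works on long-format ROI tables with columns
``subject, session, repeat, roi, metric, value`` — one row per ROI mean
per scan per metric.  ROI means are computed in each scan's native
space (labels are pulled through the concatenated transform chain
rather than resampling the maps), so a map is averaged exactly once.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import RatioMaps
from .volumes import LabelVolume, Volume3D

__all__ = [
    "roi_means",
    "roi_table_from_maps",
    "cov_between",
    "cov_within",
    "cov_map",
    "summarize_table",
    "read_roi_table",
]

TABLE_COLUMNS = ["subject", "session", "repeat", "roi", "metric", "value"]


def roi_means(map_: Volume3D, labels: LabelVolume) -> pd.DataFrame:
    """Mean of the non-NaN voxels of ``map_`` within each non-zero label.

    Returns a frame with columns (roi, label, n_voxels, value); ROIs
    whose voxels are all NaN are reported with value NaN (missing).
    """
    if map_.data.shape != labels.labels.shape or not np.allclose(
        map_.voxel_to_mm, labels.voxel_to_mm, atol=1e-6
    ):
        raise ValueError("grid mismatch between map and labels")
    present = np.unique(labels.labels)
    present = present[present != 0]
    if present.size == 0:
        raise ValueError("label volume contains no non-zero labels")
    rows = []
    for lbl in present:
        vals = map_.data[labels.labels == lbl]
        good = np.isfinite(vals)
        rows.append(
            {
                "roi": labels.label_names.get(int(lbl), str(int(lbl))),
                "label": int(lbl),
                "n_voxels": int(good.sum()),
                "value": float(vals[good].mean()) if good.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def roi_table_from_maps(
    maps: RatioMaps,
    labels: LabelVolume,
    subject: str,
    session: int,
    repeat: int,
    metrics: tuple[str, ...] = ("mtr", "emtr", "ihmtr", "ihmtr_inv"),
    roi_labels: set[int] | None = None,
) -> pd.DataFrame:
    """Long-format ROI table for one scan's ratio maps."""
    frames = []
    for metric in metrics:
        rm = roi_means(getattr(maps, metric), labels)
        if roi_labels is not None:
            rm = rm[rm["label"].isin(roi_labels)]
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "session": session,
                    "repeat": repeat,
                    "roi": rm["roi"],
                    "metric": metric,
                    "value": rm["value"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def cov_between(values: np.ndarray | pd.Series) -> float:
    """Between-subject CoV: sample SD (n-1) over mean, across all scans.

    Undefined (NaN) when the mean is non-positive or fewer than two
    values are given.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("cov_between needs at least 2 values")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def cov_within(table: pd.DataFrame, min_scans: int = 2) -> pd.DataFrame:
    """Average within-subject CoV per (roi, metric).

    For each subject the CoV of that subject's scan values is computed,
    then averaged (unweighted) over subjects.  Subjects with fewer than
    ``min_scans`` values are excluded with a warning.
    """
    out = []
    for (roi, metric), grp in table.groupby(["roi", "metric"], sort=False):
        covs = []
        for subject, sub in grp.groupby("subject"):
            vals = sub["value"].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < min_scans:
                warnings.warn(
                    f"subject {subject} excluded from within-subject CoV of "
                    f"{roi}/{metric}: only {vals.size} scan(s)",
                    stacklevel=2,
                )
                continue
            m = vals.mean()
            covs.append(vals.std(ddof=1) / m if m > 0 else np.nan)
        out.append(
            {"roi": roi, "metric": metric, "cov_within": float(np.nanmean(covs))}
        )
    return pd.DataFrame(out)


def cov_table(table: pd.DataFrame) -> pd.DataFrame:
    """Between- and within-subject CoV per (roi, metric) in one frame."""
    within = cov_within(table)
    between = (
        table.groupby(["roi", "metric"], sort=False)["value"]
        .apply(lambda v: cov_between(v.to_numpy()))
        .rename("cov_between")
        .reset_index()
    )
    return within.merge(between, on=["roi", "metric"])


def cov_map(stack: list[Volume3D], grouping: str = "between",
            subjects: list[str] | None = None) -> Volume3D:
    """Voxelwise CoV map over a stack of aligned volumes.

    ``grouping="between"`` applies sd/mean across all volumes;
    ``grouping="within"`` computes each subject's voxelwise CoV and
    averages over subjects (requires ``subjects`` giving the subject of
    each volume).  Voxels that are NaN in any input are NaN.
    """
    if len(stack) < 2:
        raise ValueError("cov_map needs at least 2 volumes")
    ref = stack[0]
    for v in stack[1:]:
        if not ref.same_grid(v):
            raise ValueError("grid mismatch in cov_map stack")
    data = np.stack([v.data for v in stack])

    def _cov(arr: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=1)
            out = sd / m
        out[~(m > 0)] = np.nan
        return out

    if grouping == "between":
        out = _cov(data)
    elif grouping == "within":
        if subjects is None or len(subjects) != len(stack):
            raise ValueError("grouping='within' needs one subject id per volume")
        subj = np.asarray(subjects)
        per_subject = []
        for s in np.unique(subj):
            idx = np.flatnonzero(subj == s)
            if idx.size < 2:
                warnings.warn(f"subject {s} excluded from within CoV map", stacklevel=2)
                continue
            per_subject.append(_cov(data[idx]))
        if not per_subject:
            raise ValueError("no subject has >= 2 volumes")
        out = np.mean(per_subject, axis=0)
    else:
        raise ValueError("grouping must be 'between' or 'within'")
    return Volume3D(out, ref.voxel_to_mm.copy())


def summarize_table(table: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Per-ROI group mean and SD of each metric, across all subjects.

    The mean pools all scans of all subjects; the SD is taken over the
    four scan-occasion group means (the spread of the across-subject
    mean between scan occasions).  With ``percent=True`` values are
    scaled by 100 to match conventional percentage reporting.
    """
    scale = 100.0 if percent else 1.0
    rows = []
    for (roi, metric), grp in table.groupby(["roi", "metric"], sort=False):
        occ = grp.groupby(["session", "repeat"])["value"].mean()
        rows.append(
            {
                "roi": roi,
                "metric": metric,
                "mean": scale * grp["value"].mean(),
                "sd": scale * occ.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format ROI CSV, validating schema and uniqueness."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table {path} lacks columns {missing}")
    key = ["subject", "session", "repeat", "roi", "metric"]
    if df.duplicated(key).any():
        raise ValueError(f"ROI table {path} has duplicate (scan, roi, metric) rows")
    return df[TABLE_COLUMNS]
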