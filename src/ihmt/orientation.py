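"""Head-orientation angle extraction and the angle x ROI mixed model.

The per-session head rotation is summarised by the angle between the
scanner Z axis (head-foot) of the native MT space and the atlas Z axis:
the three affine transforms (native -> T1, T1 -> study template,
template -> atlas) are concatenated, the linear part is applied to
Z = (0, 0, 1), and the angle is ``arccos`` of the normalised dot
product with Z.  Translation is ignored (direction vector) and the
transformed vector is normalised so shears/scalings cannot masquerade
as rotation.  The angle is unsigned.

The effect of head angle on a ratio metric is assessed with a linear
mixed model on the long ROI table:

* fixed effects: angle, ROI (sum-coded), angle x ROI, subject;
* random intercepts: subject x ROI, and scan (one per acquired volume
  set) — the scan intercept absorbs the scan-to-scan fluctuation that
  is shared by every ROI of one scan, without which the angle test is
  anticonservative;
* REML estimation; F-tests with Satterthwaite-type denominator df.

With sum-coded ROIs the angle coefficient is the ROI-averaged
within-subject slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reml import kr_adjusted_cov, reml_fit, satterthwaite_ftest
from .volumes import AffineTransform

__all__ = [
    "AngleModelResult",
    "concat_affines",
    "head_angle",
    "fit_angle_model",
    "summarize_angles",
]


@dataclass
class AngleModelResult:
    slope_angle: float      # metric units per degree (ROI-averaged)
    se_slope: float
    f_angle: float
    p_angle: float
    df_num_angle: float
    df_den_angle: float
    f_interaction: float
    p_interaction: float
    df_num_interaction: float
    df_den_interaction: float
    var_subject_roi: float
    var_scan: float
    var_resid: float
    n_obs: int


def concat_affines(chain: list[AffineTransform]) -> AffineTransform:
    """Compose a chain of transforms (first transform applied first).

    Adjacent named spaces must match; unnamed (empty) spaces are not
    checked.
    """
    if not chain:
        raise ValueError("empty transform chain")
    for a, b in zip(chain, chain[1:]):
        if a.to_space and b.from_space and a.to_space != b.from_space:
            raise ValueError(
                f"space mismatch in chain: '{a.to_space}' -> '{b.from_space}'"
            )
    m = np.eye(4)
    for t in chain:
        m = t.matrix @ m
    return AffineTransform(m, from_space=chain[0].from_space, to_space=chain[-1].to_space)


def head_angle(t: AffineTransform) -> float:
    """Angle in degrees between the transformed Z axis and Z.

    ``v = linear(t) @ (0, 0, 1)`` is normalised before the arccos, so
    the result is invariant to translation and uniform scaling and lies
    in [0, 180].
    """
    v = t.matrix[:3, 2]
    if np.linalg.norm(v) == 0:
        raise ValueError("transform maps Z to the zero vector")
    # atan2 form of arccos(v.Z/|v|): accurate near 0 and 180 degrees
    return math.degrees(math.atan2(math.hypot(v[0], v[1]), v[2]))


def summarize_angles(angles) -> tuple[float, float, float]:
    """(median, lower quartile, upper quartile) by linear interpolation."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("no angle records")
    q1, med, q3 = np.quantile(a, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def _sum_code(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding; last level is the reference."""
    levels = sorted(values.unique())
    ref = levels[-1]
    cols = np.zeros((len(values), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(values == lev, 1.0, np.where(values == ref, -1.0, 0.0))
    return cols, levels[:-1]


def _dummy_code(values: pd.Series) -> np.ndarray:
    levels = sorted(values.unique())
    cols = np.zeros((len(values), len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        cols[:, j] = (values == lev).astype(float)
    return cols


def _indicator(values: pd.Series) -> np.ndarray:
    levels = sorted(values.unique())
    z = np.zeros((len(values), len(levels)))
    for j, lev in enumerate(levels):
        z[:, j] = (values == lev).astype(float)
    return z


def fit_angle_model(
    table: pd.DataFrame,
    angles: pd.DataFrame,
    metric: str = "ihmtr_inv",
    exclude_subjects: tuple[str, ...] = (),
) -> AngleModelResult:
    """Fit the angle x ROI mixed model for one metric.

    Parameters
    ----------
    table
        Long ROI table with columns (subject, session, repeat, roi,
        metric, value).
    angles
        Per-session angles with columns (subject, session, angle_deg);
        the two repeats of a session share the session's angle.
    metric
        Which metric's rows to model.
    exclude_subjects
        Subjects dropped before fitting (e.g. outlier re-analysis).
    """
    df = table[table["metric"] == metric].copy()
    if exclude_subjects:
        df = df[~df["subject"].isin(exclude_subjects)]
    df = df.merge(angles, on=["subject", "session"], how="left", validate="m:1")
    if df["angle_deg"].isna().any():
        bad = df.loc[df["angle_deg"].isna(), ["subject", "session"]].drop_duplicates()
        raise ValueError(f"missing angle for sessions:\n{bad}")
    if df["roi"].nunique() < 2:
        raise ValueError("angle model needs at least 2 ROIs")
    df = df.dropna(subset=["value"]).reset_index(drop=True)

    y = df["value"].to_numpy(dtype=float)
    angle = df["angle_deg"].to_numpy(dtype=float)
    roi_cols, _ = _sum_code(df["roi"])
    subj_cols = _dummy_code(df["subject"])
    inter_cols = roi_cols * angle[:, None]

    X = np.column_stack([np.ones(len(y)), angle, roi_cols, inter_cols, subj_cols])
    idx_angle = 1
    idx_inter = np.arange(2 + roi_cols.shape[1], 2 + roi_cols.shape[1] + inter_cols.shape[1])

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient fixed-effect design: the angle term is aliased "
            "with the subject effects (e.g. a single angle per subject)"
        )

    z_subj_roi = _indicator(df["subject"].astype(str) + ":" + df["roi"].astype(str))
    z_scan = _indicator(
        df["subject"].astype(str) + ":" + df["session"].astype(str)
        + ":" + df["repeat"].astype(str)
    )
    fit = reml_fit(y, X, [z_subj_roi, z_scan])
    if not fit.converged:
        raise RuntimeError("angle mixed model did not converge")

    p = X.shape[1]
    l_angle = np.zeros((1, p)); l_angle[0, idx_angle] = 1.0
    l_inter = np.zeros((len(idx_inter), p))
    for r, c in enumerate(idx_inter):
        l_inter[r, c] = 1.0

    cov = kr_adjusted_cov(fit)
    f_a, dfn_a, dfd_a, p_a = satterthwaite_ftest(fit, l_angle, cov=cov)
    f_i, dfn_i, dfd_i, p_i = satterthwaite_ftest(fit, l_inter, cov=cov)

    return AngleModelResult(
        slope_angle=float(fit.beta[idx_angle]),
        se_slope=float(np.sqrt(cov[idx_angle, idx_angle])),
        f_angle=f_a,
        p_angle=p_a,
        df_num_angle=dfn_a,
        df_den_angle=dfd_a,
        f_interaction=f_i,
        p_interaction=p_i,
        df_num_interaction=dfn_i,
        df_den_interaction=dfd_i,
        var_subject_roi=float(fit.variances[0]),
        var_scan=float(fit.variances[1]),
        var_resid=float(fit.variances[2]),
        n_obs=fit.n_obs,
    )
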