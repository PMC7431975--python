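"""Synthetic ihMT study generator.

Builds a complete digital study with the statistical structure the
downstream analyses assume: an ellipsoidal head phantom (WM core, GM
shell, CSF ventricles, ten labelled WM ROI boxes), six weighted volumes
per scan obtained by algebraically inverting the ratio definitions for
tissue-wise ground truths, a subjects x sessions x repeats design with
additive subject and scan variance components, per-session head-rotation
angles with a linear angle effect on the dual-saturation ratio, Rician
noise, and ground-truth native-to-atlas transforms.

Two levels of simulation are provided:

* :func:`simulate_study` / :func:`iter_study` — full image-level
  simulation (volumes + transforms + truth table).
* :func:`simulate_roi_table` — a fast table-level emulation that draws
  ROI-mean signals directly (the ROI mean of i.i.d. voxel noise), used
  for replicate-study statistics where generating volumes would add
  nothing but runtime.

Determinism: every random draw is tied to the spec's master seed through
fixed per-scan substreams, so adding subjects never reshuffles the draws
of existing scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import WeightedVolumeSet
from .volumes import AffineTransform, LabelVolume, Volume3D, write_affine, write_labels, write_volume

__all__ = [
    "TissueTruth",
    "PhantomSpec",
    "ScanData",
    "StudyData",
    "DEFAULT_TISSUES",
    "DEFAULT_ROI_BOXES",
    "make_phantom",
    "signals_from_truth",
    "ratios_from_truth",
    "add_rician",
    "simulate_study",
    "iter_study",
    "simulate_roi_table",
    "simulate_icc_table",
    "write_study",
]

# Integer labels of the phantom compartments.
LABEL_WM, LABEL_GM, LABEL_CSF = 1, 2, 3
ROI_LABEL_START = 11


@dataclass(frozen=True)
class TissueTruth:
    """Ground-truth signal level and ratio values of one tissue class."""

    s0: float           # unsaturated signal, a.u.
    mtr: float          # single-sided MT ratio, fraction
    emtr: float         # dual-sided (enhanced) MT ratio, fraction
    mtasym: float       # MT asymmetry, fraction
    t1_factor: float    # ST1 / S0


# Ratio scales echo in-vivo reports: WM ihMTR ~ 0.12 and inverse ihMTR
# ~ 0.15, lower values in GM, and a CSF compartment whose dual-sided
# ratio sits slightly below the single-sided one so the small negative
# ihMTR seen in fluid is exercised.  Per-ROI dual-sided ratios ladder
# over the WM tract range (ihMTR ~ 0.105 .. 0.152).
DEFAULT_TISSUES: dict[str, TissueTruth] = {
    "wm": TissueTruth(100.0, 0.20, 0.260, 0.010, 0.37),
    "gm": TissueTruth(90.0, 0.17, 0.200, 0.008, 0.45),
    "csf": TissueTruth(120.0, 0.02, 0.015, -0.005, 0.85),
    "genu_cc": TissueTruth(100.0, 0.20, 0.254, 0.010, 0.37),
    "body_cc": TissueTruth(100.0, 0.20, 0.259, 0.010, 0.37),
    "splenium_cc": TissueTruth(100.0, 0.20, 0.2625, 0.010, 0.37),
    "corticospinal_tract": TissueTruth(100.0, 0.20, 0.276, 0.010, 0.37),
    "cerebral_peduncle": TissueTruth(100.0, 0.20, 0.2695, 0.010, 0.37),
    "internal_capsule": TissueTruth(100.0, 0.20, 0.2635, 0.010, 0.37),
    "corona_radiata": TissueTruth(100.0, 0.20, 0.2635, 0.010, 0.37),
    "thalamic_radiation": TissueTruth(100.0, 0.20, 0.261, 0.010, 0.37),
    "cingulum_cingulate": TissueTruth(100.0, 0.20, 0.254, 0.010, 0.37),
    "cingulum_hippocampus": TissueTruth(100.0, 0.20, 0.2525, 0.010, 0.37),
}

# ROI boxes as (center, half-extent) in fractions of the grid shape,
# relative to the grid centre.  All lie inside the WM ellipsoid and
# clear of the CSF ventricles (validated at build time).
DEFAULT_ROI_BOXES: dict[str, tuple[tuple[float, float, float], float]] = {
    "genu_cc": ((0.17, 0.0, 0.05), 0.035),
    "body_cc": ((-0.17, 0.0, 0.05), 0.035),
    "splenium_cc": ((0.0, 0.19, 0.05), 0.035),
    "corticospinal_tract": ((0.0, -0.19, 0.05), 0.035),
    "cerebral_peduncle": ((0.13, 0.13, -0.08), 0.035),
    "internal_capsule": ((-0.13, 0.13, -0.08), 0.035),
    "corona_radiata": ((0.13, -0.13, -0.08), 0.035),
    "thalamic_radiation": ((-0.13, -0.13, -0.08), 0.035),
    "cingulum_cingulate": ((0.0, 0.12, 0.17), 0.035),
    "cingulum_hippocampus": ((0.0, -0.12, 0.17), 0.035),
}

# Normalised semi-axes (fractions of the grid shape) of the phantom
# compartment ellipsoids.
_HEAD_SEMI = (0.45, 0.45, 0.42)
_WM_SEMI = (0.30, 0.30, 0.28)
_CSF_SEMI = (0.10, 0.14, 0.08)


@dataclass(frozen=True)
class PhantomSpec:
    """Definition of a synthetic repeatability study.

    The default design mirrors a 12-subject, two-session, two-repeat
    protocol (four scans per subject).  Variance components act
    additively on the dual-saturation ratio (eMTR) of the WM
    compartment and the ROI boxes; the head-angle effect is a linear
    decrement of the same quantity, homogeneous across ROIs.

    Attributes
    ----------
    sd_subject, sd_scan : float
        Standard deviations of the subject and per-scan random effects
        on eMTR (fraction units).
    noise_sigma : float
        Rician noise level in signal units (WM S0 defaults to 100, so
        ``noise_sigma=1`` is voxel SNR 100).
    angle_mean, angle_sd : float
        Head-rotation angle distribution (degrees, normal truncated
        at zero, shared by the two repeats of a session).
    angle_slope : float
        eMTR decrement per degree of head rotation.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 3.0
    tissue_truths: dict[str, TissueTruth] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    roi_boxes: dict[str, tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_BOXES)
    )
    n_subjects: int = 12
    n_sessions: int = 2
    n_repeats: int = 2
    sd_subject: float = 1.2e-3
    sd_scan: float = 4.0e-4
    noise_sigma: float = 1.0
    angle_mean: float = 7.0
    angle_sd: float = 5.0
    angle_slope: float = 1.2e-4
    rotate_grid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name, t in self.tissue_truths.items():
            for val in (t.mtr, t.emtr, t.mtasym):
                if not -1.0 < val < 1.0:
                    raise ValueError(f"tissue {name}: ratios must lie in (-1, 1)")
            if name != "csf" and t.emtr < t.mtr:
                raise ValueError(
                    f"tissue {name}: emtr < mtr would give negative ihMTR "
                    "(only the CSF compartment may do that)"
                )

    @property
    def roi_names(self) -> list[str]:
        return list(self.roi_boxes)

    @property
    def roi_labels(self) -> dict[int, str]:
        return {ROI_LABEL_START + i: name for i, name in enumerate(self.roi_boxes)}

    def subjects(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class ScanData:
    """One simulated scan: six volumes plus its ground-truth transform."""

    subject: str
    session: int
    repeat: int
    volumes: WeightedVolumeSet
    transform: AffineTransform  # native -> atlas
    angle: float                # degrees


@dataclass
class StudyData:
    labels: LabelVolume
    scans: list[ScanData]
    truth: pd.DataFrame


# ----------------------------------------------------------------- phantom


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spec.voxel_size
    aff[:3, 3] = -spec.voxel_size * (np.asarray(spec.grid_shape) - 1) / 2.0
    return aff


def _ellipsoid_mask(shape: tuple[int, int, int], semi_frac) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(semi_frac) * np.asarray(shape)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _roi_slices(spec: PhantomSpec) -> dict[str, tuple[slice, slice, slice]]:
    shape = np.asarray(spec.grid_shape)
    center = (shape - 1) / 2.0
    out = {}
    for name, (cfrac, half_frac) in spec.roi_boxes.items():
        c = center + np.asarray(cfrac) * shape
        half = max(1, int(round(half_frac * shape.min())))
        sl = tuple(
            slice(int(round(ci)) - half, int(round(ci)) + half + 1) for ci in c
        )
        out[name] = sl
    return out


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Build the labelled head phantom.

    Ellipsoidal head with a GM shell, WM core and central CSF
    ventricles; ten ROI boxes are carved into the WM compartment with
    labels 11..20.  Raises if ROI boxes overlap each other or leave the
    WM compartment.
    """
    shape = spec.grid_shape
    head = _ellipsoid_mask(shape, _HEAD_SEMI)
    wm = _ellipsoid_mask(shape, _WM_SEMI)
    csf = _ellipsoid_mask(shape, _CSF_SEMI)

    labels = np.zeros(shape, dtype=np.int16)
    labels[head] = LABEL_GM
    labels[wm] = LABEL_WM
    labels[csf] = LABEL_CSF

    claimed = np.zeros(shape, dtype=bool)
    slices = _roi_slices(spec)
    for label, name in spec.roi_labels.items():
        sl = slices[name]
        box = np.zeros(shape, dtype=bool)
        box[sl] = True
        if (box & claimed).any():
            raise ValueError(f"ROI box '{name}' overlaps another ROI box")
        if not np.all(labels[box] == LABEL_WM):
            raise ValueError(f"ROI box '{name}' leaves the WM compartment")
        labels[box] = label
        claimed |= box

    names = {LABEL_WM: "wm", LABEL_GM: "gm", LABEL_CSF: "csf", **spec.roi_labels}
    return LabelVolume(labels, _grid_affine(spec), names)


# ------------------------------------------------------------- truth maths


def signals_from_truth(
    s0: float, mtr: float, emtr: float, mtasym: float, t1_factor: float
) -> tuple[float, float, float, float, float, float]:
    """Invert the ratio definitions to the six noise-free signals.

    Returns ``(S0, S+, S-, S+/-, S-/+, ST1)``.  Raises on truths that
    would imply a non-positive signal.
    """
    splus = s0 * (1.0 - mtr + mtasym / 2.0)
    sminus = s0 * (1.0 - mtr - mtasym / 2.0)
    se = s0 * (1.0 - emtr)
    st1 = s0 * t1_factor
    sig = (s0, splus, sminus, se, se, st1)
    if min(sig) <= 0.0:
        raise ValueError(
            f"non-physical truth: signals {sig} from "
            f"(s0={s0}, mtr={mtr}, emtr={emtr}, mtasym={mtasym}, t1={t1_factor})"
        )
    return sig


def ratios_from_truth(t: TissueTruth) -> dict[str, float]:
    """Closed-form ratio values implied by one tissue truth."""
    s0, sp, sm, spm, smp, st1 = signals_from_truth(
        t.s0, t.mtr, t.emtr, t.mtasym, t.t1_factor
    )
    return {
        "mtr": t.mtr,
        "emtr": t.emtr,
        "mtasym": t.mtasym,
        "ihmtr": 2.0 * (t.emtr - t.mtr),
        "ihmtr_inv": 2.0 * st1 * (1.0 / spm + 1.0 / smp - 1.0 / sp - 1.0 / sm),
    }


def add_rician(v: Volume3D, sigma: float, seed: int | np.random.Generator) -> Volume3D:
    """Corrupt a volume with Rician noise of scale ``sigma``.

    Each voxel becomes ``sqrt((x + n1)^2 + n2^2)`` with independent
    ``n1, n2 ~ N(0, sigma^2)`` — the magnitude of complex Gaussian noise
    added to a real signal.  ``sigma=0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Volume3D(v.data.copy(), v.voxel_to_mm.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=v.data.shape)
    n2 = rng.normal(0.0, sigma, size=v.data.shape)
    return Volume3D(np.hypot(v.data + n1, n2), v.voxel_to_mm.copy())


def _rotation_x(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    m = np.eye(4)
    m[1, 1] = math.cos(th)
    m[1, 2] = -math.sin(th)
    m[2, 1] = math.sin(th)
    m[2, 2] = math.cos(th)
    return m


# --------------------------------------------------------- random streams
# Fixed salts keep subject / session / scan / table substreams disjoint.
_SALT_SUBJECT, _SALT_SESSION, _SALT_SCAN, _SALT_TABLE = 11, 23, 37, 53


def _subject_effect(spec: PhantomSpec, subj: int) -> float:
    rng = np.random.default_rng([spec.seed, _SALT_SUBJECT, subj])
    return rng.normal(0.0, spec.sd_subject)


def _session_angle(spec: PhantomSpec, subj: int, sess: int) -> float:
    rng = np.random.default_rng([spec.seed, _SALT_SESSION, subj, sess])
    if spec.angle_sd == 0:
        return max(0.0, spec.angle_mean)
    a = -spec.angle_mean / spec.angle_sd
    return float(
        stats.truncnorm.rvs(
            a, np.inf, loc=spec.angle_mean, scale=spec.angle_sd, random_state=rng
        )
    )


def _scan_effect(spec: PhantomSpec, subj: int, sess: int, rep: int) -> float:
    rng = np.random.default_rng([spec.seed, _SALT_SCAN, subj, sess, rep])
    return rng.normal(0.0, spec.sd_scan)


def _noise_rng(spec: PhantomSpec, subj: int, sess: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _SALT_SCAN, subj, sess, rep, 1])


def _adjusted_truths(
    spec: PhantomSpec, u: float, w: float, theta: float
) -> dict[str, TissueTruth]:
    """Apply subject/scan/angle effects to the WM-family eMTR values."""
    delta = u + w - spec.angle_slope * theta
    out = {}
    for name, t in spec.tissue_truths.items():
        if name in ("gm", "csf"):
            out[name] = t
        else:
            out[name] = replace(t, emtr=t.emtr + delta)
    return out


def _scan_truth_rows(
    spec: PhantomSpec, subject: str, sess: int, rep: int,
    truths: dict[str, TissueTruth], theta: float,
) -> list[dict]:
    rows = []
    for roi in spec.roi_names:
        vals = ratios_from_truth(truths[roi])
        rows.append(
            {
                "subject": subject,
                "session": sess,
                "repeat": rep,
                "roi": roi,
                "head_angle": theta,
                **{k: vals[k] for k in ("mtr", "emtr", "ihmtr", "ihmtr_inv")},
            }
        )
    return rows


def _scan_volumes(
    spec: PhantomSpec, labels: LabelVolume, truths: dict[str, TissueTruth],
    rng: np.random.Generator | None,
) -> WeightedVolumeSet:
    affine = labels.voxel_to_mm
    name_by_label = {0: None, **{lbl: nm for lbl, nm in labels.label_names.items()}}
    max_label = int(labels.labels.max())
    lut = np.zeros((max_label + 1, 6))
    for lbl, nm in name_by_label.items():
        if nm is None:
            continue
        lut[lbl] = signals_from_truth(
            truths[nm].s0, truths[nm].mtr, truths[nm].emtr,
            truths[nm].mtasym, truths[nm].t1_factor,
        )
    stack = lut[labels.labels]  # (..., 6)
    vols = []
    for c in range(6):
        v = Volume3D(stack[..., c].copy(), affine.copy())
        if rng is not None and spec.noise_sigma > 0:
            v = add_rician(v, spec.noise_sigma, rng)
        vols.append(v)
    return WeightedVolumeSet(*vols)


def iter_study(spec: PhantomSpec) -> Iterator[ScanData]:
    """Lazily yield the study's scans (memory stays one scan deep).

    With ``rotate_grid`` enabled, the phantom labels are rigidly rotated
    into each session's native orientation (nearest neighbour, about the
    head centre) before the signals are synthesised; by default only the
    emitted transform records the rotation.
    """
    from .volumes import Volume3D, resample_labels

    labels = make_phantom(spec)
    for si, subject in enumerate(spec.subjects()):
        u = _subject_effect(spec, si)
        for sess in range(1, spec.n_sessions + 1):
            theta = _session_angle(spec, si, sess)
            transform = AffineTransform(
                _rotation_x(-theta), from_space="native", to_space="atlas"
            )
            if spec.rotate_grid:
                target = Volume3D(
                    np.zeros(spec.grid_shape), labels.voxel_to_mm.copy()
                )
                scan_labels = resample_labels(labels, transform, target)
            else:
                scan_labels = labels
            for rep in range(1, spec.n_repeats + 1):
                w = _scan_effect(spec, si, sess, rep)
                truths = _adjusted_truths(spec, u, w, theta)
                rng = _noise_rng(spec, si, sess, rep) if spec.noise_sigma > 0 else None
                ws = _scan_volumes(spec, scan_labels, truths, rng)
                yield ScanData(subject, sess, rep, ws, transform, theta)


def study_truth_table(spec: PhantomSpec) -> pd.DataFrame:
    """Ground-truth ratio values and head angles for every scan and ROI."""
    rows = []
    for si, subject in enumerate(spec.subjects()):
        u = _subject_effect(spec, si)
        for sess in range(1, spec.n_sessions + 1):
            theta = _session_angle(spec, si, sess)
            for rep in range(1, spec.n_repeats + 1):
                w = _scan_effect(spec, si, sess, rep)
                truths = _adjusted_truths(spec, u, w, theta)
                rows.extend(_scan_truth_rows(spec, subject, sess, rep, truths, theta))
    return pd.DataFrame(rows)


def simulate_study(spec: PhantomSpec) -> StudyData:
    """Materialise the full study (volumes, transforms, truth table).

    Memory scales with ``n_scans x grid volume``; for replicate-study
    statistics prefer :func:`simulate_roi_table`, and for streaming to
    disk use :func:`iter_study` / :func:`write_study`.
    """
    labels = make_phantom(spec)
    scans = list(iter_study(spec))
    return StudyData(labels=labels, scans=scans, truth=study_truth_table(spec))


def write_study(spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write the study to ``out_dir`` in a BIDS-flavoured layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = make_phantom(spec)
    write_labels(labels, out / "labels.nii.gz")
    names = ("s0", "splus", "sminus", "spm", "smp", "st1")
    for scan in iter_study(spec):
        d = out / scan.subject / f"ses-{scan.session}" / f"run-{scan.repeat}"
        d.mkdir(parents=True, exist_ok=True)
        for name, vol in scan.volumes.volumes().items():
            write_volume(vol, d / f"{name}.nii.gz")
        write_affine(scan.transform, d / "native_to_atlas.txt")
    study_truth_table(spec).to_csv(out / "truth.csv", index=False)
    return out


# ----------------------------------------------------- table-level studies


def roi_voxel_counts(spec: PhantomSpec) -> dict[str, int]:
    """Voxel count of each ROI box on the spec's grid."""
    out = {}
    for name, sl in _roi_slices(spec).items():
        out[name] = int(np.prod([s.stop - s.start for s in sl]))
    return out


def simulate_roi_table(spec: PhantomSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a study's ROI-mean table without generating volumes.

    The ROI mean of a map computed from voxelwise i.i.d. noise is
    emulated by perturbing each ROI's mean signals with independent
    ``N(0, noise_sigma^2 / V)`` errors (V = ROI voxel count) and passing
    the perturbed signals through the ratio definitions.  At the SNR of
    the default spec the Rician bias is negligible, so Gaussian errors
    on the ROI-mean signals are an accurate surrogate.

    Returns ``(table, angles)`` — a long-format ROI table with columns
    (subject, session, repeat, roi, metric, value) and a per-session
    angle table (subject, session, angle_deg).
    """
    counts = roi_voxel_counts(spec)
    rows = []
    angle_rows = []
    for si, subject in enumerate(spec.subjects()):
        u = _subject_effect(spec, si)
        for sess in range(1, spec.n_sessions + 1):
            theta = _session_angle(spec, si, sess)
            angle_rows.append(
                {"subject": subject, "session": sess, "angle_deg": theta}
            )
            for rep in range(1, spec.n_repeats + 1):
                w = _scan_effect(spec, si, sess, rep)
                truths = _adjusted_truths(spec, u, w, theta)
                rng = np.random.default_rng(
                    [spec.seed, _SALT_TABLE, si, sess, rep]
                )
                for roi in spec.roi_names:
                    t = truths[roi]
                    sig = np.array(signals_from_truth(
                        t.s0, t.mtr, t.emtr, t.mtasym, t.t1_factor
                    ))
                    se_roi = spec.noise_sigma / math.sqrt(counts[roi])
                    s0, sp, sm, spm, smp, st1 = sig + rng.normal(0, se_roi, 6)
                    vals = {
                        "mtr": 1.0 - (sp + sm) / (2.0 * s0),
                        "emtr": 1.0 - (spm + smp) / (2.0 * s0),
                        "mtasym": (sp - sm) / s0,
                        "ihmtr": (sp + sm - spm - smp) / s0,
                        "ihmtr_inv": 2.0 * st1
                        * (1.0 / spm + 1.0 / smp - 1.0 / sp - 1.0 / sm),
                    }
                    for metric, value in vals.items():
                        rows.append(
                            {
                                "subject": subject,
                                "session": sess,
                                "repeat": rep,
                                "roi": roi,
                                "metric": metric,
                                "value": value,
                            }
                        )
    return pd.DataFrame(rows), pd.DataFrame(angle_rows)


def simulate_icc_table(
    n_subjects: int,
    n_scans: int,
    var_subject: float,
    var_scan: float,
    var_resid: float,
    mu: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one balanced two-way crossed dataset y_ij = mu + s_i + r_j + e_ij.

    Subject effects s_i and scan-occasion effects r_j (shared across
    subjects) are the classic ICC(2,1) generating model.  Returns an
    (n_subjects, n_scans) array.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = rng.normal(0.0, math.sqrt(var_subject), size=(n_subjects, 1))
    r = rng.normal(0.0, math.sqrt(var_scan), size=(1, n_scans))
    e = rng.normal(0.0, math.sqrt(var_resid), size=(n_subjects, n_scans))
    return mu + s + r + e
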