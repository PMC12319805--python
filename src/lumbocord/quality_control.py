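"""Run-level quality control: motion, scrubbing, exclusion, and tSNR.

Framewise displacement (FD) summarizes realignment parameters per volume
pair; runs with mean FD >= 0.5 mm are excluded.  DVARS (RMS intensity
change between consecutive volumes within the cord) feeds a boxplot rule
(above Q3 + 1.5 IQR) that flags outlier volumes for scrubbing; flagged
volumes become one-hot nuisance regressors in the GLM.  tSNR (temporal
mean over temporal SD) tracks signal quality through preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default run-exclusion threshold on mean FD (mm): runs kept iff below it.
FD_EXCLUSION_MM = 0.5

#: Rotations (degrees) are converted to arc length on a sphere of this radius.
ROTATION_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """Realignment parameters for one run.

    ``translations`` has shape ``(n_volumes, 3)`` in mm, or
    ``(n_volumes, n_slices, 3)`` for slice-wise realignment.  ``rotations``
    (degrees), if present, matches the leading shape of ``translations``.
    """

    translations: np.ndarray
    rotations: np.ndarray | None = None
    tr: float = 2.5

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        if self.translations.ndim == 2:
            self.translations = self.translations[:, None, :]
        if self.translations.ndim != 3 or self.translations.shape[-1] != 3:
            raise ValueError("translations must be (n_volumes[, n_slices], 3)")
        if self.rotations is not None:
            self.rotations = np.asarray(self.rotations, dtype=float)
            if self.rotations.ndim == 2:
                self.rotations = self.rotations[:, None, :]
            if self.rotations.shape != self.translations.shape:
                raise ValueError("rotations must match translations in shape")
        if not np.isfinite(self.translations).all():
            raise ValueError("motion parameters contain non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, tr: float = 2.5) -> "MotionTrace":
        """Build from a 6-column TSV-style table (trans_{x,y,z}, rot_{x,y,z})."""
        trans = df[["trans_x", "trans_y", "trans_z"]].to_numpy()
        rot = None
        if {"rot_x", "rot_y", "rot_z"}.issubset(df.columns):
            rot = df[["rot_x", "rot_y", "rot_z"]].to_numpy()
        return cls(translations=trans, rotations=rot, tr=tr)

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass
class QcReport:
    """Per-run quality metrics and the exclusion decision."""

    mean_fd: float
    fd_series: np.ndarray
    dvars_series: np.ndarray | None = None
    outlier_volumes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    tsnr_mean: float | None = None
    excluded: bool = False
    reason: str | None = None
    run_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "mean_fd": float(self.mean_fd),
            "fd_series": np.asarray(self.fd_series).tolist(),
            "dvars_series": None
            if self.dvars_series is None
            else np.asarray(self.dvars_series).tolist(),
            "outlier_volumes": np.asarray(self.outlier_volumes).tolist(),
            "tsnr_mean": None if self.tsnr_mean is None else float(self.tsnr_mean),
            "excluded": bool(self.excluded),
            "reason": self.reason,
        }


def framewise_displacement(
    trace: MotionTrace,
    rotation_radius_mm: float = ROTATION_RADIUS_MM,
    include_rotations: bool = True,
) -> tuple[np.ndarray, float]:
    """FD per volume pair (slice-averaged) and its temporal mean.

    Per slice and volume pair, FD is the sum of absolute backward
    differences of the three translations; when rotations are present (and
    ``include_rotations``), the absolute rotation differences are converted
    to mm as arc length at ``rotation_radius_mm`` and added.  The series is
    averaged over slices, then over time.
    """
    if trace.n_volumes < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    d = np.abs(np.diff(trace.translations, axis=0)).sum(axis=-1)  # (n-1, n_slices)
    if trace.rotations is not None and include_rotations:
        dr = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=-1)
        d = d + np.deg2rad(dr) * rotation_radius_mm
    fd_series = d.mean(axis=1)
    return fd_series, float(fd_series.mean())


def exclude_runs(
    reports: list[QcReport], fd_threshold: float = FD_EXCLUSION_MM
) -> tuple[list[QcReport], list[QcReport]]:
    """Partition runs into (kept, excluded) by the strict mean-FD rule.

    A run is kept iff ``mean_fd < fd_threshold`` (a run sitting exactly at
    the threshold is excluded).  Reports are flagged in place.
    """
    if fd_threshold <= 0:
        raise ValueError("fd_threshold must be positive")
    kept, excluded = [], []
    for r in reports:
        if r.mean_fd < fd_threshold:
            r.excluded = False
            kept.append(r)
        else:
            r.excluded = True
            r.reason = f"mean FD {r.mean_fd:.3g} mm >= {fd_threshold} mm"
            excluded.append(r)
    return kept, excluded


def dvars(volume4d: np.ndarray, cord_mask: np.ndarray) -> np.ndarray:
    """RMS intensity difference between consecutive volumes within the cord.

    Element ``t`` (t = 1..n-1) is the RMS over cord voxels of
    ``vol_t - vol_{t-1}``; computed on unsmoothed data.
    """
    cord_mask = np.asarray(cord_mask, dtype=bool)
    if not cord_mask.any():
        raise ValueError("cord mask is empty")
    if volume4d.shape[-1] < 2:
        raise ValueError("DVARS needs at least 2 volumes")
    ts = volume4d[cord_mask]  # (n_voxels, n_volumes)
    diff = np.diff(ts, axis=1)
    return np.sqrt(np.mean(diff**2, axis=0))


def scrub_outliers(dvars_series: np.ndarray) -> np.ndarray:
    """Volumes to scrub by the boxplot rule on DVARS.

    Flags series elements strictly above Q3 + 1.5 IQR, quartiles by linear
    interpolation between order statistics.  Returned indices are volume
    indices (series element t-1 corresponds to volume t), i.e. a subset of
    ``{1..n_volumes-1}``; they become one-hot nuisance regressors.
    """
    s = np.asarray(dvars_series, dtype=float)
    if s.size < 4:
        raise ValueError("DVARS series too short for the boxplot rule (need >= 4)")
    q1, q3 = np.quantile(s, [0.25, 0.75], method="linear")
    cutoff = q3 + 1.5 * (q3 - q1)
    return np.nonzero(s > cutoff)[0] + 1


def outlier_regressors(outlier_volumes: np.ndarray, n_volumes: int) -> pd.DataFrame:
    """One-hot nuisance regressors, one column per scrubbed volume."""
    cols = {}
    for v in np.asarray(outlier_volumes, dtype=int):
        col = np.zeros(n_volumes)
        col[v] = 1.0
        cols[f"outlier_{v:03d}"] = col
    return pd.DataFrame(cols, dtype=float)


def tsnr(
    volume4d: np.ndarray, mask: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, float]:
    """Temporal SNR map (mean / sample SD) and its mean over the mask.

    Zero-variance voxels get +inf and are excluded from the mask mean.
    """
    if volume4d.shape[-1] < 3:
        raise ValueError("tSNR needs at least 3 volumes")
    mask = np.asarray(mask, dtype=bool)
    mean = volume4d.mean(axis=-1)
    sd = volume4d.std(axis=-1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    vals = tmap[mask]
    finite = vals[np.isfinite(vals)]
    return tmap, float(finite.mean()) if finite.size else float("nan")


def qc_run(
    volume4d: np.ndarray,
    trace: MotionTrace,
    cord_mask: np.ndarray,
    fd_threshold: float = FD_EXCLUSION_MM,
    run_id: str | None = None,
) -> QcReport:
    """Full QC for one run: FD, DVARS scrubbing, tSNR, exclusion flag."""
    fd_series, mean_fd = framewise_displacement(trace)
    dv = dvars(volume4d, cord_mask)
    outliers = scrub_outliers(dv) if dv.size >= 4 else np.array([], dtype=int)
    _, tsnr_mean = tsnr(volume4d, cord_mask)
    report = QcReport(
        mean_fd=mean_fd,
        fd_series=fd_series,
        dvars_series=dv,
        outlier_volumes=outliers,
        tsnr_mean=tsnr_mean,
        run_id=run_id,
    )
    exclude_runs([report], fd_threshold)
    return report
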