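"""Block-design GLM for spinal cord BOLD runs, with fixed-effects pooling.

First level: per-voxel ordinary least squares of the run against a design
holding three task basis functions (canonical double-gamma response plus
temporal and dispersion derivatives, the derivatives orthogonalized against
the canonical column), polynomial drift, an intercept, and nuisance columns
(CSF principal components, motion parameters, outlier one-hots).  The
contrast of interest is the canonical-basis coefficient (COPE) with its
variance (VARCOPE); t statistics are converted to Z by matching cumulative
probabilities.

Second/third level: fixed-effects summation — cope_fe = sum(cope_i),
varcope_fe = sum(varcope_i), Z = cope_fe / sqrt(varcope_fe) — across runs
(second level) and across conditions (third level).

Thresholding: voxelwise Z > threshold, optionally with cluster-level
correction where the cluster-size null distribution is estimated by
sign-flip permutation of the run-level effects (a documented substitute for
Gaussian-random-field theory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import ndimage, stats
from scipy.ndimage import gaussian_filter, gaussian_filter1d, shift as nd_shift

from lumbocord.cord_geometry import ThresholdSpec
from lumbocord.hrf import convolve_blocks
from lumbocord.synthetic_data import Paradigm

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

TASK_COLUMNS = ("task", "task_tderiv", "task_ddisp")


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Named design matrix for one run.

    ``matrix`` is a DataFrame with ``n_volumes`` rows; ``task_columns``
    names the (up to three) task regressors, first the canonical one.
    """

    matrix: pd.DataFrame
    task_columns: tuple[str, ...] = TASK_COLUMNS

    @property
    def n_volumes(self) -> int:
        return len(self.matrix)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def contrast_vector(self, column: str) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        c[self.matrix.columns.get_loc(column)] = 1.0
        return c


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify offending columns via vanishing R diagonal of a QR pass
        _, R = np.linalg.qr(A)
        diag = np.abs(np.diag(R))
        tol = diag.max() * 1e-10 if diag.max() > 0 else 1e-10
        bad = [X.columns[i] for i in np.nonzero(diag < tol)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def build_design(
    paradigm: Paradigm,
    tr: float | None = None,
    n_volumes: int | None = None,
    nuisance: pd.DataFrame | None = None,
    drift_order: int = 2,
    hrf_peak_delay: float = 6.0,
    block_labels: set[str] | None = None,
) -> DesignMatrix:
    """Build the first-level design for one run.

    The task boxcar is convolved with the three-function basis; the
    derivative columns are then Gram-Schmidt orthogonalized against the
    canonical column.  All columns except the intercept are mean-centered.
    ``drift_order`` Legendre polynomials model slow drift.  ``nuisance``
    columns (CSF components, motion parameters, outlier one-hots) are
    appended mean-centered.  An empty paradigm yields an
    intercept-plus-drift-plus-nuisance design.
    """
    tr = paradigm.tr if tr is None else tr
    n_volumes = paradigm.n_volumes if n_volumes is None else n_volumes
    cols: dict[str, np.ndarray] = {}
    task_columns: tuple[str, ...] = ()

    blocks = [b for b in paradigm.blocks if block_labels is None or b[2] in block_labels]
    if blocks:
        reg = convolve_blocks(
            blocks, tr, n_volumes, peak_delay=hrf_peak_delay
        )
        reg = reg - reg.mean(axis=0)
        # orthogonalize derivatives against the canonical regressor
        c0 = reg[:, 0]
        for j in (1, 2):
            reg[:, j] -= c0 * (reg[:, j] @ c0) / (c0 @ c0)
        for j, name in enumerate(TASK_COLUMNS):
            cols[name] = reg[:, j]
        task_columns = TASK_COLUMNS

    cols["intercept"] = np.ones(n_volumes)
    if drift_order > 0:
        t = np.linspace(-1.0, 1.0, n_volumes)
        for k in range(1, drift_order + 1):
            coef = np.zeros(k + 1)
            coef[k] = 1.0
            col = legendre.legval(t, coef)
            cols[f"drift_{k}"] = col - col.mean()

    if nuisance is not None:
        if len(nuisance) != n_volumes:
            raise ValueError("nuisance table length must equal n_volumes")
        for name in nuisance.columns:
            col = nuisance[name].to_numpy(dtype=float)
            cols[str(name)] = col - col.mean()

    X = pd.DataFrame(cols)
    _check_rank(X)
    return DesignMatrix(matrix=X, task_columns=task_columns)


def acompcor(
    volume4d: np.ndarray, csf_mask: np.ndarray, n_components: int = 5
) -> pd.DataFrame:
    """CSF component-based nuisance regressors (aCompCor).

    Principal-component time courses of the CSF voxel-by-time matrix
    (each voxel time series mean-centered), variance-ranked, unit-norm.
    Computed on unsmoothed data.
    """
    csf_mask = np.asarray(csf_mask, dtype=bool)
    if not csf_mask.any():
        raise ValueError("CSF mask is empty")
    X = volume4d[csf_mask].T.astype(float)  # (n_volumes, n_voxels)
    X = X - X.mean(axis=0, keepdims=True)
    rank = min(X.shape)
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but the CSF matrix has rank "
            f"at most {rank}"
        )
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if np.linalg.matrix_rank(np.diag(s)) < n_components:
        raise ValueError("CSF matrix rank is below the requested component count")
    comps = U[:, :n_components]
    return pd.DataFrame(
        comps, columns=[f"csf_pc{i + 1}" for i in range(n_components)]
    )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


@dataclass
class EffectMap:
    """COPE/VARCOPE volumes with degrees of freedom and provenance."""

    cope: np.ndarray
    varcope: np.ndarray
    dof: int
    analysis_level: int = 1
    mask: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)


@dataclass
class StatMap:
    """A Z volume with its thresholding state."""

    z: np.ndarray
    threshold_spec: ThresholdSpec | None = None
    corrected: bool = False
    analysis_level: int = 1
    active_mask: np.ndarray | None = None
    cluster_pvalues: list[float] | None = None


def _isf_from_logp(logp: np.ndarray) -> np.ndarray:
    # Asymptotic inversion of the normal survival function from log p:
    # log Q(z) ~ -z^2/2 - log z - log sqrt(2*pi); two fixed-point passes.
    z = np.sqrt(np.maximum(-2.0 * logp, 1e-12))
    for _ in range(3):
        z = np.sqrt(np.maximum(-2.0 * (logp + np.log(z) + 0.5 * np.log(2 * np.pi)), 1e-12))
    return z


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Convert t statistics to Z by matching one-sided tail probabilities.

    For extreme |t| where the tail probability underflows, an asymptotic
    inversion of the normal survival function from log p is used.
    """
    t = np.asarray(t, dtype=float)
    logp = stats.t.logsf(np.abs(t), dof)
    finite = np.isfinite(logp)
    safe_logp = np.where(finite, logp, -1.0)
    small = safe_logp < np.log(1e-290)
    p = np.exp(np.where(small, np.log(0.5), safe_logp))  # placeholder where underflowing
    z = stats.norm.isf(p)
    z = np.where(small, _isf_from_logp(np.where(small, safe_logp, -1.0)), z)
    # where even log p underflows, |t| bounds the normal quantile from above
    z = np.where(finite, z, np.abs(t))
    return np.sign(t) * z


def first_level(
    volume4d: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    contrast: str = "task",
) -> tuple[EffectMap, np.ndarray]:
    """Per-voxel OLS fit of one run; returns the effect map and a Z volume.

    The contrast selects a single design column (default the canonical task
    regressor).  Voxels outside the mask are zero in every output.
    """
    mask = np.asarray(mask, dtype=bool)
    X = design.values
    n, p = X.shape
    if volume4d.shape[-1] != n:
        raise ValueError(
            f"data has {volume4d.shape[-1]} volumes but design has {n} rows"
        )
    dof = n - np.linalg.matrix_rank(X)
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    c = design.contrast_vector(contrast)

    Y = volume4d[mask].T.astype(float)  # (n_volumes, n_voxels)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = pinv @ pinv.T
    cvar = float(c @ xtx_inv @ c)

    cope_v = c @ beta
    varcope_v = sigma2 * cvar
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(varcope_v > 0, cope_v / np.sqrt(np.where(varcope_v > 0, varcope_v, 1.0)), 0.0)
    z_v = t_to_z(t, dof)

    shape = volume4d.shape[:3]
    cope = np.zeros(shape)
    varcope = np.zeros(shape)
    z = np.zeros(shape)
    cope[mask] = cope_v
    varcope[mask] = varcope_v
    z[mask] = z_v
    effect = EffectMap(cope=cope, varcope=varcope, dof=int(dof), analysis_level=1, mask=mask)
    return effect, z


def fixed_effects(effect_maps: list[EffectMap]) -> tuple[EffectMap, np.ndarray]:
    """Fixed-effects combination to the next analysis level.

    cope_fe = sum(cope_i); varcope_fe = sum(varcope_i);
    Z = cope_fe / sqrt(varcope_fe).  (This is the unweighted fixed-effects
    convention: with identical inputs Z scales as sqrt(k).)
    """
    if not effect_maps:
        raise ValueError("fixed_effects needs at least one effect map")
    shape = effect_maps[0].cope.shape
    for em in effect_maps[1:]:
        if em.cope.shape != shape:
            raise ValueError("effect maps lie on different grids")
    cope = np.sum([em.cope for em in effect_maps], axis=0)
    varcope = np.sum([em.varcope for em in effect_maps], axis=0)
    mask = None
    if all(em.mask is not None for em in effect_maps):
        mask = np.logical_and.reduce([em.mask for em in effect_maps])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(varcope > 0, cope / np.sqrt(np.where(varcope > 0, varcope, 1.0)), 0.0)
    out = EffectMap(
        cope=cope,
        varcope=varcope,
        dof=int(sum(em.dof for em in effect_maps)),
        analysis_level=max(em.analysis_level for em in effect_maps) + 1,
        mask=mask,
        provenance=[p for em in effect_maps for p in em.provenance],
    )
    return out, z


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def _cluster_sizes(active: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(active, structure=_STRUCT_26)
    return labels, n


def threshold_map(
    z_map: np.ndarray,
    spec: ThresholdSpec,
    mask: np.ndarray | None = None,
    analysis_level: int = 1,
    run_effects: list[EffectMap] | None = None,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> StatMap:
    """Threshold a Z volume, optionally with cluster-level correction.

    Uncorrected: active = z > z_threshold (within ``mask`` if given).
    Cluster correction: clusters are 26-connected components of the
    suprathreshold mask; the max-cluster-size null distribution is built by
    sign-flip permutation of the ``run_effects`` (each permutation flips
    the sign of whole runs' COPEs, recombines by fixed effects and
    rethresholds); clusters with permutation p >= cluster_p are removed.
    """
    z = np.asarray(z_map, dtype=float)
    restrict = np.ones(z.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    active = (z > spec.z_threshold) & restrict

    if spec.correction == "none":
        return StatMap(
            z=z,
            threshold_spec=spec,
            corrected=False,
            analysis_level=analysis_level,
            active_mask=active,
        )

    if not run_effects:
        raise ValueError(
            "cluster correction requires run-level effect maps for the "
            "sign-flip permutation null"
        )
    labels, n_clusters = _cluster_sizes(active)
    if n_clusters == 0:
        return StatMap(
            z=z,
            threshold_spec=spec,
            corrected=True,
            analysis_level=analysis_level,
            active_mask=active,
            cluster_pvalues=[],
        )
    sizes = ndimage.sum_labels(active, labels, index=np.arange(1, n_clusters + 1))

    rng = np.random.default_rng(seed)
    copes = np.stack([em.cope for em in run_effects])
    varsum = np.sum([em.varcope for em in run_effects], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sd = np.where(varsum > 0, 1.0 / np.sqrt(np.where(varsum > 0, varsum, 1.0)), 0.0)
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=len(run_effects))
        z_perm = np.tensordot(signs, copes, axes=1) * inv_sd
        act = (z_perm > spec.z_threshold) & restrict
        lab, npc = _cluster_sizes(act)
        if npc == 0:
            null_max[i] = 0
        else:
            null_max[i] = ndimage.sum_labels(act, lab, index=np.arange(1, npc + 1)).max()

    pvals = [
        float((1 + np.sum(null_max >= s)) / (n_permutations + 1)) for s in sizes
    ]
    keep = np.zeros_like(active)
    for ci, p in enumerate(pvals, start=1):
        if p < spec.cluster_p:
            keep |= labels == ci
    return StatMap(
        z=z,
        threshold_spec=spec,
        corrected=True,
        analysis_level=analysis_level,
        active_mask=keep,
        cluster_pvalues=pvals,
    )


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth_along_cord(
    volume: np.ndarray,
    centerline: np.ndarray,
    voxel_size: tuple[float, float, float],
    fwhm_mm: tuple[float, float, float] = (2.0, 2.0, 6.0),
) -> np.ndarray:
    """Anisotropic Gaussian smoothing in cord-aligned coordinates.

    Each slice is shifted so the centerline is straight, the volume is
    smoothed with an anisotropic Gaussian (in-plane FWHM then along-z
    FWHM), and the slices are shifted back.  Works on 3D volumes or 4D
    runs (last axis time).
    """
    if volume.ndim == 4:
        out = np.empty_like(volume, dtype=float)
        for t in range(volume.shape[-1]):
            out[..., t] = smooth_along_cord(volume[..., t], centerline, voxel_size, fwhm_mm)
        return out
    sigma_vox = tuple(
        f / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for f, v in zip(fwhm_mm, voxel_size)
    )
    ref = centerline.mean(axis=0)
    offsets = ref[None, :] - centerline  # shift to align each slice to ref
    straight = np.empty_like(volume, dtype=float)
    for zi in range(volume.shape[2]):
        straight[:, :, zi] = nd_shift(
            volume[:, :, zi], offsets[zi], order=1, mode="nearest"
        )
    straight = gaussian_filter(straight, sigma=(sigma_vox[0], sigma_vox[1], 0.0))
    straight = gaussian_filter1d(straight, sigma=sigma_vox[2], axis=2, mode="nearest")
    out = np.empty_like(straight)
    for zi in range(volume.shape[2]):
        out[:, :, zi] = nd_shift(
            straight[:, :, zi], -offsets[zi], order=1, mode="nearest"
        )
    return out
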