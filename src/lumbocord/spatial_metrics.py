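"""Laterality and rostrocaudal distribution of activation patterns.

Left-right and dorsal-ventral laterality indices are normalized voxel-count
asymmetries over hemicords: LR = (n_left - n_right) / (n_left + n_right)
and DV = (n_dorsal - n_ventral) / (n_dorsal + n_ventral), so +1 means all
active voxels are in the left (resp. dorsal) hemicord and -1 all in the
right (resp. ventral) hemicord.

The segmental distribution counts active voxels per spinal level, labels a
level 'active' when it holds over 30% of the significant voxels, divides
counts by a size-correction factor (level volume over the mean level
volume) so unequal segment volumes do not drive the profile, and normalizes
the corrected counts to sum to 1.  Group histograms sum the corrected
counts of active levels across participants before renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lumbocord.cord_geometry import LEVEL_NAMES, HemicordPartition, LevelMap


@dataclass
class LateralityResult:
    """Hemicord voxel counts and the derived LR/DV indices.

    Indices are ``None`` (reported as missing, not zero) when the
    corresponding denominator is zero — an empty map has no laterality.
    """

    n_left: int
    n_right: int
    n_dorsal: int
    n_ventral: int
    lr_index: float | None
    dv_index: float | None
    region: str = "full"


@dataclass
class SegmentalDistribution:
    """Size-corrected per-level activity fractions and active-level flags."""

    raw_counts: dict[str, int]
    correction_factors: dict[str, float]
    corrected_counts: dict[str, float]
    normalized: dict[str, float] | None
    active_levels: list[str] = field(default_factory=list)
    active_fraction_threshold: float = 0.30


def _active_mask(statmap_or_mask) -> np.ndarray:
    m = getattr(statmap_or_mask, "active_mask", statmap_or_mask)
    if m is None:
        raise ValueError("stat map has no active mask (threshold it first)")
    return np.asarray(m, dtype=bool)


def laterality_indices(
    statmap_or_mask,
    partition: HemicordPartition,
    region: np.ndarray | str = "full",
) -> LateralityResult:
    """LR and DV laterality of an active mask within a region.

    ``region`` is ``"full"`` (the whole partition) or a boolean mask (for
    example one spinal level).  Counts are taken over
    ``active & hemicord & region``.
    """
    active = _active_mask(statmap_or_mask)
    if isinstance(region, str):
        if region != "full":
            raise ValueError(f"unknown region {region!r}")
        region_mask = partition.cord_mask
        region_name = "full"
    else:
        region_mask = np.asarray(region, dtype=bool)
        region_name = "custom"
    if not region_mask.any():
        raise ValueError("region mask is empty")
    counts = partition.counts(active & region_mask)
    nl, nr = counts["left"], counts["right"]
    nd, nv = counts["dorsal"], counts["ventral"]
    lr = (nl - nr) / (nl + nr) if (nl + nr) > 0 else None
    dv = (nd - nv) / (nd + nv) if (nd + nv) > 0 else None
    return LateralityResult(
        n_left=nl,
        n_right=nr,
        n_dorsal=nd,
        n_ventral=nv,
        lr_index=lr,
        dv_index=dv,
        region=region_name,
    )


def per_level_laterality(
    statmap_or_mask, partition: HemicordPartition, level_map: LevelMap
) -> dict[str, LateralityResult]:
    """Laterality indices restricted to each spinal level's mask."""
    out = {}
    for lvl in level_map.levels():
        res = laterality_indices(
            statmap_or_mask, partition, region=level_map.maps[lvl].astype(bool)
        )
        res.region = lvl
        out[lvl] = res
    return out


def segmental_distribution(
    statmap_or_mask,
    level_map: LevelMap,
    active_fraction_threshold: float = 0.30,
) -> SegmentalDistribution:
    """Size-corrected rostrocaudal distribution of active voxels.

    Per level: raw count of active voxels; correction factor = level voxel
    count / mean level voxel count; corrected = raw / factor; normalized =
    corrected / sum(corrected).  A level is labeled active when its *raw*
    share of all significant voxels exceeds ``active_fraction_threshold``
    (the 30% rule is applied before size correction).
    """
    if level_map.kind != "binary":
        raise ValueError("segmental distribution requires a binary LevelMap")
    active = _active_mask(statmap_or_mask)
    if active.shape != level_map.grid_shape:
        raise ValueError(
            f"stat map grid {active.shape} does not match level map grid "
            f"{level_map.grid_shape}"
        )
    levels = level_map.levels()
    volumes = {lvl: int(np.count_nonzero(level_map.maps[lvl])) for lvl in levels}
    mean_vol = float(np.mean(list(volumes.values())))
    factors = {lvl: volumes[lvl] / mean_vol for lvl in levels}
    raw = {
        lvl: int(np.count_nonzero(active & level_map.maps[lvl].astype(bool)))
        for lvl in levels
    }
    total_raw = sum(raw.values())
    corrected = {
        lvl: (raw[lvl] / factors[lvl]) if factors[lvl] > 0 else 0.0 for lvl in levels
    }
    total_corr = sum(corrected.values())
    normalized = (
        {lvl: corrected[lvl] / total_corr for lvl in levels} if total_corr > 0 else None
    )
    active_levels = [
        lvl
        for lvl in levels
        if total_raw > 0 and raw[lvl] / total_raw > active_fraction_threshold
    ]
    return SegmentalDistribution(
        raw_counts=raw,
        correction_factors=factors,
        corrected_counts=corrected,
        normalized=normalized,
        active_levels=active_levels,
        active_fraction_threshold=active_fraction_threshold,
    )


def group_distribution(
    distributions: list[SegmentalDistribution],
) -> SegmentalDistribution:
    """Group histogram: corrected active-level counts summed, renormalized.

    Each participant contributes the size-corrected counts of the levels
    labeled active; the summed histogram is normalized to sum to 1.
    """
    if not distributions:
        raise ValueError("need at least one participant distribution")
    level_sets = {tuple(d.raw_counts) for d in distributions}
    if len(level_sets) > 1:
        raise ValueError("participant distributions cover different level sets")
    levels = list(distributions[0].raw_counts)
    summed = {lvl: 0.0 for lvl in levels}
    for d in distributions:
        for lvl in d.active_levels:
            summed[lvl] += d.corrected_counts[lvl]
    total = sum(summed.values())
    normalized = {lvl: summed[lvl] / total for lvl in levels} if total > 0 else None
    return SegmentalDistribution(
        raw_counts={lvl: 0 for lvl in levels},
        correction_factors={lvl: 1.0 for lvl in levels},
        corrected_counts=summed,
        normalized=normalized,
        active_levels=[lvl for lvl in levels if summed[lvl] > 0],
        active_fraction_threshold=distributions[0].active_fraction_threshold,
    )


def compare_to_expected(
    distribution: SegmentalDistribution, expected_range: tuple[str, str]
) -> float:
    """Fraction of normalized activity mass inside an expected level range.

    ``expected_range`` is an inclusive (rostral, caudal) pair, e.g.
    ``("L4", "S1")`` for tibialis anterior.
    """
    rostral, caudal = expected_range
    i0, i1 = LEVEL_NAMES.index(rostral), LEVEL_NAMES.index(caudal)
    if i0 > i1:
        raise ValueError(f"range {expected_range} is not rostral-to-caudal")
    if distribution.normalized is None:
        raise ValueError("distribution has no activity mass")
    in_range = set(LEVEL_NAMES[i0 : i1 + 1])
    return float(
        sum(v for lvl, v in distribution.normalized.items() if lvl in in_range)
    )


def laterality_group_test(
    indices: dict[str, np.ndarray],
    alternative: str = "less",
    alpha: float = 0.05,
) -> dict[str, dict[str, float]]:
    """One-sided one-sample t-tests on laterality indices, BH-corrected.

    ``indices`` maps a region label (e.g. 'full', 'L4') to participant index
    values; each group is tested against zero (``alternative='less'`` tests
    for right-lateralized, i.e. negative LR, activity).  P-values are
    corrected for false discovery rate across regions (Benjamini-Hochberg).
    """
    regions = list(indices)
    pvals, tvals, means = [], [], []
    for r in regions:
        vals = np.asarray(indices[r], dtype=float)
        vals = vals[np.isfinite(vals)]
        t, p = stats.ttest_1samp(vals, 0.0, alternative=alternative)
        pvals.append(p)
        tvals.append(t)
        means.append(vals.mean() if vals.size else np.nan)
    reject, p_fdr, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return {
        r: {
            "mean": float(means[i]),
            "t": float(tvals[i]),
            "p": float(pvals[i]),
            "p_fdr": float(p_fdr[i]),
            "significant": bool(reject[i]),
        }
        for i, r in enumerate(regions)
    }
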