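"""Spinal-level geometry in the lumbosacral cord.

The lumbosacral cord comprises seven segmental levels (L1-L5, S1, S2) whose
rostrocaudal extents vary across individuals and are shifted relative to the
vertebral bodies.  This module delimits personalized levels from root entry
zone (REZ) annotations, splits the cord cross-section into hemicords
(left/right and dorsal/ventral), and converts probabilistic level maps into
non-overlapping, z-contiguous binary label maps suitable for segmental
activity analysis.

Conventions
-----------
Volumes are RAS+: +x points right, +y anterior (ventral), +z superior
(rostral).  Slice intervals are 0-based and half-open ``[lo, hi)``.  A voxel
whose in-plane coordinate equals the centerline coordinate is assigned to
the *right* hemicord (left/right split) and to the *ventral* hemicord
(dorsal/ventral split); this tie rule is fixed so counts are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

#: Lumbosacral segmental levels, rostral to caudal.
LEVEL_NAMES: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5", "S1", "S2")

#: Nerve roots whose entry zones flank the L1-S2 levels, rostral to caudal.
ROOT_NAMES: tuple[str, ...] = ("T12", "L1", "L2", "L3", "L4", "L5", "S1", "S2", "S3")

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RezAnnotation:
    """Rostrocaudal coordinates of the root entry zones T12..S3.

    Parameters
    ----------
    entries
        Mapping root name -> z coordinate, containing all of
        :data:`ROOT_NAMES`.  Under RAS+ the rostral-most root (T12) has the
        largest z; coordinates must be strictly decreasing caudally.
    units
        ``"mm"`` or ``"slice"``.  Internal level computation is in mm; slice
        units require ``slice_thickness_mm``.
    slice_thickness_mm
        Conversion factor when ``units == "slice"``.
    """

    entries: Mapping[str, float]
    units: str = "mm"
    slice_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        missing = [r for r in ROOT_NAMES if r not in self.entries]
        if missing:
            raise ValueError(f"REZ annotation is missing roots: {missing}")
        if self.units not in ("mm", "slice"):
            raise ValueError(f"unknown REZ units {self.units!r}")
        if self.units == "slice" and self.slice_thickness_mm is None:
            raise ValueError("slice units require slice_thickness_mm")
        z = self.z_mm()
        if not np.all(np.diff(z) < 0):
            raise ValueError(
                "REZ z coordinates must decrease strictly from T12 to S3 "
                "(rostral = larger z under RAS+)"
            )

    def z_mm(self) -> np.ndarray:
        """Root z coordinates in mm, ordered T12..S3."""
        z = np.array([float(self.entries[r]) for r in ROOT_NAMES])
        if self.units == "slice":
            z = z * float(self.slice_thickness_mm)
        return z


@dataclass
class LevelMap:
    """Per-level 3D maps for L1..S2, probabilistic or binary.

    ``maps`` holds one volume per level present.  Probabilistic values lie
    in [0, 1]; binary maps are pairwise disjoint and each forms a single
    z-contiguous block filling the in-plane cord extent.
    """

    kind: str  # "probabilistic" | "binary"
    maps: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("probabilistic", "binary"):
            raise ValueError(f"unknown LevelMap kind {self.kind!r}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"level maps have inconsistent shapes: {shapes}")
        if self.kind == "probabilistic":
            for name, m in self.maps.items():
                if m.min() < 0 or m.max() > 1:
                    raise ValueError(f"probabilities for {name} outside [0, 1]")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.maps.values())).shape

    def levels(self) -> list[str]:
        """Levels present, in rostral-to-caudal order."""
        return [lvl for lvl in LEVEL_NAMES if lvl in self.maps]

    def to_label_volume(self) -> np.ndarray:
        """Binary maps as one integer volume, codes 1..7 = L1..S2 (0 = none)."""
        if self.kind != "binary":
            raise ValueError("label volume requires a binary LevelMap")
        out = np.zeros(self.grid_shape, dtype=np.int16)
        for code, lvl in enumerate(LEVEL_NAMES, start=1):
            if lvl in self.maps:
                out[self.maps[lvl].astype(bool)] = code
        return out

    @classmethod
    def from_label_volume(
        cls, labels: np.ndarray, voxel_size: tuple[float, float, float] | None = None
    ) -> "LevelMap":
        maps = {}
        for code, lvl in enumerate(LEVEL_NAMES, start=1):
            m = labels == code
            if m.any():
                maps[lvl] = m
        return cls(kind="binary", maps=maps, voxel_size=voxel_size)


@dataclass
class HemicordPartition:
    """Four binary masks splitting the cord left/right and dorsal/ventral.

    left/right and dorsal/ventral each partition the cord mask exactly.
    The tie rule (centerline voxels -> right, ventral) is recorded in
    ``meta``.
    """

    left: np.ndarray
    right: np.ndarray
    dorsal: np.ndarray
    ventral: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def cord_mask(self) -> np.ndarray:
        return self.left | self.right

    def counts(self, mask: np.ndarray) -> dict[str, int]:
        """Voxel counts of ``mask`` within each hemicord."""
        return {
            "left": int(np.count_nonzero(mask & self.left)),
            "right": int(np.count_nonzero(mask & self.right)),
            "dorsal": int(np.count_nonzero(mask & self.dorsal)),
            "ventral": int(np.count_nonzero(mask & self.ventral)),
        }


@dataclass
class ThresholdSpec:
    """Voxelwise Z threshold with optional cluster-level correction."""

    z_threshold: float = 2.3
    correction: str = "none"  # "none" | "cluster"
    cluster_p: float | None = None

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.correction not in ("none", "cluster"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.correction == "cluster":
            if self.cluster_p is None or not (0 < self.cluster_p < 1):
                raise ValueError("cluster correction requires cluster_p in (0, 1)")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def levels_from_rez(rez: RezAnnotation) -> dict[str, tuple[float, float]]:
    """Delimit levels L1..S2 from root-entry-zone coordinates.

    The boundary between consecutive levels is placed at the rostrocaudal
    midpoint of the two flanking REZ coordinates; level ``Lk`` spans the
    half-open interval ``(mid(REZ_{k-1}, REZ_k), mid(REZ_k, REZ_{k+1})]``
    (caudal-exclusive, rostral-inclusive in z, mm).

    Returns
    -------
    dict
        Ordered (rostral to caudal) mapping level -> ``(z_caudal, z_rostral)``
        with the convention that the level occupies ``(z_caudal, z_rostral]``.
    """
    z = rez.z_mm()
    mids = (z[:-1] + z[1:]) / 2.0  # one boundary per consecutive root pair
    out: dict[str, tuple[float, float]] = {}
    for i, lvl in enumerate(LEVEL_NAMES):
        rostral = mids[i]
        caudal = mids[i + 1]
        out[lvl] = (float(caudal), float(rostral))
    return out


def hemicord_partition(
    cord_mask: np.ndarray, centerline: np.ndarray
) -> HemicordPartition:
    """Split the cord into left/right and dorsal/ventral hemicords.

    Parameters
    ----------
    cord_mask
        Boolean 3D volume in RAS+ orientation.
    centerline
        Array ``(nz, 2)`` of per-slice in-plane centerline coordinates
        ``(x, y)`` in voxels; must be finite for every slice intersecting
        the cord.

    Voxels with ``x >= cx`` go right (+x = right), ``x < cx`` left; voxels
    with ``y >= cy`` go ventral (+y = anterior = ventral), ``y < cy``
    dorsal.
    """
    cord_mask = np.asarray(cord_mask, dtype=bool)
    if not cord_mask.any():
        raise ValueError("cord mask is empty")
    centerline = np.asarray(centerline, dtype=float)
    nz = cord_mask.shape[2]
    if centerline.shape != (nz, 2):
        raise ValueError(f"centerline must have shape ({nz}, 2), got {centerline.shape}")
    cord_slices = np.unique(np.nonzero(cord_mask)[2])
    if not np.all(np.isfinite(centerline[cord_slices])):
        raise ValueError("centerline undefined for a slice intersecting the cord")

    xi = np.arange(cord_mask.shape[0])[:, None, None]
    yi = np.arange(cord_mask.shape[1])[None, :, None]
    cx = centerline[:, 0][None, None, :]
    cy = centerline[:, 1][None, None, :]
    right = cord_mask & (xi >= cx)
    left = cord_mask & (xi < cx)
    ventral = cord_mask & (yi >= cy)
    dorsal = cord_mask & (yi < cy)
    return HemicordPartition(
        left=left,
        right=right,
        dorsal=dorsal,
        ventral=ventral,
        meta={"tie_rule": "centerline voxels assigned right (LR) and ventral (DV)"},
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _level_z_interval(mask: np.ndarray) -> tuple[int, int]:
    zs = np.nonzero(mask.any(axis=(0, 1)))[0]
    return int(zs.min()), int(zs.max()) + 1


def binarize_prob_levels(
    prob: LevelMap,
    threshold: float = 0.6,
    cord_mask: np.ndarray | None = None,
    on_empty: str = "error",
) -> LevelMap:
    """Convert probabilistic level maps into contiguous binary label maps.

    Per level: threshold the probability map, keep the largest 26-connected
    component, fill holes in 3D, then dilate in-plane (x, y only) to the
    full cord cross-section — each level then occupies a block of whole cord
    slices.  Between adjacent levels, any z-overlap is divided equally along
    z and any z-gap is filled and divided equally; when the slice count is
    odd the extra slice goes to the more rostral level.

    Parameters
    ----------
    prob
        Probabilistic :class:`LevelMap` (values in [0, 1]).
    threshold
        Binarization threshold in (0, 1); default 0.6.
    cord_mask
        Cord mask defining the in-plane extent.  Required.
    on_empty
        ``"error"`` (default) raises when a level has no suprathreshold
        voxel; ``"drop"`` warns and omits the level (its span is absorbed by
        the neighbours via the gap rule).
    """
    if prob.kind != "probabilistic":
        raise ValueError("binarize_prob_levels expects a probabilistic LevelMap")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if cord_mask is None:
        raise ValueError("cord_mask is required to define the in-plane extent")
    if on_empty not in ("error", "drop"):
        raise ValueError(f"unknown on_empty policy {on_empty!r}")
    cord_mask = np.asarray(cord_mask, dtype=bool)

    intervals: dict[str, list[int]] = {}
    for lvl in prob.levels():
        m = prob.maps[lvl] >= threshold
        if not m.any():
            if on_empty == "error":
                raise ValueError(f"level {lvl} has no voxel above threshold {threshold}")
            warnings.warn(f"dropping level {lvl}: no voxel above threshold", stacklevel=2)
            continue
        m = _largest_component(m)
        m = ndimage.binary_fill_holes(m, structure=_STRUCT_26)
        lo, hi = _level_z_interval(m)
        intervals[lvl] = [lo, hi]

    order = [lvl for lvl in LEVEL_NAMES if lvl in intervals]
    if not order:
        raise ValueError("no level survived binarization")

    # Non-adjacent levels must stay rostrocaudally ordered.
    for i in range(len(order)):
        for j in range(i + 2, len(order)):
            lo_r, hi_r = intervals[order[i]]
            lo_c, hi_c = intervals[order[j]]
            if max(lo_r, lo_c) < min(hi_r, hi_c):
                raise ValueError(
                    f"non-adjacent levels {order[i]} and {order[j]} overlap in z: "
                    "rostrocaudal order violated"
                )

    # Resolve overlaps/gaps between adjacent levels.  Rostral = larger z.
    for rost, caud in zip(order[:-1], order[1:]):
        lo_r, hi_r = intervals[rost]
        lo_c, hi_c = intervals[caud]
        if hi_c > lo_r:  # overlap of (hi_c - lo_r) slices
            m = hi_c - lo_r
            n_rostral = (m + 1) // 2  # odd count: extra slice to the rostral level
            cut = hi_c - n_rostral
        elif hi_c < lo_r:  # gap of (lo_r - hi_c) slices
            m = lo_r - hi_c
            n_rostral = (m + 1) // 2
            cut = lo_r - n_rostral
        else:
            cut = lo_r
        if cut >= hi_r or cut <= lo_c:
            raise ValueError(
                f"resolving the {rost}/{caud} boundary would empty a level "
                f"(cut at slice {cut})"
            )
        intervals[rost][0] = cut
        intervals[caud][1] = cut

    maps: dict[str, np.ndarray] = {}
    for lvl in order:
        lo, hi = intervals[lvl]
        m = np.zeros_like(cord_mask)
        m[:, :, lo:hi] = cord_mask[:, :, lo:hi]
        maps[lvl] = m
    return LevelMap(
        kind="binary",
        maps=maps,
        voxel_size=prob.voxel_size,
        meta={
            "threshold": threshold,
            "z_intervals": {lvl: tuple(intervals[lvl]) for lvl in order},
            "odd_split_rule": "extra slice to the more rostral level",
        },
    )


def combine_levels(
    levels: LevelMap, partition: HemicordPartition | None = None
) -> tuple[np.ndarray, dict[tuple[str, str], np.ndarray] | None]:
    """Union binary levels into a continuous L1-S2 cord mask.

    Returns the union mask and, when a :class:`HemicordPartition` is given,
    per-(level, hemicord) sub-masks partitioning it.
    """
    if levels.kind != "binary":
        raise ValueError("combine_levels expects a binary LevelMap")
    order = levels.levels()
    union = np.zeros(levels.grid_shape, dtype=bool)
    for lvl in order:
        m = levels.maps[lvl].astype(bool)
        if (union & m).any():
            raise ValueError(f"binary level {lvl} overlaps a previous level")
        union |= m
    zs = np.nonzero(union.any(axis=(0, 1)))[0]
    if zs.size and not np.array_equal(zs, np.arange(zs.min(), zs.max() + 1)):
        raise ValueError("combined level mask is not z-contiguous")
    sub = None
    if partition is not None:
        sub = {}
        for lvl in order:
            for hemi in ("left", "right", "dorsal", "ventral"):
                sub[(lvl, hemi)] = levels.maps[lvl].astype(bool) & getattr(
                    partition, hemi
                )
    return union, sub
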