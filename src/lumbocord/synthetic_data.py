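"""Synthetic lumbosacral cord fMRI data with known ground truth.

Generates a reduced-FOV axial acquisition geometry (default 48x48x32 voxels
at 1.1 x 1.1 x 3 mm, TR 2.5 s), block task paradigms (12 x 15 s task blocks
interleaved with 13 x 15 s rests for active/passive movement; 18 alternating
10 s vibration blocks with 10-15 s jittered rests), and 4D BOLD runs with
planted hemicord- and level-localized activation clusters, polynomial drift,
white Gaussian noise, and optional motion spikes and low-rank CSF signal.

Every generator is a pure function of its arguments including the seed, so
downstream stages can be tested against planted truth without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from lumbocord.cord_geometry import LEVEL_NAMES, LevelMap
from lumbocord.hrf import convolve_blocks

#: Muscles studied: extensor/flexor pairs at the ankle, knee and hip.
MUSCLES: tuple[str, ...] = ("TA", "Gas", "Qd", "BF", "Il", "GMax")

_QUADRANTS = {"left", "right", "dorsal", "ventral"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CordGeometry:
    """Voxel grid, cord/CSF masks, centerline and true level boundaries.

    ``true_level_bounds`` maps level name (L1..S2, rostral to caudal) to a
    half-open z-slice interval ``[lo, hi)``; rostral levels have larger z
    (RAS+).
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    cord_mask: np.ndarray
    csf_mask: np.ndarray
    centerline: np.ndarray  # (nz, 2) in-plane (x, y) voxel coordinates
    true_level_bounds: dict[str, tuple[int, int]]

    def level_mask(self, level: str) -> np.ndarray:
        """Cord voxels belonging to one true level."""
        lo, hi = self.true_level_bounds[level]
        m = np.zeros_like(self.cord_mask)
        m[:, :, lo:hi] = self.cord_mask[:, :, lo:hi]
        return m

    def true_level_map(self) -> LevelMap:
        """Ground-truth binary :class:`LevelMap` over the cord mask."""
        return LevelMap(
            kind="binary",
            maps={lvl: self.level_mask(lvl) for lvl in self.true_level_bounds},
            voxel_size=self.voxel_size,
        )


@dataclass
class Paradigm:
    """Block task timing for one run."""

    condition: str  # "active" | "passive" | "vibration"
    tr: float
    n_volumes: int
    blocks: list[tuple[float, float, str]]  # (onset s, duration s, label)
    jitter_seed: int | None = None

    def __post_init__(self) -> None:
        onsets = [b[0] for b in self.blocks]
        if onsets != sorted(onsets):
            raise ValueError("blocks must be sorted by onset")
        for (o1, d1, _), (o2, _, _) in zip(self.blocks[:-1], self.blocks[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError("blocks overlap")
        total = self.n_volumes * self.tr
        if self.blocks and self.blocks[-1][0] + self.blocks[-1][1] > total + 1e-9:
            raise ValueError("blocks extend past the end of the run")

    def events_table(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            self.blocks, columns=["onset", "duration", "trial_type"]
        )


@dataclass
class PlantedCluster:
    """One planted activation: a voxel set with a task-locked response."""

    muscle: str
    level: str
    quadrant: str  # e.g. "right-ventral"
    amplitude: float  # % signal change
    voxels: np.ndarray  # (n, 3) integer voxel indices
    block_label: str | None = None  # restrict response to blocks with this label

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("planted amplitude must be positive")
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))


@dataclass
class GroundTruth:
    """Everything planted into a simulated run."""

    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    noise_sd: float = 1.0
    drift: tuple[float, ...] = (0.0, 0.0, 0.0)  # polynomial coeffs, highest first
    motion_spikes: list[tuple[int, float]] = field(default_factory=list)
    csf_signals: list[np.ndarray] | None = None


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _default_level_extents(nz: int) -> list[int]:
    base, extra = divmod(nz, len(LEVEL_NAMES))
    return [base + (1 if i < extra else 0) for i in range(len(LEVEL_NAMES))]


def make_cord_geometry(
    grid_shape: tuple[int, int, int] = (48, 48, 32),
    voxel_size: tuple[float, float, float] = (1.1, 1.1, 3.0),
    cord_radius_mm: float = 4.0,
    level_extents: list[int] | dict[str, int] | None = None,
    csf_thickness_mm: float = 2.0,
    seed: int | None = None,
) -> CordGeometry:
    """Build a cylindrical cord with a CSF ring and true level boundaries.

    The cord is a per-slice disk of ``cord_radius_mm`` around the centerline
    (straight through the grid center, or smoothly meandering when a seed is
    given); the CSF mask is the surrounding annulus of ``csf_thickness_mm``.
    ``level_extents`` gives slice counts for L1..S2 rostral to caudal
    (default: near-even partition of the grid); levels are stacked from the
    top of the grid (rostral = larger z) downward.
    """
    nx, ny, nz = grid_shape
    if level_extents is None:
        extents = _default_level_extents(nz)
    elif isinstance(level_extents, dict):
        extents = [int(level_extents[lvl]) for lvl in LEVEL_NAMES]
    else:
        extents = [int(e) for e in level_extents]
    if len(extents) != len(LEVEL_NAMES):
        raise ValueError(f"need {len(LEVEL_NAMES)} level extents (L1..S2), got {len(extents)}")
    if any(e <= 0 for e in extents):
        raise ValueError("level extents must be positive")
    if sum(extents) > nz:
        raise ValueError(
            f"level extents sum to {sum(extents)} slices but the grid has only "
            f"{nz}: overflow of {sum(extents) - nz}"
        )

    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    centerline = np.tile([cx, cy], (nz, 1)).astype(float)
    if seed is not None:
        rng = np.random.default_rng(seed)
        for axis in range(2):
            steps = rng.normal(0, 0.6, nz)
            walk = gaussian_filter1d(np.cumsum(steps), sigma=3.0, mode="nearest")
            walk -= walk.mean()
            amp = np.abs(walk).max()
            if amp > 2.0:  # bounded meander keeps cord + CSF inside the grid
                walk *= 2.0 / amp
            centerline[:, axis] += walk

    xi = np.arange(nx)[:, None, None] * voxel_size[0]
    yi = np.arange(ny)[None, :, None] * voxel_size[1]
    cxm = centerline[:, 0][None, None, :] * voxel_size[0]
    cym = centerline[:, 1][None, None, :] * voxel_size[1]
    r2 = (xi - cxm) ** 2 + (yi - cym) ** 2
    cord_mask = r2 <= cord_radius_mm**2
    outer = cord_radius_mm + csf_thickness_mm
    csf_mask = (r2 > cord_radius_mm**2) & (r2 <= outer**2)

    bounds: dict[str, tuple[int, int]] = {}
    hi = nz
    for lvl, ext in zip(LEVEL_NAMES, extents):
        bounds[lvl] = (hi - ext, hi)
        hi -= ext
    return CordGeometry(
        grid_shape=tuple(grid_shape),
        voxel_size=tuple(voxel_size),
        cord_mask=cord_mask,
        csf_mask=csf_mask,
        centerline=centerline,
        true_level_bounds=bounds,
    )


def make_paradigm(
    condition: str,
    tr: float = 2.5,
    params: dict | None = None,
    seed: int | None = None,
) -> Paradigm:
    """Build a task paradigm.

    active/passive: 12 task blocks of 15 s interleaved with 13 rest periods
    of 15 s (rest first), 375 s total.  vibration: 18 blocks of 10 s with
    labels alternating agonist/antagonist, separated (and led/trailed) by
    rests drawn uniformly from 10-15 s with the given seed.

    ``params`` may override ``n_blocks``, ``block_s``, ``rest_s`` (active/
    passive), ``jitter_s`` (vibration, a (lo, hi) pair), and ``pad_volumes``
    (extra volumes appended after the block structure; the published run
    length of 153 volumes for the 375 s paradigm at TR 2.5 s corresponds to
    ``pad_volumes=3``, unexplained in the source protocol, default 0).
    """
    p = dict(params or {})
    pad = int(p.pop("pad_volumes", 0))
    if condition in ("active", "passive"):
        n_blocks = int(p.pop("n_blocks", 12))
        block_s = float(p.pop("block_s", 15.0))
        rest_s = float(p.pop("rest_s", 15.0))
        blocks = [
            (rest_s + i * (block_s + rest_s), block_s, "task") for i in range(n_blocks)
        ]
        total = n_blocks * block_s + (n_blocks + 1) * rest_s
        jitter_seed = None
    elif condition == "vibration":
        n_blocks = int(p.pop("n_blocks", 18))
        block_s = float(p.pop("block_s", 10.0))
        lo, hi = p.pop("jitter_s", (10.0, 15.0))
        if not (lo >= 10.0 - 1e-9 and hi <= 15.0 + 1e-9 and lo <= hi):
            raise ValueError("vibration jitter bounds must lie within 10-15 s")
        rng = np.random.default_rng(seed)
        rests = rng.uniform(lo, hi, n_blocks + 1)  # lead-in, 17 gaps, trailing
        labels = ["agonist", "antagonist"]
        blocks = []
        t = rests[0]
        for i in range(n_blocks):
            blocks.append((float(t), block_s, labels[i % 2]))
            t += block_s + rests[i + 1]
        total = float(t)
        jitter_seed = seed
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if p:
        raise ValueError(f"unknown paradigm parameters: {sorted(p)}")
    n_volumes = math.ceil(total / tr) + pad
    return Paradigm(
        condition=condition,
        tr=tr,
        n_volumes=n_volumes,
        blocks=blocks,
        jitter_seed=jitter_seed,
    )


def quadrant_mask(geometry: CordGeometry, level: str, quadrant: str) -> np.ndarray:
    """Cord voxels of one true level strictly inside one quadrant.

    ``quadrant`` is e.g. ``"right-ventral"`` or a single hemicord name.
    Strict inequalities against the centerline keep planted clusters clear
    of the tie column so planted laterality is unambiguous.
    """
    m = geometry.level_mask(level)
    xi = np.arange(geometry.grid_shape[0])[:, None, None]
    yi = np.arange(geometry.grid_shape[1])[None, :, None]
    cx = geometry.centerline[:, 0][None, None, :]
    cy = geometry.centerline[:, 1][None, None, :]
    for part in quadrant.split("-"):
        if part == "left":
            m &= xi < cx
        elif part == "right":
            m &= xi > cx
        elif part == "ventral":
            m &= yi > cy
        elif part == "dorsal":
            m &= yi < cy
        else:
            raise ValueError(f"unknown quadrant component {part!r}")
    return m


def plant_cluster(
    geometry: CordGeometry,
    muscle: str,
    level: str,
    quadrant: str,
    amplitude: float,
    n_voxels: int = 12,
    seed: int | None = None,
    block_label: str | None = None,
) -> PlantedCluster:
    """Pick a compact voxel set in one level/quadrant for a planted response.

    Voxels are the ``n_voxels`` nearest (in voxel index space) to a randomly
    chosen seed voxel inside the region, giving a roughly spherical blob.
    """
    region = quadrant_mask(geometry, level, quadrant)
    coords = np.argwhere(region)
    if len(coords) < n_voxels:
        raise ValueError(
            f"region {level}/{quadrant} has only {len(coords)} voxels, "
            f"need {n_voxels}"
        )
    rng = np.random.default_rng(seed)
    center = coords[rng.integers(len(coords))]
    d2 = ((coords - center) ** 2).sum(axis=1)
    picked = coords[np.argsort(d2, kind="stable")[:n_voxels]]
    return PlantedCluster(
        muscle=muscle,
        level=level,
        quadrant=quadrant,
        amplitude=amplitude,
        voxels=picked,
        block_label=block_label,
    )


def simulate_run(
    geometry: CordGeometry,
    paradigm: Paradigm,
    ground_truth: GroundTruth,
    seed: int | None = None,
    baseline: float = 100.0,
    hrf_peak_delay: float = 6.0,
) -> tuple[np.ndarray, pd.DataFrame, GroundTruth]:
    """Simulate one 4D BOLD run plus its motion-parameter trace.

    Signal model: at planted voxels,
    ``baseline * (1 + amplitude/100 * convolved boxcar)``; everywhere,
    polynomial drift over normalized time plus white Gaussian noise.
    Baseline is ``baseline`` in the cord, 80% of it in CSF and 10% outside.
    Motion spikes add their magnitude to the x-translation at the given
    volume and perturb that volume's cord/CSF intensity (5% of baseline per
    mm) so DVARS scrubbing has something to find.  ``csf_signals`` time
    courses are added to CSF voxels with random loadings (exercises CSF
    component-based noise regression).
    """
    for cl in ground_truth.planted_clusters:
        inside = geometry.cord_mask[tuple(cl.voxels.T)]
        if not inside.all():
            bad = cl.voxels[~inside]
            raise ValueError(
                f"planted cluster for {cl.muscle} has voxels outside the cord "
                f"mask: {bad.tolist()}"
            )

    rng = np.random.default_rng(seed)
    n = paradigm.n_volumes
    shape = geometry.grid_shape + (n,)

    base = np.full(geometry.grid_shape, 0.1 * baseline)
    base[geometry.csf_mask] = 0.8 * baseline
    base[geometry.cord_mask] = baseline
    data = np.repeat(base[..., None], n, axis=3)

    t_norm = np.linspace(-1.0, 1.0, n)
    data += np.polyval(ground_truth.drift, t_norm)[None, None, None, :]

    resp_cache: dict[str | None, np.ndarray] = {}
    for cl in ground_truth.planted_clusters:
        key = cl.block_label
        if key not in resp_cache:
            labels = None if key is None else {key}
            resp_cache[key] = convolve_blocks(
                paradigm.blocks, paradigm.tr, n, peak_delay=hrf_peak_delay, labels=labels
            )[:, 0]
        resp = resp_cache[key]
        idx = tuple(cl.voxels.T)
        data[idx] += baseline * (cl.amplitude / 100.0) * resp[None, :]

    if ground_truth.csf_signals:
        csf_idx = np.nonzero(geometry.csf_mask)
        for sig in ground_truth.csf_signals:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (n,):
                raise ValueError("csf signal length must equal n_volumes")
            loadings = rng.normal(0, 1.0, len(csf_idx[0]))
            data[csf_idx] += loadings[:, None] * sig[None, :]

    if ground_truth.noise_sd > 0:
        data += rng.normal(0, ground_truth.noise_sd, shape)

    motion = pd.DataFrame(
        np.zeros((n, 6)),
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    tissue = geometry.cord_mask | geometry.csf_mask
    for vol, mag in ground_truth.motion_spikes:
        if not (0 <= vol < n):
            raise ValueError(f"motion spike volume {vol} outside run of {n} volumes")
        motion.loc[vol, "trans_x"] += mag
        data[..., vol][tissue] += 0.05 * baseline * mag

    return data, motion, ground_truth


def make_probabilistic_levels(
    geometry: CordGeometry,
    n_subjects: int,
    boundary_jitter_slices: int = 0,
    seed: int | None = None,
) -> LevelMap:
    """Across-subject probabilistic level maps (label frequency per voxel).

    Each synthetic subject's level boundaries are the true boundaries with
    the six internal boundaries independently jittered by an integer number
    of slices in ``[-j, j]`` (monotonicity enforced; outer extents fixed).
    The probability of a level at a voxel is the fraction of subjects whose
    label map assigns it, so with zero jitter the maps are binary and equal
    the true bounds.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(geometry.true_level_bounds)
    # internal boundaries rostral->caudal: hi of level k+1 == lo of level k
    lows = np.array([geometry.true_level_bounds[lvl][0] for lvl in order])
    top = geometry.true_level_bounds[order[0]][1]
    bottom = lows[-1]

    counts = {lvl: np.zeros(geometry.grid_shape) for lvl in order}
    j = int(boundary_jitter_slices)
    for _ in range(n_subjects):
        b = lows[:-1].copy()  # the 6 internal boundaries
        if j > 0:
            b = b + rng.integers(-j, j + 1, size=len(b))
            b = np.clip(b, bottom + 1, top - 1)
            # keep strictly decreasing rostral->caudal (non-empty levels)
            for k in range(1, len(b)):
                b[k] = min(b[k], b[k - 1] - 1)
            b = np.maximum(b, bottom + (len(b) - np.arange(len(b))))
        his = np.concatenate([[top], b])
        los = np.concatenate([b, [bottom]])
        for lvl, lo, hi in zip(order, los, his):
            counts[lvl][:, :, int(lo) : int(hi)] += geometry.cord_mask[
                :, :, int(lo) : int(hi)
            ]
    maps = {lvl: counts[lvl] / n_subjects for lvl in order}
    return LevelMap(kind="probabilistic", maps=maps, voxel_size=geometry.voxel_size)
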