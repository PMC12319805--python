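"""Decision-tree construction of personalized projectomes.

A projectome entry is one muscle's inferred spinal innervation: the level
and side of the activation component most plausibly representing it, its
neuron-pool type (motor/ventral vs sensory/dorsal), and a confidence grade.
The decision tree iterates a participant's stat maps in priority order —
third-level before second-level, corrected before uncorrected, stricter
thresholds first — extracts 26-connected components, keeps those whose
center of gravity falls in the muscle's literature-expected level range,
and assigns the largest kept component of the first map that yields one.
An entry is high confidence only when it comes from a third-level corrected
map; muscles with no kept candidate anywhere are reported not-estimable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import ndimage

from lumbocord.activation_glm import StatMap
from lumbocord.cord_geometry import LEVEL_NAMES, HemicordPartition, LevelMap

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def default_expected_ranges() -> dict[str, tuple[str, str]]:
    """Shipped expected innervation ranges (inclusive rostral, caudal).

    TA L4-S1, Gas L4-S2, Qd L1-L4, Il L1-L4, BF L5-S2, GMax L5-S2, per
    intraoperative nerve-root stimulation literature; users may substitute
    their own table.
    """
    text = resources.files("lumbocord.data").joinpath("expected_ranges.json").read_text()
    raw = json.loads(text)
    return {
        k: (v[0], v[1]) for k, v in raw.items() if not k.startswith("_")
    }


@dataclass
class MapSetEntry:
    """One stat map in a muscle's priority ladder."""

    statmap: StatMap
    muscle: str
    analysis_level: int | None = None
    corrected: bool | None = None
    z_threshold: float | None = None
    cluster_p: float | None = None

    def __post_init__(self) -> None:
        if self.analysis_level is None:
            self.analysis_level = self.statmap.analysis_level
        if self.corrected is None:
            self.corrected = self.statmap.corrected
        spec = self.statmap.threshold_spec
        if self.z_threshold is None and spec is not None:
            self.z_threshold = spec.z_threshold
        if self.cluster_p is None and spec is not None:
            self.cluster_p = spec.cluster_p
        if self.analysis_level != self.statmap.analysis_level or (
            self.corrected != self.statmap.corrected
        ):
            raise ValueError("MapSetEntry metadata inconsistent with its StatMap")


@dataclass
class Component:
    """One 26-connected suprathreshold component."""

    voxels: np.ndarray  # (n, 3)
    size: int
    center_of_gravity: tuple[float, float, float]
    level_at_cog: str  # L1..S2 or "outside"
    tallies: dict[str, int]  # left/right/dorsal/ventral voxel counts
    source: MapSetEntry | None = None

    def lr_index(self) -> float | None:
        n = self.tallies["left"] + self.tallies["right"]
        return (self.tallies["left"] - self.tallies["right"]) / n if n else None

    def dv_index(self) -> float | None:
        n = self.tallies["dorsal"] + self.tallies["ventral"]
        return (self.tallies["dorsal"] - self.tallies["ventral"]) / n if n else None


@dataclass
class ProjectomeEntry:
    """One muscle's inferred innervation (or a not-estimable record)."""

    muscle: str
    assigned_level: str | None
    side: str | None  # "left" | "right"
    pool: str | None  # "motor" | "sensory" | "mixed"
    confidence: str | None  # "high" | "standard"
    source_level: int | None = None
    source_corrected: bool | None = None
    component_size: int | None = None
    estimable: bool = True

    def to_dict(self) -> dict:
        return {
            "muscle": self.muscle,
            "level": self.assigned_level,
            "side": self.side,
            "pool": self.pool,
            "confidence": self.confidence,
            "source_analysis_level": self.source_level,
            "source_corrected": self.source_corrected,
            "component_size": self.component_size,
            "estimable": self.estimable,
        }


def build_map_set(entries: list[MapSetEntry]) -> list[MapSetEntry]:
    """Priority-order a muscle's stat maps.

    Sort key: analysis level descending (third before second), corrected
    before uncorrected, Z threshold descending (stricter first), cluster
    threshold ascending (stricter first); ties keep input order.
    """
    if not entries:
        raise ValueError("map set needs at least one entry")

    def key(e: MapSetEntry):
        return (
            -e.analysis_level,
            0 if e.corrected else 1,
            -(e.z_threshold if e.z_threshold is not None else -np.inf),
            e.cluster_p if e.cluster_p is not None else np.inf,
        )

    return sorted(entries, key=key)


def extract_components(
    statmap: StatMap,
    level_map: LevelMap,
    partition: HemicordPartition,
    source: MapSetEntry | None = None,
    cog_weighted: bool = False,
) -> list[Component]:
    """26-connected components of a thresholded map, with CoG and tallies.

    The center of gravity is the unweighted voxel centroid by default
    (``cog_weighted`` switches to Z-weighted, for sensitivity analysis);
    its spinal level is read from the level map at the nearest voxel
    ('outside' when unlabeled).  Hemicord tallies come from the partition.
    """
    if statmap.active_mask is None:
        raise ValueError("stat map must be thresholded before component extraction")
    labels_vol = level_map.to_label_volume()
    lab, n = ndimage.label(statmap.active_mask, structure=_STRUCT_26)
    comps = []
    for ci in range(1, n + 1):
        voxels = np.argwhere(lab == ci)
        if cog_weighted:
            w = np.abs(statmap.z[tuple(voxels.T)])
            w = w / w.sum() if w.sum() > 0 else np.full(len(voxels), 1 / len(voxels))
            cog = tuple((voxels * w[:, None]).sum(axis=0))
        else:
            cog = tuple(voxels.mean(axis=0))
        nearest = np.clip(
            np.round(cog).astype(int), 0, np.array(labels_vol.shape) - 1
        )
        code = int(labels_vol[tuple(nearest)])
        level = LEVEL_NAMES[code - 1] if code >= 1 else "outside"
        mask = lab == ci
        comps.append(
            Component(
                voxels=voxels,
                size=len(voxels),
                center_of_gravity=cog,
                level_at_cog=level,
                tallies=partition.counts(mask),
                source=source,
            )
        )
    return comps


def evaluate_candidate(
    component: Component,
    muscle: str,
    expected: dict[str, tuple[str, str]],
) -> tuple[bool, str | None]:
    """Keep a component iff its CoG level lies in the muscle's expected range.

    Returns ``(kept, reason)``; the rejection reason records the
    out-of-range level.
    """
    if muscle not in expected:
        raise ValueError(f"no expected innervation range for muscle {muscle!r}")
    rostral, caudal = expected[muscle]
    if component.level_at_cog == "outside":
        return False, "center of gravity outside the L1-S2 level maps"
    i = LEVEL_NAMES.index(component.level_at_cog)
    if LEVEL_NAMES.index(rostral) <= i <= LEVEL_NAMES.index(caudal):
        return True, None
    return False, (
        f"center of gravity in {component.level_at_cog}, outside expected "
        f"{rostral}-{caudal} for {muscle}"
    )


def classify_pool(
    component: Component, margin: float = 0.2
) -> tuple[str, str]:
    """Classify a component as motor/sensory/mixed and left/right.

    The component's DV index decides the pool: below ``-margin`` motor
    (ventral), above ``+margin`` sensory (dorsal), otherwise mixed.  Side is
    left when the LR index is positive, right otherwise (ties go right, the
    geometry tie rule).
    """
    dv = component.dv_index()
    lr = component.lr_index()
    if dv is None:
        pool = "mixed"
    elif dv < -margin:
        pool = "motor"
    elif dv > margin:
        pool = "sensory"
    else:
        pool = "mixed"
    side = "left" if (lr is not None and lr > 0) else "right"
    return pool, side


def build_projectome(
    map_sets: dict[str, list[MapSetEntry]],
    level_map: LevelMap,
    partition: HemicordPartition,
    expected: dict[str, tuple[str, str]] | None = None,
    margin: float = 0.2,
    cog_weighted: bool = False,
) -> list[ProjectomeEntry]:
    """Run the decision tree for every muscle.

    Per muscle the priority-ordered maps are scanned; the first map with at
    least one kept candidate determines the assignment — the largest kept
    component wins (equal sizes: the more caudal CoG, deterministically).
    Confidence is high iff that map is third-level corrected.  A muscle with
    no kept candidate anywhere yields a not-estimable entry (a result, not
    an error).
    """
    expected = default_expected_ranges() if expected is None else expected
    out = []
    for muscle, entries in map_sets.items():
        ordered = build_map_set(list(entries))
        chosen: Component | None = None
        chosen_entry: MapSetEntry | None = None
        for entry in ordered:
            comps = extract_components(
                entry.statmap, level_map, partition, source=entry,
                cog_weighted=cog_weighted,
            )
            kept = [c for c in comps if evaluate_candidate(c, muscle, expected)[0]]
            if kept:
                # largest wins; ties broken toward the more caudal CoG (smaller z)
                kept.sort(key=lambda c: (-c.size, c.center_of_gravity[2]))
                chosen = kept[0]
                chosen_entry = entry
                break
        if chosen is None:
            out.append(
                ProjectomeEntry(
                    muscle=muscle,
                    assigned_level=None,
                    side=None,
                    pool=None,
                    confidence=None,
                    estimable=False,
                )
            )
            continue
        pool, side = classify_pool(chosen, margin=margin)
        confidence = (
            "high"
            if (chosen_entry.analysis_level == 3 and chosen_entry.corrected)
            else "standard"
        )
        out.append(
            ProjectomeEntry(
                muscle=muscle,
                assigned_level=chosen.level_at_cog,
                side=side,
                pool=pool,
                confidence=confidence,
                source_level=chosen_entry.analysis_level,
                source_corrected=chosen_entry.corrected,
                component_size=chosen.size,
            )
        )
    return out
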