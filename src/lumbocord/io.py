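"""File I/O: NIfTI volumes, BIDS-style events, motion TSVs, JSON sidecars.

Volumes are written as NIfTI-1 in RAS+ with a diagonal affine built from
the voxel size.  Binary level maps travel as a multi-label NIfTI (integer
codes 1..7 = L1..S2) with a JSON sidecar naming the codes.  REZ annotations
load from JSON (``{"units": "mm", "entries": {"T12": ...}}``) or two-column
TSV (root, z).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from lumbocord.cord_geometry import LEVEL_NAMES, LevelMap, RezAnnotation
from lumbocord.quality_control import QcReport
from lumbocord.synthetic_data import Paradigm


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(path, data: np.ndarray, voxel_size=(1.1, 1.1, 3.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vox = tuple(float(v) for v in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), vox


def save_events(path, paradigm: Paradigm) -> None:
    paradigm.events_table().to_csv(path, sep="\t", index=False)


def load_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_motion(path, motion: pd.DataFrame) -> None:
    motion.to_csv(path, sep="\t", index=False)


def load_motion(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_level_map(path, level_map: LevelMap) -> None:
    """Binary level map as multi-label NIfTI plus a JSON code sidecar."""
    labels = level_map.to_label_volume()
    vox = level_map.voxel_size or (1.0, 1.0, 1.0)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), _affine(vox)), str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz/.nii
    codes = {str(i + 1): lvl for i, lvl in enumerate(LEVEL_NAMES)}
    Path(f"{sidecar}.json").write_text(json.dumps({"level_codes": codes}, indent=2))


def load_level_map(path) -> LevelMap:
    labels, vox = load_volume(path)
    return LevelMap.from_label_volume(np.round(labels).astype(np.int16), voxel_size=vox)


def load_rez(path) -> RezAnnotation:
    """REZ annotation from JSON or TSV (columns: root, z)."""
    path = Path(str(path))
    if path.suffix == ".json":
        d = json.loads(path.read_text())
        return RezAnnotation(
            entries=d["entries"],
            units=d.get("units", "mm"),
            slice_thickness_mm=d.get("slice_thickness_mm"),
        )
    df = pd.read_csv(path, sep="\t")
    return RezAnnotation(entries=dict(zip(df["root"], df["z"])), units="mm")


def save_qc_report(path, report: QcReport) -> None:
    Path(str(path)).write_text(json.dumps(report.to_dict(), indent=2))


def save_projectome(path, entries) -> None:
    """Projectome as JSON; a sibling .csv is written alongside."""
    rows = [e.to_dict() for e in entries]
    Path(str(path)).write_text(json.dumps(rows, indent=2))
    pd.DataFrame(rows).to_csv(Path(str(path)).with_suffix(".csv"), index=False)


def save_stat_sidecar(path, statmap) -> None:
    spec = statmap.threshold_spec
    meta = {
        "analysis_level": statmap.analysis_level,
        "corrected": bool(statmap.corrected),
        "z_threshold": None if spec is None else spec.z_threshold,
        "cluster_p": None if spec is None else spec.cluster_p,
    }
    Path(str(path)).write_text(json.dumps(meta, indent=2))
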