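"""Core cohort data model: volumes, layer masks, scan metadata, labels, folds, I/O.

The imaging unit is a :class:`MultimodalScan` — one or two co-registered 3D
scalar grids (B-mode echogenicity, and optionally a shear-modulus map from
shear-wave elastography) over the same voxel lattice.  An integer-coded
:class:`LayerLabelMap` assigns every voxel to background or one of six tissue
layers ordered superficial to deep: dermis, superficial fat, superficial
fascial membrane (SFM), deep fat, deep fascial membrane (DFM), muscle.

Axis convention: arrays are indexed ``(depth, height, width)`` with depth
increasing into the tissue; voxel indices are 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LAYER_CODES",
    "LAYER_NAMES",
    "VolumeGrid",
    "MultimodalScan",
    "LayerLabelMap",
    "ScanMetadata",
    "CohortIndex",
    "PredictionRecord",
    "derive_scan_label",
    "derive_visit_label",
    "split_by_patient",
    "probability_to_logit",
    "logit_to_probability",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_manifest",
    "write_manifest",
]

#: Tissue-layer integer codes in superficial-to-deep order (0 = background).
LAYER_NAMES: dict[int, str] = {
    0: "background",
    1: "dermis",
    2: "superficial_fat",
    3: "SFM",
    4: "deep_fat",
    5: "DFM",
    6: "muscle",
}
LAYER_CODES: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

MODALITIES = ("bmode", "swe")
SIDES = ("left", "right")
SITES = ("MF", "ES")
SCAN_LABELS = ("control", "tender_mp", "trigger_mp")

#: Probability clamp applied before the log-odds transform.
PROB_EPS = 1e-6

#: Aggregation levels, finest to coarsest, with their manifest grouping keys.
LEVEL_KEYS: dict[str, tuple[str, ...]] = {
    "scan": ("patient_id", "visit", "side", "site", "repetition"),
    "repetition": ("patient_id", "visit", "side", "site", "repetition"),
    "site": ("patient_id", "visit", "side", "site"),
    "side": ("patient_id", "visit", "side"),
    "visit": ("patient_id", "visit"),
    "patient": ("patient_id",),
}


def probability_to_logit(p: float) -> float:
    """Log-odds of ``p``, with ``p`` clipped to [1e-6, 1 - 1e-6] first."""
    p = float(np.clip(p, PROB_EPS, 1.0 - PROB_EPS))
    return math.log(p / (1.0 - p))


def logit_to_probability(z: float) -> float:
    return float(1.0 / (1.0 + math.exp(-z)))


@dataclass
class VolumeGrid:
    """A single-modality 3D scalar grid.

    Parameters
    ----------
    values
        Array of shape ``(depth, height, width)``.
    spacing_mm
        Voxel spacing along each axis, strictly positive.
    modality
        ``"bmode"`` (echogenicity, arbitrary units) or ``"swe"``
        (shear modulus, Pa, non-negative).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "bmode"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("volume must be 3D with all dimensions >= 1")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if self.modality == "swe" and np.any(self.values < 0):
            raise ValueError("shear modulus values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ScanMetadata:
    patient_id: str
    visit: int = 1
    side: str = "left"
    site: str = "MF"
    repetition: int = 1
    tender_points: int = 0
    trigger_points: int = 0
    scan_label: str | None = None

    def __post_init__(self) -> None:
        if self.visit < 1 or self.repetition < 1:
            raise ValueError("visit and repetition indices start at 1")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        derived = derive_scan_label(self.tender_points, self.trigger_points)
        if self.scan_label is None:
            self.scan_label = derived
        elif self.scan_label != derived:
            raise ValueError(
                f"scan_label {self.scan_label!r} inconsistent with point counts "
                f"(expected {derived!r})"
            )


@dataclass
class MultimodalScan:
    """One or two co-registered volumes plus their metadata.

    Channel order is fixed: B-mode first, shear modulus (optional) second.
    """

    scan_id: str
    channels: list[VolumeGrid]
    metadata: ScanMetadata

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a scan needs at least one channel")
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        mods = [c.modality for c in self.channels]
        if len(set(mods)) != len(mods):
            raise ValueError("channel modalities must be unique")
        if mods[0] != "bmode":
            raise ValueError("channel order is bmode first")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(c.modality for c in self.channels)

    def channel(self, modality: str) -> VolumeGrid:
        for c in self.channels:
            if c.modality == modality:
                return c
        raise KeyError(modality)

    def values(self, modalities: Sequence[str] | None = None) -> np.ndarray:
        """Stack channels into a ``(C, depth, height, width)`` array."""
        mods = tuple(modalities) if modalities is not None else self.modalities
        return np.stack([self.channel(m).values for m in mods], axis=0)


@dataclass
class LayerLabelMap:
    """Integer-coded tissue-layer map; code ``i`` yields the binary mask
    ``labels == i`` of the i-th layer."""

    labels: np.ndarray
    code_names: Mapping[int, str] = field(default_factory=lambda: dict(LAYER_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-coded")
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        bad = set(np.unique(self.labels)) - set(self.code_names)
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, codes: int | Iterable[int]) -> np.ndarray:
        """Boolean mask of the union of the given layer codes."""
        if isinstance(codes, (int, np.integer)):
            codes = (int(codes),)
        codes = tuple(int(c) for c in codes)
        for c in codes:
            if c not in self.code_names:
                raise ValueError(f"unknown layer code {c}")
        return np.isin(self.labels, codes)

    def volume(self, code: int) -> int:
        """Voxel count of one layer (its mask norm)."""
        return int(np.count_nonzero(self.labels == code))

    def present_codes(self) -> list[int]:
        return [c for c in LAYER_CODES if self.volume(c) > 0]


@dataclass
class PredictionRecord:
    """A classifier output at some aggregation level."""

    scan_id: str
    probability: float
    logit: float | None = None
    level: str = "scan"

    def __post_init__(self) -> None:
        if not (0.0 < self.probability < 1.0):
            self.probability = float(
                np.clip(self.probability, PROB_EPS, 1.0 - PROB_EPS)
            )
        if self.logit is None:
            self.logit = probability_to_logit(self.probability)
        else:
            expected = probability_to_logit(self.probability)
            if abs(self.logit - expected) > 1e-6:
                raise ValueError("logit inconsistent with probability")
        if self.level not in LEVEL_KEYS:
            raise ValueError(f"unknown level {self.level!r}")


# ---------------------------------------------------------------------------
# Clinical label derivation
# ---------------------------------------------------------------------------

def derive_scan_label(tender_points: int, trigger_points: int) -> str:
    """Scan-level clinical label from palpation point counts.

    ``control`` if no points of either kind; ``trigger_mp`` as soon as at
    least one trigger point is present (regardless of tender points);
    ``tender_mp`` for tender points without trigger points.
    """
    if tender_points < 0 or trigger_points < 0:
        raise ValueError("point counts must be non-negative")
    if trigger_points >= 1:
        return "trigger_mp"
    if tender_points >= 1:
        return "tender_mp"
    return "control"


def derive_visit_label(side_labels: Sequence[str]) -> str:
    """Visit-level label: ``control`` only when every side label is control."""
    if len(side_labels) == 0:
        raise ValueError("need at least one side label")
    for lab in side_labels:
        if lab not in SCAN_LABELS:
            raise ValueError(f"unknown scan label {lab!r}")
    return "control" if all(l == "control" for l in side_labels) else "mp_present"


# ---------------------------------------------------------------------------
# Cohort index and patient-level folds
# ---------------------------------------------------------------------------

@dataclass
class CohortIndex:
    """Manifest of scans plus an optional patient-level fold assignment."""

    manifest: pd.DataFrame
    folds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "patient_id" not in self.manifest.columns:
            raise ValueError("manifest needs a patient_id column")
        if self.folds:
            missing = set(self.manifest["patient_id"]) - set(self.folds)
            if missing:
                raise ValueError(f"patients without fold assignment: {sorted(missing)}")

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.manifest["patient_id"].astype(str)))

    def fold_of(self, patient_id: str) -> int:
        return self.folds[patient_id]


def split_by_patient(index: CohortIndex, n_folds: int, seed: int) -> CohortIndex:
    """Partition patients into ``n_folds`` near-equal folds (sizes differ by at
    most one), deterministically for a fixed seed.  Every scan of a patient
    lands in that patient's single fold, preventing leakage across folds."""
    if n_folds < 2:
        raise ValueError("need at least two folds")
    patients = index.patients
    if len(patients) < n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    folds = {pid: i % n_folds for i, pid in enumerate(order)}
    return CohortIndex(manifest=index.manifest, folds=folds)


# ---------------------------------------------------------------------------
# On-disk formats: NIfTI volumes, CSV manifest, JSON folds
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "scan_id", "patient_id", "visit", "side", "site", "repetition",
    "tender_points", "trigger_points", "scan_label",
    "bmode_path", "swe_path", "labels_path",
]


def _affine(spacing_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(grid.values.astype(np.float32), _affine(grid.spacing_mm))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, modality: str = "bmode") -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asarray(img.dataobj, dtype=np.float64), spacing, modality)


def write_labels(labels: LayerLabelMap, path: str | Path,
                 spacing_mm: Sequence[float] = (1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(labels.labels.astype(np.int16), _affine(spacing_mm))
    nib.save(img, str(path))
    return path


def read_labels(path: str | Path, expected_shape: tuple[int, int, int] | None = None
                ) -> LayerLabelMap:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj).astype(np.int16)
    lmap = LayerLabelMap(arr)
    if expected_shape is not None and lmap.shape != tuple(expected_shape):
        raise ValueError(
            f"label map shape {lmap.shape} does not match scan shape {tuple(expected_shape)}"
        )
    return lmap


def write_scan(scan: MultimodalScan, out_dir: str | Path) -> dict[str, Path]:
    """Write one NIfTI file per channel; returns modality -> path."""
    out_dir = Path(out_dir)
    paths = {}
    for ch in scan.channels:
        p = out_dir / f"{scan.scan_id}_{ch.modality}.nii.gz"
        write_volume(ch, p)
        paths[ch.modality] = p
    return paths


def read_scan(scan_id: str, metadata: ScanMetadata,
              bmode_path: str | Path, swe_path: str | Path | None = None
              ) -> MultimodalScan:
    channels = [read_volume(bmode_path, "bmode")]
    if swe_path is not None:
        channels.append(read_volume(swe_path, "swe"))
    return MultimodalScan(scan_id=scan_id, channels=channels, metadata=metadata)


def write_manifest(index: CohortIndex, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in MANIFEST_COLUMNS if c in index.manifest.columns]
    extra = [c for c in index.manifest.columns if c not in cols]
    index.manifest[cols + extra].to_csv(path, index=False)
    if index.folds:
        with open(path.with_suffix(".folds.json"), "w") as fh:
            json.dump(index.folds, fh, indent=1, sort_keys=True)
    return path


def read_manifest(path: str | Path) -> CohortIndex:
    path = Path(path)
    manifest = pd.read_csv(path)
    folds_path = path.with_suffix(".folds.json")
    folds = {}
    if folds_path.exists():
        with open(folds_path) as fh:
            folds = {k: int(v) for k, v in json.load(fh).items()}
    return CohortIndex(manifest=manifest, folds=folds)


def metadata_from_row(row: Mapping) -> ScanMetadata:
    return ScanMetadata(
        patient_id=str(row["patient_id"]),
        visit=int(row["visit"]),
        side=str(row["side"]),
        site=str(row["site"]),
        repetition=int(row["repetition"]),
        tender_points=int(row["tender_points"]),
        trigger_points=int(row["trigger_points"]),
        scan_label=str(row["scan_label"]) if "scan_label" in row else None,
    )


def metadata_to_row(scan_id: str, md: ScanMetadata) -> dict:
    return {
        "scan_id": scan_id,
        "patient_id": md.patient_id,
        "visit": md.visit,
        "side": md.side,
        "site": md.site,
        "repetition": md.repetition,
        "tender_points": md.tender_points,
        "trigger_points": md.trigger_points,
        "scan_label": md.scan_label,
    }
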