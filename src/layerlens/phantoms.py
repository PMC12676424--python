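"""Synthetic layered ultrasound phantoms.

Generates desk-scale cohorts that mimic the structure of a paraspinal
multimodal ultrasound study: six depth-stacked tissue layers with wobbled
interfaces, multiplicative gamma speckle in B-mode, smooth additive noise in
the shear-modulus channel, a scan hierarchy of
``patients x visits x 2 sides x sites x repetitions``, side-level disease
labels, and a planted layer-specific class signal.

Three signal geometries are supported:

``additive``
    every signal layer's mean is shifted independently in positives;
``synergistic``
    a per-side latent sign ``s`` shifts the two designated layers with the
    *same* polarity in positives and *opposite* polarity in controls, so each
    layer's marginal distribution is class-independent while the pair's
    product carries the class — single-layer occlusion is uninformative but
    joint occlusion is not;
``redundant``
    the identical shift is duplicated in both designated layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cohort import (
    CohortIndex,
    LayerLabelMap,
    MultimodalScan,
    ScanMetadata,
    VolumeGrid,
    derive_scan_label,
    metadata_to_row,
    read_labels,
    read_scan,
    write_labels,
    write_manifest,
    write_scan,
)

__all__ = [
    "PhantomConfig",
    "PhantomCohort",
    "shear_speed_to_modulus",
    "generate_label_map",
    "generate_scan",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

#: Tissue density used for the speed-to-modulus conversion, kg/m^3.
TISSUE_DENSITY = 1000.0

INTERACTION_MODES = ("additive", "synergistic", "redundant")


def shear_speed_to_modulus(c):
    """Shear modulus mu = rho * c^2 (Pa) from shear-wave speed c (m/s),
    with tissue density rho = 1000 kg/m^3."""
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("shear-wave speed must be non-negative")
    out = TISSUE_DENSITY * c ** 2
    return float(out) if out.ndim == 0 else out


@dataclass
class PhantomConfig:
    """Generator settings.  Defaults describe a desk-scale cohort with the
    full acquisition hierarchy (2 visits, 2 sides, 2 sites, 3 B-mode and 2
    SWE repetitions) and an additive B-mode + SWE signal planted in layer 5
    (the deep fascial membrane)."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    layer_fractions: tuple[float, ...] = (1 / 6,) * 6
    interface_wobble: float = 1.0
    #: per-layer mean echogenicity (arbitrary units), superficial to deep;
    #: membranes (SFM, DFM) echogenic, fat hypoechoic.
    bmode_base: tuple[float, ...] = (1.2, 0.8, 1.5, 0.7, 1.6, 0.9)
    #: per-layer shear-wave speed (m/s); muscle and membranes stiffer.
    swe_base: tuple[float, ...] = (2.5, 1.8, 3.0, 1.6, 3.2, 2.2)
    speckle_shape: float = 4.0
    swe_noise_sd: float = 300.0
    signal_layers: tuple[int, ...] = (5,)
    #: scalar shift applied to every signal layer, or one shift per signal layer
    effect_bmode: float | tuple[float, ...] = 0.5
    effect_swe: float | tuple[float, ...] = 2000.0
    interaction_mode: str = "additive"
    n_patients: int = 8
    visits_per_patient: int = 2
    sites_per_side: int = 2
    bmode_reps: int = 3
    swe_reps: int = 2
    prevalence: float = 0.5
    seed: int = 0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.layer_fractions) != 6 or any(f <= 0 for f in self.layer_fractions):
            raise ValueError("need six strictly positive layer fractions")
        if sum(self.layer_fractions) > 1 + 1e-9:
            raise ValueError("layer fractions must sum to at most 1")
        if self.interaction_mode not in INTERACTION_MODES:
            raise ValueError(f"interaction_mode must be one of {INTERACTION_MODES}")
        if not all(1 <= k <= 6 for k in self.signal_layers):
            raise ValueError("signal layers must be codes in 1..6")
        if self.interaction_mode in ("synergistic", "redundant") and len(
            self.signal_layers
        ) != 2:
            raise ValueError(f"{self.interaction_mode} mode needs exactly two signal layers")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.interface_wobble < 0 or self.speckle_shape <= 0 or self.swe_noise_sd < 0:
            raise ValueError("noise parameters out of range")
        if min(self.n_patients, self.visits_per_patient, self.sites_per_side,
               self.bmode_reps, self.swe_reps) < 1:
            raise ValueError("cohort size parameters must be positive")
        for eff in (self.effect_bmode, self.effect_swe):
            arr = np.atleast_1d(np.asarray(eff, dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValueError("effect sizes must be finite")
            if arr.size not in (1, len(self.signal_layers)):
                raise ValueError("per-layer effects must match signal_layers")


@dataclass
class PhantomCohort:
    """An in-memory generated cohort plus its ground truth."""

    config: PhantomConfig
    scans: list[MultimodalScan]
    label_maps: dict[str, LayerLabelMap]  # scan_id -> label map
    index: CohortIndex
    #: per-scan truth: signal layers perturbed and the side-level label.
    truth: pd.DataFrame

    def labels_for(self, scan: MultimodalScan | str) -> LayerLabelMap:
        sid = scan if isinstance(scan, str) else scan.scan_id
        return self.label_maps[sid]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _smooth_unit_field(shape: tuple[int, int], rng: np.random.Generator,
                       sigma: float = 4.0) -> np.ndarray:
    """A smooth random field on (height, width) scaled into [-1, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def generate_label_map(config: PhantomConfig, rng: np.random.Generator) -> LayerLabelMap:
    """Six contiguous depth-stacked slabs (codes 1..6 superficial to deep)
    with interfaces displaced by a smooth random offset field bounded by
    ``interface_wobble`` voxels; background (0) only above layer 1 and below
    layer 6."""
    depth, height, width = config.grid_shape
    if depth < 12:
        raise ValueError("grid depth must be >= 12 so each layer gets a slab")
    fracs = np.asarray(config.layer_fractions, dtype=float)
    thick = fracs * depth
    if np.any(thick < 1.0):
        raise ValueError("layer fractions incompatible with grid depth (layer thinner than one voxel)")
    top_bg = (1.0 - fracs.sum()) * depth / 2.0
    # 7 interface surfaces: top of layer 1 ... bottom of layer 6
    flat = top_bg + np.concatenate(([0.0], np.cumsum(thick)))
    surfaces = np.empty((7, height, width))
    for i in range(7):
        wob = config.interface_wobble
        offset = wob * _smooth_unit_field((height, width), rng) if wob > 0 else 0.0
        surfaces[i] = flat[i] + offset
    # keep surfaces ordered and at least one voxel apart so every code
    # survives in every column, even after clipping to the grid
    for i in range(6, -1, -1):
        surfaces[i] = np.minimum(surfaces[i], depth - (6 - i))
    surfaces[0] = np.maximum(surfaces[0], 0.0)
    for i in range(1, 7):
        surfaces[i] = np.maximum(surfaces[i], surfaces[i - 1] + 1.0)
    z = np.arange(depth, dtype=float)[:, None, None]
    # the 1e-9 tolerance absorbs cumulative-sum rounding at integer surfaces
    count = (z >= surfaces[:, None] - 1e-9).sum(axis=0)  # 0..7
    labels = np.where((count >= 1) & (count <= 6), count, 0).astype(np.int16)
    lmap = LayerLabelMap(labels)
    missing = set(range(1, 7)) - set(lmap.present_codes())
    if missing:  # cannot happen with the one-voxel separation above
        raise RuntimeError(f"layer codes {sorted(missing)} absent from generated map")
    return lmap


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def _layer_shifts(config: PhantomConfig, is_positive: bool, latent_sign: int,
                  effect: float | tuple[float, ...]) -> np.ndarray:
    """Per-layer additive mean shift (index 0 = layer code 1)."""
    shifts = np.zeros(6)
    eff = np.broadcast_to(np.atleast_1d(np.asarray(effect, dtype=float)),
                          (len(config.signal_layers),))
    if config.interaction_mode == "additive":
        if is_positive:
            for k, e in zip(config.signal_layers, eff):
                shifts[k - 1] = e
    elif config.interaction_mode == "synergistic":
        i, j = config.signal_layers
        shifts[i - 1] = latent_sign * eff[0]
        shifts[j - 1] = (latent_sign if is_positive else -latent_sign) * eff[1]
    else:  # redundant: identical shift duplicated in both layers
        if is_positive:
            i, j = config.signal_layers
            shifts[i - 1] = eff[0]
            shifts[j - 1] = eff[0]
    return shifts


def generate_scan(config: PhantomConfig, label_map: LayerLabelMap,
                  is_positive: bool, rng: np.random.Generator,
                  scan_id: str = "phantom", metadata: ScanMetadata | None = None,
                  latent_sign: int | None = None,
                  with_swe: bool = True) -> MultimodalScan:
    """One multimodal scan over a given layer geometry.

    B-mode is per-layer mean echogenicity times unit-mean gamma speckle
    (shape ``speckle_shape``); the SWE channel is the per-layer shear modulus
    (from ``swe_base`` speeds via mu = rho c^2) plus smooth additive noise,
    clipped at zero.  ``latent_sign`` is the per-side latent used by the
    synergistic mode; drawn from ``rng`` when not supplied.
    """
    labels = label_map.labels
    if latent_sign is None:
        latent_sign = int(rng.choice((-1, 1)))
    b_shift = _layer_shifts(config, is_positive, latent_sign, config.effect_bmode)
    s_shift = _layer_shifts(config, is_positive, latent_sign, config.effect_swe)

    b_mean = np.zeros(7)
    b_mean[1:] = np.asarray(config.bmode_base) + b_shift
    mu_mean = np.zeros(7)
    mu_mean[1:] = shear_speed_to_modulus(np.asarray(config.swe_base)) + s_shift
    mu_mean = np.maximum(mu_mean, 0.0)

    k = config.speckle_shape
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=labels.shape)
    bmode = b_mean[labels] * speckle

    channels = [VolumeGrid(bmode, config.spacing_mm, "bmode")]
    if with_swe:
        swe = mu_mean[labels].astype(np.float64)
        if config.swe_noise_sd > 0:
            noise = gaussian_filter(rng.standard_normal(labels.shape), sigma=2.0,
                                    mode="nearest")
            sd = noise.std()
            if sd > 0:
                swe = swe + noise * (config.swe_noise_sd / sd)
        swe[labels == 0] = 0.0
        swe = np.clip(swe, 0.0, None)
        channels.append(VolumeGrid(swe, config.spacing_mm, "swe"))

    if metadata is None:
        metadata = ScanMetadata(patient_id="p000")
    return MultimodalScan(scan_id=scan_id, channels=channels, metadata=metadata)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _draw_point_counts(rng: np.random.Generator, positive: bool) -> tuple[int, int]:
    if not positive:
        return 0, 0
    if rng.random() < 0.6:  # tender-only side
        return int(1 + rng.poisson(1.0)), 0
    return int(rng.poisson(0.8)), int(1 + rng.poisson(0.5))


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Full phantom cohort, reproducible from ``config.seed``.

    Disease status is assigned per (patient, side) with probability
    ``prevalence`` and held constant across visits; every scan of a positive
    side is generated with the planted signal.  One layer geometry is drawn
    per (patient, side, site) and shared by its repetitions and visits
    (the acquisitions are co-registered).  Repetition r carries an SWE
    channel when ``r <= swe_reps``.
    """
    rng = np.random.default_rng(config.seed)
    scans: list[MultimodalScan] = []
    label_maps: dict[str, LayerLabelMap] = {}
    rows, truth_rows = [], []
    for p in range(config.n_patients):
        pid = f"p{p:03d}"
        for side in ("left", "right"):
            positive = bool(rng.random() < config.prevalence)
            latent = int(rng.choice((-1, 1)))
            tender, trigger = _draw_point_counts(rng, positive)
            site_maps = {}
            for s in range(config.sites_per_side):
                site = ("MF", "ES")[s % 2]
                site_maps[site] = generate_label_map(config, rng)
            for visit in range(1, config.visits_per_patient + 1):
                for s in range(config.sites_per_side):
                    site = ("MF", "ES")[s % 2]
                    lmap = site_maps[site]
                    for rep in range(1, config.bmode_reps + 1):
                        sid = f"{pid}_v{visit}_{side}_{site}_r{rep}"
                        md = ScanMetadata(
                            patient_id=pid, visit=visit, side=side, site=site,
                            repetition=rep, tender_points=tender,
                            trigger_points=trigger,
                        )
                        scan = generate_scan(
                            config, lmap, positive, rng, scan_id=sid,
                            metadata=md, latent_sign=latent,
                            with_swe=(rep <= config.swe_reps),
                        )
                        scans.append(scan)
                        label_maps[sid] = lmap
                        rows.append(metadata_to_row(sid, md))
                        truth_rows.append({
                            "scan_id": sid,
                            "side_positive": positive,
                            "latent_sign": latent,
                            "signal_layers": ",".join(map(str, config.signal_layers))
                            if positive or config.interaction_mode == "synergistic" else "",
                        })
    manifest = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    index = CohortIndex(manifest=manifest)
    return PhantomCohort(config=config, scans=scans, label_maps=label_maps,
                         index=index, truth=truth)


def write_cohort(cohort: PhantomCohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes and label maps, the CSV manifest, the JSON truth
    file, and the generator config."""
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    path_cols = {"bmode_path": [], "swe_path": [], "labels_path": []}
    written_maps: dict[int, str] = {}
    for scan in cohort.scans:
        paths = write_scan(scan, out / "volumes")
        lmap = cohort.label_maps[scan.scan_id]
        key = id(lmap)
        if key not in written_maps:
            lp = out / "volumes" / f"labels_{len(written_maps):04d}.nii.gz"
            write_labels(lmap, lp, cohort.config.spacing_mm)
            written_maps[key] = str(lp.relative_to(out))
        path_cols["bmode_path"].append(str(paths["bmode"].relative_to(out)))
        path_cols["swe_path"].append(
            str(paths["swe"].relative_to(out)) if "swe" in paths else "")
        path_cols["labels_path"].append(written_maps[key])
    manifest = cohort.index.manifest.copy()
    for c, v in path_cols.items():
        manifest[c] = v
    write_manifest(CohortIndex(manifest, cohort.index.folds), out / "manifest.csv")
    cohort.truth.to_json(out / "truth.json", orient="records", indent=1)
    with open(out / "phantom_config.json", "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=1)
    return out


def load_cohort(cohort_dir: str | Path) -> PhantomCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from .cohort import metadata_from_row, read_manifest

    out = Path(cohort_dir)
    index = read_manifest(out / "manifest.csv")
    with open(out / "phantom_config.json") as fh:
        raw = json.load(fh)
    for key in ("grid_shape", "layer_fractions", "bmode_base", "swe_base",
                "signal_layers", "spacing_mm"):
        raw[key] = tuple(raw[key])
    config = PhantomConfig(**raw)
    truth = pd.read_json(out / "truth.json")
    scans, label_maps = [], {}
    map_cache: dict[str, LayerLabelMap] = {}
    for _, row in index.manifest.iterrows():
        md = metadata_from_row(row)
        swe = row["swe_path"] if isinstance(row["swe_path"], str) and row["swe_path"] else None
        scan = read_scan(row["scan_id"], md, out / row["bmode_path"],
                         out / swe if swe else None)
        lp = row["labels_path"]
        if lp not in map_cache:
            map_cache[lp] = read_labels(out / lp, scan.shape)
        scans.append(scan)
        label_maps[scan.scan_id] = map_cache[lp]
    return PhantomCohort(config=config, scans=scans, label_maps=label_maps,
                         index=index, truth=truth)
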