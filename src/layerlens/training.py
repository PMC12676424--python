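"""Curriculum training loop and hierarchical prediction aggregation.

The curriculum keeps an exponentially smoothed per-sample difficulty
``L_i(t) = beta * L_i(t-1) + (1 - beta) * l_i(t)`` (initialized at the first
observed loss), exposes a linearly growing fraction
``f_e = f_min + (1 - f_min) * e / (E - 1)`` of the training set each epoch,
and trains on the ``N_e = round(f_e * N)`` currently-easiest samples.
Samples never yet visited sort as easiest, so the pool genuinely grows.

Each selected sample passes through the adaptive intensity re-weighting
path ``C(G(I) * I)``; binary cross-entropy is backpropagated jointly through
classifier and generator, and the sample's difficulty is updated with its
instantaneous loss.  Difficulties of unselected samples are frozen between
epochs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    LEVEL_KEYS,
    MultimodalScan,
    PredictionRecord,
    probability_to_logit,
)
from .models import Adam, CarnModel, build_model
from .phantoms import PhantomCohort

__all__ = [
    "DifficultyState",
    "CurriculumSchedule",
    "TrainConfig",
    "TrainingHistory",
    "update_difficulty",
    "exposure_fraction",
    "select_easiest",
    "bce_loss",
    "train",
    "ScanDataset",
    "build_dataset",
    "predict_dataset",
    "aggregate_predictions",
]


# ---------------------------------------------------------------------------
# Difficulty state and exposure schedule
# ---------------------------------------------------------------------------

@dataclass
class DifficultyState:
    """Per-sample smoothed difficulty scores.

    ``momentum`` is the EMA coefficient beta in [0, 1).  Samples are
    registered in a stable order that also breaks score ties.
    """

    momentum: float = 0.9
    scores: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    _order: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")

    def register(self, sample_ids) -> None:
        for sid in sample_ids:
            if sid not in self._order:
                self._order[sid] = len(self._order)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self._order, key=self._order.get)

    def visited(self, sample_id: str) -> bool:
        return self.counts.get(sample_id, 0) > 0

    def snapshot(self) -> dict[str, float]:
        return dict(self.scores)


def update_difficulty(state: DifficultyState, sample_id: str, loss: float
                      ) -> DifficultyState:
    """EMA update ``L <- beta L + (1 - beta) l``; the first observation
    initializes ``L = l`` so the average is not biased toward zero."""
    if not np.isfinite(loss) or loss < 0:
        raise ValueError("instantaneous loss must be finite and non-negative")
    state.register([sample_id])
    if state.counts.get(sample_id, 0) == 0:
        state.scores[sample_id] = float(loss)
    else:
        b = state.momentum
        state.scores[sample_id] = b * state.scores[sample_id] + (1.0 - b) * float(loss)
    state.counts[sample_id] = state.counts.get(sample_id, 0) + 1
    return state


@dataclass
class CurriculumSchedule:
    """Linear exposure ramp from ``f_min`` at epoch 0 to 1 at the last epoch."""

    f_min: float = 0.2
    total_epochs: int = 20
    dataset_size: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.f_min <= 1.0):
            raise ValueError("f_min must lie in (0, 1]")
        if self.total_epochs < 1 or self.dataset_size < 1:
            raise ValueError("epochs and dataset size must be positive")


def exposure_fraction(schedule: CurriculumSchedule, epoch: int) -> float:
    """``f_e = f_min + (1 - f_min) * e / (E - 1)``; 1.0 when E == 1."""
    E = schedule.total_epochs
    if not (0 <= epoch <= E - 1):
        raise ValueError(f"epoch {epoch} outside 0..{E - 1}")
    if E == 1:
        return 1.0
    return schedule.f_min + (1.0 - schedule.f_min) * epoch / (E - 1)


def exposure_count(schedule: CurriculumSchedule, epoch: int) -> int:
    """``N_e = round(f_e N)`` with round-half-up and a floor of 1."""
    f = exposure_fraction(schedule, epoch)
    n = int(math.floor(f * schedule.dataset_size + 0.5))
    return max(1, min(n, schedule.dataset_size))


def select_easiest(state: DifficultyState, n: int) -> list[str]:
    """The ``n`` sample ids with smallest smoothed difficulty.

    Never-visited samples count as easiest (difficulty -inf surrogate);
    ties break by stable registration order.
    """
    ids = state.sample_ids
    if not (1 <= n <= len(ids)):
        raise ValueError(f"selection size {n} outside 1..{len(ids)}")
    keyed = sorted(
        ids,
        key=lambda sid: (
            state.scores.get(sid, -math.inf) if state.visited(sid) else -math.inf,
            state._order[sid],
        ),
    )
    return keyed[:n]


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class ScanDataset:
    """In-memory training set: value arrays, binary targets, ids, manifest."""

    sample_ids: list[str]
    values: list[np.ndarray]  # each (C, D, H, W)
    targets: np.ndarray  # binary
    manifest: pd.DataFrame
    modalities: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.values[0].shape


def _pad_to(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Zero-pad a (C, D, H, W) array up to a common spatial shape."""
    if arr.shape == shape:
        return arr
    pads = [(0, t - s) for s, t in zip(arr.shape, shape)]
    if any(p[1] < 0 for p in pads):
        raise ValueError("cannot pad down")
    return np.pad(arr, pads)


#: model-input units per modality: B-mode stays in its native O(1) units,
#: shear modulus is converted Pa -> kPa so the channels share a scale.
#: Pure scaling (no centering) keeps "occluded voxel = 0" meaningful.
CHANNEL_SCALES = {"bmode": 1.0, "swe": 1e-3}


def build_dataset(cohort: PhantomCohort | list[MultimodalScan],
                  modalities: tuple[str, ...] = ("bmode", "swe"),
                  target: str = "mp",
                  channel_scales: dict[str, float] | None = None) -> ScanDataset:
    """Select the scans carrying all requested modalities and stack them.

    ``target="mp"`` labels any non-control scan positive;
    ``target="trigger"`` labels trigger-point scans against everything else.
    Scans are zero-padded to the largest spatial shape present and each
    channel is rescaled into model-input units (see ``CHANNEL_SCALES``).
    """
    if isinstance(cohort, PhantomCohort):
        scans = cohort.scans
        manifest = cohort.index.manifest
    else:
        scans = cohort
        from .cohort import metadata_to_row
        manifest = pd.DataFrame([metadata_to_row(s.scan_id, s.metadata) for s in scans])
    chosen = [s for s in scans if set(modalities) <= set(s.modalities)]
    if not chosen:
        raise ValueError(f"no scans carry modalities {modalities}")
    scales = dict(CHANNEL_SCALES)
    if channel_scales:
        scales.update(channel_scales)
    scale_vec = np.array([scales.get(m, 1.0) for m in modalities])[:, None, None, None]
    shapes = np.array([s.shape for s in chosen])
    common = tuple(shapes.max(axis=0))
    ids, values, targets = [], [], []
    for s in chosen:
        ids.append(s.scan_id)
        vals = s.values(modalities) * scale_vec
        values.append(_pad_to(vals, (len(modalities), *common)))
        lab = s.metadata.scan_label
        targets.append(
            int(lab == "trigger_mp") if target == "trigger" else int(lab != "control")
        )
    sub = manifest[manifest["scan_id"].isin(ids)].reset_index(drop=True)
    return ScanDataset(ids, values, np.asarray(targets), sub, tuple(modalities))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 20
    f_min: float = 0.2
    ema_momentum: float = 0.9
    learning_rate: float = 1e-2
    weight_decay: float = 1.0
    batch_size: int = 8
    seed: int = 0
    classifier: str = "linear"
    generator: str | None = "gate"
    n_slabs: int = 6


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    exposure: list[int] = field(default_factory=list)
    difficulty_snapshots: list[dict[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.epoch_loss)),
            "mean_loss": self.epoch_loss,
            "n_selected": self.exposure,
        })


def bce_loss(logit: float, target: int) -> tuple[float, float]:
    """Numerically stable binary cross-entropy from the logit.

    Returns ``(loss, dloss/dlogit)`` with ``dloss/dlogit = p - y``.
    """
    z, y = float(logit), float(target)
    loss = max(z, 0.0) - z * y + math.log1p(math.exp(-abs(z)))
    p = 1.0 / (1.0 + math.exp(-min(max(z, -60.0), 60.0)))
    return loss, p - y


def train(dataset: ScanDataset, config: TrainConfig,
          model: CarnModel | None = None
          ) -> tuple[CarnModel, DifficultyState, TrainingHistory]:
    """Run the curriculum loop over a dataset.

    Per epoch: compute the exposure count, select the easiest samples,
    minimize BCE of the re-weighted forward pass over them in seeded
    shuffled mini-batches, and update each visited sample's difficulty with
    its latest instantaneous loss.  Fully deterministic for a fixed seed.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty training set")
    classes = set(int(t) for t in dataset.targets)
    if len(classes) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)

    if model is None:
        model = build_model(dataset.input_shape, config.classifier,
                            config.generator, config.n_slabs, seed=config.seed)
    state = DifficultyState(momentum=config.ema_momentum)
    state.register(dataset.sample_ids)
    schedule = CurriculumSchedule(config.f_min, config.epochs, n)
    optimizer = Adam(model.modules(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    history = TrainingHistory()
    rng = np.random.default_rng(config.seed)
    by_id = {sid: i for i, sid in enumerate(dataset.sample_ids)}

    for epoch in range(config.epochs):
        n_e = exposure_count(schedule, epoch)
        selected = select_easiest(state, n_e)
        order = [selected[i] for i in rng.permutation(len(selected))]
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            model.zero_grad()
            for sid in batch:
                i = by_id[sid]
                logit, cache = model.forward(dataset.values[i])
                loss, dlogit = bce_loss(logit, dataset.targets[i])
                model.backward(dlogit / len(batch), cache)
                update_difficulty(state, sid, loss)
                losses.append(loss)
            optimizer.step()
        history.epoch_loss.append(float(np.mean(losses)))
        history.exposure.append(n_e)
        history.difficulty_snapshots.append(state.snapshot())
    return model, state, history


# ---------------------------------------------------------------------------
# Inference and hierarchical aggregation
# ---------------------------------------------------------------------------

def predict_dataset(model, dataset: ScanDataset) -> pd.DataFrame:
    """Scan-level predictions as a tidy frame (one row per scan)."""
    rows = []
    for sid, x in zip(dataset.sample_ids, dataset.values):
        p = model.predict_proba(x)
        rec = PredictionRecord(scan_id=sid, probability=p, level="scan")
        rows.append({"scan_id": sid, "probability": rec.probability,
                     "logit": rec.logit, "level": "scan"})
    return pd.DataFrame(rows).merge(dataset.manifest, on="scan_id", how="left")


def aggregate_predictions(records: pd.DataFrame, level: str) -> pd.DataFrame:
    """Average probabilities up the scan hierarchy.

    ``records`` must carry ``probability`` plus the manifest key columns; the
    group probability is the arithmetic mean of member probabilities, with
    the logit recomputed from the mean.  The aggregate therefore always lies
    within [min, max] of its members.
    """
    if level not in LEVEL_KEYS:
        raise ValueError(f"unknown level {level!r}")
    keys = list(LEVEL_KEYS[level])
    missing = [k for k in keys if k not in records.columns]
    if missing:
        raise ValueError(f"records lack grouping columns {missing}")
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    grouped = records.groupby(keys, as_index=False)["probability"].mean()
    grouped["logit"] = grouped["probability"].map(probability_to_logit)
    grouped["level"] = level
    grouped["group_id"] = grouped[keys].astype(str).agg("/".join, axis=1)
    return grouped
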