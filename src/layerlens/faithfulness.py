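"""Insertion/deletion faithfulness evaluation of layer rankings.

Given a ranking of the six tissue layers by claimed importance, the
insertion curve starts from an all-zero volume and restores the ranked
layers one at a time (background voxels stay zero throughout), recording
the classifier logit after each step; the deletion curve starts from the
intact scan and zeroes the ranked layers in the same order.  Both curves
include the k = 0 anchor (empty / full volume), so with K layers each has
K + 1 points and the trapezoidal summaries are::

    AUC_ins = (1/K) sum_k (i_{k-1} + i_k) / 2        (similarly AUC_del)
    AUC_delta = AUC_ins - AUC_del
    IROF = max_k i_k / (min_k d_k + eps)

A faithful ranking yields a steep insertion rise and a sharp deletion drop:
high AUC-insertion and AUC-delta, low AUC-deletion, high IROF.  Because
logits are signed, the IROF quotient is flagged when the deletion minimum
is non-positive; a probability-space variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import LayerLabelMap, MultimodalScan
from .saliency import DEFAULT_EPS, Z95, _as_values, _unpack, saliency_scores

__all__ = [
    "RankedLayerList",
    "FaithfulnessCurves",
    "FaithfulnessMetrics",
    "IrofResult",
    "insertion_curve",
    "deletion_curve",
    "auc_insertion",
    "auc_deletion",
    "auc_delta",
    "irof",
    "evaluate_ranking",
    "compare_rankers",
    "saliency_ranker",
    "random_ranker",
    "volume_ranker",
]


@dataclass
class RankedLayerList:
    """Layer codes in descending claimed importance, plus provenance."""

    layers: tuple[int, ...]
    method: str = "unspecified"

    def __post_init__(self) -> None:
        self.layers = tuple(int(c) for c in self.layers)
        if len(set(self.layers)) != len(self.layers):
            raise ValueError("ranking contains duplicate layers")
        if any(not (1 <= c <= 6) for c in self.layers):
            raise ValueError("layer codes must lie in 1..6")


class IrofResult(NamedTuple):
    value: float
    flagged: bool  # deletion minimum was non-positive


@dataclass
class FaithfulnessCurves:
    insertion: np.ndarray  # i_0 .. i_K
    deletion: np.ndarray  # d_0 .. d_K

    def __post_init__(self) -> None:
        self.insertion = np.asarray(self.insertion, dtype=float)
        self.deletion = np.asarray(self.deletion, dtype=float)
        if self.insertion.shape != self.deletion.shape:
            raise ValueError("curves must have equal length")


@dataclass
class FaithfulnessMetrics:
    auc_insertion: float
    auc_deletion: float
    auc_delta: float
    irof: float
    irof_flagged: bool = False


def _trapezoid_mean(curve: Sequence[float]) -> float:
    c = np.asarray(curve, dtype=float)
    if c.size < 2:
        raise ValueError("curve needs at least two points")
    return float(np.mean((c[:-1] + c[1:]) / 2.0))


def auc_insertion(curve: Sequence[float]) -> float:
    """Trapezoidal mean of the insertion curve."""
    return _trapezoid_mean(curve)


def auc_deletion(curve: Sequence[float]) -> float:
    """Trapezoidal mean of the deletion curve."""
    return _trapezoid_mean(curve)


def auc_delta(insertion: Sequence[float], deletion: Sequence[float]) -> float:
    return auc_insertion(insertion) - auc_deletion(deletion)


def irof(insertion: Sequence[float], deletion: Sequence[float],
         eps: float = DEFAULT_EPS) -> IrofResult:
    """Max of the insertion curve over (min of the deletion curve + eps).

    Computed as printed even when the deletion minimum is non-positive,
    but flagged in that case because the signed quotient is ill-behaved.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    ins = np.asarray(insertion, dtype=float)
    dele = np.asarray(deletion, dtype=float)
    if ins.size == 0 or dele.size == 0:
        raise ValueError("curves must be non-empty")
    dmin = float(dele.min())
    return IrofResult(float(ins.max() / (dmin + eps)), flagged=dmin <= 0.0)


# ---------------------------------------------------------------------------
# Curve construction
# ---------------------------------------------------------------------------

def insertion_curve(model, scan, labels: LayerLabelMap,
                    ranking: RankedLayerList | Sequence[int],
                    modalities: Sequence[str] | None = None) -> np.ndarray:
    """Logits while layers are cumulatively restored onto a zero volume."""
    order = _order(ranking)
    values, _ = _as_values(scan, modalities)
    _check(values, labels)
    current = np.zeros_like(values)
    curve = [model.predict_logit(current)]
    for code in order:
        mask = labels.mask(code)
        current[..., mask] = values[..., mask]
        curve.append(model.predict_logit(current))
    return np.asarray(curve)


def deletion_curve(model, scan, labels: LayerLabelMap,
                   ranking: RankedLayerList | Sequence[int],
                   modalities: Sequence[str] | None = None) -> np.ndarray:
    """Logits while layers are cumulatively zeroed from the intact scan."""
    order = _order(ranking)
    values, _ = _as_values(scan, modalities)
    _check(values, labels)
    current = values.copy()
    curve = [model.predict_logit(current)]
    for code in order:
        current[..., labels.mask(code)] = 0.0
        curve.append(model.predict_logit(current))
    return np.asarray(curve)


def _order(ranking) -> tuple[int, ...]:
    return ranking.layers if isinstance(ranking, RankedLayerList) else RankedLayerList(tuple(ranking)).layers


def _check(values: np.ndarray, labels: LayerLabelMap) -> None:
    if values.shape[-3:] != labels.shape:
        raise ValueError("label map shape does not match the scan")


def evaluate_ranking(model, scan, labels: LayerLabelMap,
                     ranking: RankedLayerList | Sequence[int],
                     eps: float = DEFAULT_EPS,
                     modalities: Sequence[str] | None = None
                     ) -> tuple[FaithfulnessCurves, FaithfulnessMetrics]:
    ins = insertion_curve(model, scan, labels, ranking, modalities)
    dele = deletion_curve(model, scan, labels, ranking, modalities)
    ir = irof(ins, dele, eps)
    metrics = FaithfulnessMetrics(
        auc_insertion=auc_insertion(ins),
        auc_deletion=auc_deletion(dele),
        auc_delta=auc_delta(ins, dele),
        irof=ir.value, irof_flagged=ir.flagged,
    )
    return FaithfulnessCurves(ins, dele), metrics


# ---------------------------------------------------------------------------
# Ranker-comparison harness
# ---------------------------------------------------------------------------

Ranker = Callable[[int, np.ndarray, LayerLabelMap], RankedLayerList]


def saliency_ranker(model, dataset: Sequence,
                    modalities: Sequence[str] | None = None) -> Ranker:
    """Dataset-level occlusion-saliency ranking (the same ranking is applied
    to every scan, as when a validation fold is explained once)."""
    table = saliency_scores(model, list(dataset), modalities=modalities)
    fixed = RankedLayerList(tuple(table.ranking("ss")), method="occlusion_saliency")

    def rank(i: int, values: np.ndarray, labels: LayerLabelMap) -> RankedLayerList:
        return fixed

    return rank


def random_ranker(seed: int) -> Ranker:
    """A fresh seeded permutation per scan index (deterministic per seed)."""

    def rank(i: int, values: np.ndarray, labels: LayerLabelMap) -> RankedLayerList:
        rng = np.random.default_rng((seed, i))
        return RankedLayerList(tuple(rng.permutation([1, 2, 3, 4, 5, 6])),
                               method="random")

    return rank


def volume_ranker() -> Ranker:
    """Layers by descending voxel count in the scan's own label map."""

    def rank(i: int, values: np.ndarray, labels: LayerLabelMap) -> RankedLayerList:
        counts = [(labels.volume(c), -c) for c in (1, 2, 3, 4, 5, 6)]
        order = sorted(range(6), key=lambda j: counts[j], reverse=True)
        return RankedLayerList(tuple(j + 1 for j in order), method="volume")

    return rank


def compare_rankers(model, dataset: Sequence, rankers: dict[str, Ranker],
                    eps: float = DEFAULT_EPS,
                    modalities: Sequence[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scan faithfulness metrics for each ranker plus a dataset summary.

    Returns ``(per_scan, summary)``; the summary carries the mean of each
    metric with a normal-approximation 95% CI, and paired mean differences
    in AUC-delta against every other ranker.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    if not rankers:
        raise ValueError("need at least one ranker")
    rows = []
    for name, ranker in rankers.items():
        for i, item in enumerate(dataset):
            sid, values, labels = _unpack(item, i, modalities)
            ranking = ranker(i, values, labels)
            _, m = evaluate_ranking(model, values, labels, ranking, eps)
            rows.append({"ranker": name, "scan_index": i, "scan_id": sid,
                         "auc_insertion": m.auc_insertion,
                         "auc_deletion": m.auc_deletion,
                         "auc_delta": m.auc_delta, "irof": m.irof,
                         "irof_flagged": m.irof_flagged})
    per_scan = pd.DataFrame(rows)
    summaries = []
    for name, sub in per_scan.groupby("ranker"):
        row: dict = {"ranker": name, "n_scans": len(sub)}
        for metric in ("auc_insertion", "auc_deletion", "auc_delta", "irof"):
            vals = sub[metric].to_numpy()
            m = float(np.mean(vals))
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            row[metric] = m
            row[f"{metric}_ci_lo"] = m - Z95 * se
            row[f"{metric}_ci_hi"] = m + Z95 * se
        for other, osub in per_scan.groupby("ranker"):
            if other == name:
                continue
            diff = (sub.set_index("scan_index")["auc_delta"]
                    - osub.set_index("scan_index")["auc_delta"])
            row[f"auc_delta_minus_{other}"] = float(diff.mean())
        summaries.append(row)
    return per_scan, pd.DataFrame(summaries)
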