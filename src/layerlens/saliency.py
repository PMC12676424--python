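"""Tissue-layer occlusion saliency.

The central operation zeroes every voxel of one tissue layer (in all
channels at once) and records the resulting change in the classifier's
log-odds.  For a scan ``I`` with layer mask ``M_i`` and classifier ``C``::

    delta_i = logit(C(I)) - logit(C(I * (1 - M_i)))

Across a dataset the signed deltas split into a positive directional
saliency score (PDSS, mean positive part) and a negative one (NDSS, minus
the mean negative part), with the layer's overall saliency score
``SS = mean |delta| = PDSS + NDSS``.  Volume-adjusted variants divide each
scan's delta by that scan's layer voxel count before averaging, measuring
information density rather than bulk.  Pairwise structure is captured by
the Pearson correlation of per-scan saliencies and the occlusion
interaction score::

    OIS_ij = (SS_ij - (SS_i + SS_j)) / max(SS_i + SS_j, eps)

positive when occluding the pair jointly hurts more than the parts
(synergy), negative when less (redundancy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LAYER_CODES, LAYER_NAMES, LayerLabelMap, MultimodalScan

__all__ = [
    "DEFAULT_EPS",
    "OcclusionDelta",
    "SaliencyTable",
    "InteractionMatrix",
    "OisResult",
    "occlude",
    "occlude_values",
    "scan_delta",
    "joint_delta",
    "saliency_scores",
    "ois",
    "saliency_correlation",
    "interaction_matrix",
]

#: Small constant guarding the OIS denominator.
DEFAULT_EPS = 1e-8

Z95 = 1.959963984540054  # normal 97.5% quantile


class OcclusionDelta(NamedTuple):
    scan_id: str
    layers: tuple[int, ...]
    delta: float
    voxels: int  # occluded voxel count in this scan


class OisResult(NamedTuple):
    value: float
    degenerate: bool  # denominator fell back to eps


# ---------------------------------------------------------------------------
# Occlusion primitives
# ---------------------------------------------------------------------------

def occlude_values(values: np.ndarray, labels: LayerLabelMap,
                   layer_codes: int | Iterable[int]) -> np.ndarray:
    """Zero the given layers' voxels in every channel of a (C, D, H, W)
    array; other voxels are untouched."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-3:] != labels.shape:
        raise ValueError("label map shape does not match the scan")
    mask = labels.mask(layer_codes)
    out = values.copy()
    out[..., mask] = 0.0
    return out


def occlude(scan: MultimodalScan, labels: LayerLabelMap,
            layer_codes: int | Iterable[int]) -> MultimodalScan:
    """Occluded copy of a scan (all channels masked simultaneously)."""
    from dataclasses import replace

    mask = labels.mask(layer_codes)
    channels = []
    for ch in scan.channels:
        vals = ch.values.copy()
        vals[mask] = 0.0
        channels.append(replace(ch, values=vals))
    return MultimodalScan(scan.scan_id, channels, scan.metadata)


def _delta(model, values: np.ndarray, labels: LayerLabelMap,
           codes: tuple[int, ...], scan_id: str, base_logit: float | None
           ) -> OcclusionDelta:
    for c in codes:
        if c not in LAYER_CODES:
            raise ValueError(f"layer code {c} outside 1..6")
    if base_logit is None:
        base_logit = model.predict_logit(values)
    occluded = occlude_values(values, labels, codes)
    d = base_logit - model.predict_logit(occluded)
    if not np.isfinite(d):
        raise ValueError("non-finite occlusion delta")
    return OcclusionDelta(scan_id, codes, float(d),
                          int(np.count_nonzero(labels.mask(codes))))


def scan_delta(model, scan: MultimodalScan | np.ndarray, labels: LayerLabelMap,
               layer: int, modalities: Sequence[str] | None = None,
               base_logit: float | None = None) -> OcclusionDelta:
    """Directional occlusion delta of a single layer on a single scan."""
    values, sid = _as_values(scan, modalities)
    return _delta(model, values, labels, (int(layer),), sid, base_logit)


def joint_delta(model, scan: MultimodalScan | np.ndarray, labels: LayerLabelMap,
                layers: Sequence[int], modalities: Sequence[str] | None = None,
                base_logit: float | None = None) -> OcclusionDelta:
    """Occlusion delta of two (or more) layers removed simultaneously."""
    codes = tuple(sorted(int(c) for c in layers))
    if len(set(codes)) != len(codes) or not codes:
        raise ValueError("layer set must be non-empty without duplicates")
    values, sid = _as_values(scan, modalities)
    return _delta(model, values, labels, codes, sid, base_logit)


def _as_values(scan, modalities) -> tuple[np.ndarray, str]:
    if isinstance(scan, MultimodalScan):
        return scan.values(modalities), scan.scan_id
    return np.asarray(scan, dtype=np.float64), "scan"


def _unpack(item, index: int, modalities) -> tuple[str, np.ndarray, LayerLabelMap]:
    """Dataset items are ``(scan, labels)`` or ``(scan_id, values, labels)``."""
    if len(item) == 3:
        sid, values, labels = item
        return str(sid), np.asarray(values, dtype=np.float64), labels
    scan, labels = item
    values, sid = _as_values(scan, modalities)
    if not isinstance(scan, MultimodalScan):
        sid = f"{sid}#{index}"
    return sid, values, labels


# ---------------------------------------------------------------------------
# Dataset-level tables
# ---------------------------------------------------------------------------

@dataclass
class SaliencyTable:
    """Per-layer dataset saliency summary plus the per-scan deltas."""

    deltas: pd.DataFrame  # scan_id, layer, delta, voxels
    n_scans: int
    ci_method: str = "normal"

    def per_scan(self, layer: int, absolute: bool = True) -> np.ndarray:
        d = self.deltas.loc[self.deltas["layer"] == layer, "delta"].to_numpy()
        return np.abs(d) if absolute else d

    def summary(self) -> pd.DataFrame:
        rows = []
        for layer in LAYER_CODES:
            sub = self.deltas[self.deltas["layer"] == layer]
            if len(sub) == 0 or (sub["voxels"] == 0).all():
                rows.append({"layer": layer, "layer_name": LAYER_NAMES[layer],
                             "n_scans": 0, "ss": np.nan, "pdss": np.nan,
                             "ndss": np.nan, "ss_ci_lo": np.nan,
                             "ss_ci_hi": np.nan, "va_ss": np.nan,
                             "va_pdss": np.nan, "va_ndss": np.nan})
                continue
            d = sub["delta"].to_numpy()
            vox = sub["voxels"].to_numpy()
            pdss = float(np.mean(np.maximum(d, 0.0)))
            ndss = float(-np.mean(np.minimum(d, 0.0)))
            absd = np.abs(d)
            ss = float(np.mean(absd))
            lo, hi = self._ci(absd)
            ok = vox > 0  # per-scan volume adjustment undefined at zero volume
            dv, voxv = d[ok], vox[ok]
            rows.append({
                "layer": layer, "layer_name": LAYER_NAMES[layer],
                "n_scans": int(len(sub)), "ss": ss, "pdss": pdss, "ndss": ndss,
                "ss_ci_lo": lo, "ss_ci_hi": hi,
                "va_ss": float(np.mean(np.abs(dv) / voxv)),
                "va_pdss": float(np.mean(np.maximum(dv, 0.0) / voxv)),
                "va_ndss": float(-np.mean(np.minimum(dv, 0.0) / voxv)),
            })
        return pd.DataFrame(rows)

    def _ci(self, absd: np.ndarray, n_boot: int = 1000, seed: int = 0
            ) -> tuple[float, float]:
        m = float(np.mean(absd))
        if len(absd) < 2:
            return m, m
        if self.ci_method == "bootstrap":
            rng = np.random.default_rng(seed)
            means = rng.choice(absd, size=(n_boot, len(absd)), replace=True).mean(axis=1)
            return float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))
        se = float(np.std(absd, ddof=1) / np.sqrt(len(absd)))
        return m - Z95 * se, m + Z95 * se

    def ss(self, layer: int) -> float:
        row = self.summary().set_index("layer").loc[layer]
        return float(row["ss"])

    def ranking(self, by: str = "ss") -> list[int]:
        """Layer codes ordered by descending score (NaN layers last)."""
        s = self.summary().set_index("layer")[by]
        return list(s.sort_values(ascending=False, na_position="last").index)


def saliency_scores(model, dataset: Iterable, ci_method: str = "normal",
                    modalities: Sequence[str] | None = None) -> SaliencyTable:
    """Occlusion saliency of every layer over a dataset.

    ``dataset`` yields ``(scan, labels)`` pairs where ``scan`` is a
    :class:`MultimodalScan` or a value array.  The 95% CI for SS is the
    normal approximation ``mean +/- 1.96 SE`` over scans by default, or a
    seeded bootstrap with ``ci_method="bootstrap"``.
    """
    records = []
    n = 0
    for item in dataset:
        sid, values, labels = _unpack(item, n, modalities)
        base = model.predict_logit(values)
        for layer in LAYER_CODES:
            if labels.volume(layer) == 0:
                records.append((sid, layer, 0.0, 0))
                continue
            od = _delta(model, values, labels, (layer,), sid, base)
            records.append((sid, layer, od.delta, od.voxels))
        n += 1
    if n == 0:
        raise ValueError("empty dataset")
    deltas = pd.DataFrame(records, columns=["scan_id", "layer", "delta", "voxels"])
    return SaliencyTable(deltas=deltas, n_scans=n, ci_method=ci_method)


# ---------------------------------------------------------------------------
# Pairwise structure
# ---------------------------------------------------------------------------

def ois(ss_i: float, ss_j: float, ss_ij: float, eps: float = DEFAULT_EPS
        ) -> OisResult:
    """Occlusion interaction score of a layer pair from dataset-level
    saliencies; flagged degenerate when ``ss_i + ss_j < eps``."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    s = ss_i + ss_j
    return OisResult(float((ss_ij - s) / max(s, eps)), degenerate=s < eps)


def saliency_correlation(scores_i: Sequence[float], scores_j: Sequence[float]
                         ) -> float:
    """Pearson correlation of two per-scan saliency sequences; NaN when
    either sequence has zero variance or fewer than 3 scans."""
    a = np.asarray(scores_i, dtype=float)
    b = np.asarray(scores_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class InteractionMatrix:
    """Symmetric 6x6 inter-layer structure; diagonals are NaN."""

    correlation: np.ndarray
    ois_values: np.ndarray
    ois_degenerate: np.ndarray
    layers: tuple[int, ...] = LAYER_CODES

    def to_frames(self) -> dict[str, pd.DataFrame]:
        names = [LAYER_NAMES[c] for c in self.layers]
        return {
            "correlation": pd.DataFrame(self.correlation, index=names, columns=names),
            "ois": pd.DataFrame(self.ois_values, index=names, columns=names),
        }


def interaction_matrix(model, dataset: Sequence, eps: float = DEFAULT_EPS,
                       signed_correlation: bool = False,
                       modalities: Sequence[str] | None = None
                       ) -> InteractionMatrix:
    """Pearson correlations of per-scan saliencies and pairwise OIS over a
    dataset.  ``dataset`` is a sequence of ``(scan, labels)`` pairs (it is
    traversed several times).  Per-scan correlation uses |delta| unless
    ``signed_correlation``.
    """
    dataset = list(dataset)
    table = saliency_scores(model, dataset, modalities=modalities)
    k = len(LAYER_CODES)
    rho = np.full((k, k), np.nan)
    ois_m = np.full((k, k), np.nan)
    degen = np.zeros((k, k), dtype=bool)
    per_scan = {
        c: table.per_scan(c, absolute=not signed_correlation) for c in LAYER_CODES
    }
    single_ss = {c: table.ss(c) for c in LAYER_CODES}
    for a in range(k):
        for b in range(a + 1, k):
            ci, cj = LAYER_CODES[a], LAYER_CODES[b]
            rho[a, b] = rho[b, a] = saliency_correlation(per_scan[ci], per_scan[cj])
            joint = []
            for n, item in enumerate(dataset):
                _, values, labels = _unpack(item, n, modalities)
                joint.append(abs(joint_delta(model, values, labels, (ci, cj)).delta))
            res = ois(single_ss[ci], single_ss[cj], float(np.mean(joint)), eps)
            ois_m[a, b] = ois_m[b, a] = res.value
            degen[a, b] = degen[b, a] = res.degenerate
    return InteractionMatrix(rho, ois_m, degen)
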