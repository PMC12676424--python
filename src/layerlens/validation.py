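"""Validation of occlusion explanations: model-randomization sanity check
and directional-saliency association tests.

The sanity check re-initializes every model parameter from the
architecture's seeded initialization scheme and recomputes the full
saliency table: if explanations derive from learned structure, saliency
magnitudes collapse (collapse ratio = trained / randomized mean > 1).

The association test asks whether a layer's directional saliency carries
clinical signal: per side, the score ``S`` (mean PDSS or NDSS over the
side's scans) enters a univariate logistic model
``logit P(MP=1) = beta0 + beta1 S`` fitted by maximum likelihood, with
Wald 95% CI and p-value for ``beta1`` and the in-sample ROC AUC.  The
pre-specified directional criterion is ``beta1 > 0`` with ``p < 0.05`` for
PDSS (an MP-driving layer should raise MP odds); for NDSS the expected
sign defaults to negative, since a control-driving layer should lower
them.  Complete separation is flagged and refitted with a ridge-penalized
likelihood rather than crashing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import LAYER_CODES, LAYER_NAMES
from .models import CarnModel
from .saliency import SaliencyTable, saliency_scores

__all__ = [
    "SanityReport",
    "AssociationResult",
    "randomization_sanity",
    "logistic_association",
    "roc_auc",
    "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# Model-randomization sanity check
# ---------------------------------------------------------------------------

@dataclass
class SanityReport:
    mean_trained: float
    mean_randomized: float
    collapse_ratio: float  # trained / randomized; inf-flagged when denominator 0
    ratio_defined: bool
    per_layer: pd.DataFrame  # layer, ss_trained, ss_randomized, ratio
    seed: int


def randomization_sanity(model: CarnModel, dataset: Sequence, seed: int,
                         modalities: Sequence[str] | None = None
                         ) -> SanityReport:
    """Compare saliency magnitudes of a trained model against the same
    architecture with freshly re-drawn parameters.

    The trained model is left untouched (parameters are restored after the
    randomized pass).
    """
    dataset = list(dataset)
    trained = saliency_scores(model, dataset, modalities=modalities).summary()
    saved = [{k: v.copy() for k, v in m.params.items()} for m in model.modules()]
    try:
        model.reinitialize(seed)
        randomized = saliency_scores(model, dataset, modalities=modalities).summary()
    finally:
        for m, params in zip(model.modules(), saved):
            for k, v in params.items():
                m.params[k][...] = v
    per_layer = pd.DataFrame({
        "layer": trained["layer"],
        "layer_name": trained["layer_name"],
        "ss_trained": trained["ss"],
        "ss_randomized": randomized["ss"],
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        per_layer["ratio"] = per_layer["ss_trained"] / per_layer["ss_randomized"]
    mt = float(np.nanmean(trained["ss"]))
    mr = float(np.nanmean(randomized["ss"]))
    defined = mr > 0
    return SanityReport(
        mean_trained=mt, mean_randomized=mr,
        collapse_ratio=mt / mr if defined else float("inf"),
        ratio_defined=defined, per_layer=per_layer, seed=seed,
    )


# ---------------------------------------------------------------------------
# ROC AUC (Mann-Whitney formulation)
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Univariate logistic association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    layer: int
    score_type: str  # "pdss" or "ndss"
    beta1: float
    ci_lo: float
    ci_hi: float
    p_value: float
    auc: float
    criterion_met: bool
    expected_sign: int
    separation_flagged: bool = False

    def to_row(self) -> dict:
        return {
            "layer": self.layer,
            "layer_name": LAYER_NAMES.get(self.layer, str(self.layer)),
            "score_type": self.score_type, "beta1": self.beta1,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "p": self.p_value,
            "auc": self.auc, "criterion_met": self.criterion_met,
            "separation_flagged": self.separation_flagged,
        }


DEFAULT_EXPECTED_SIGN = {"pdss": +1, "ndss": -1}


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float = 1.0,
                 n_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized Newton fit of a univariate logistic model; returns
    (coef, covariance) from the penalized Hessian.  Used as the fallback
    under complete separation, where the unpenalized MLE diverges."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    lam = np.array([0.0, alpha])  # penalize the slope only
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (y - p) - lam * beta
        W = p * (1 - p)
        H = (X * W[:, None]).T @ X + np.diag(lam)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -35, 35)
    p = 1.0 / (1.0 + np.exp(-eta))
    H = (X * (p * (1 - p))[:, None]).T @ X + np.diag(lam)
    return beta, np.linalg.inv(H)


def logistic_association(scores: Sequence[float], labels: Sequence[int],
                         layer: int = 0, score_type: str = "pdss",
                         expected_sign: int | None = None,
                         alpha: float = 0.05,
                         inference: str = "wald") -> AssociationResult:
    """Fit ``logit P(MP=1) = beta0 + beta1 S`` and apply the directional
    significance criterion.

    ``expected_sign`` overrides the per-score-type default (+1 for PDSS,
    -1 for NDSS).  ``inference="lr"`` swaps the Wald p-value for the
    likelihood-ratio test (the CI stays Wald).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least two observations of each class")
    if score_type not in DEFAULT_EXPECTED_SIGN:
        raise ValueError("score_type must be 'pdss' or 'ndss'")
    sign = expected_sign if expected_sign is not None else DEFAULT_EXPECTED_SIGN[score_type]

    X = sm.add_constant(x)
    separation = False
    beta1 = se = np.nan
    p_value = np.nan
    llf = lln = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> raise
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta1 = float(fit.params[1])
        se = float(fit.bse[1])
        p_value = float(fit.pvalues[1])
        llf, lln = float(fit.llf), float(fit.llnull)
        if not np.isfinite(se) or abs(beta1) > 1e3 * max(1.0, 1.0 / (np.std(x) + 1e-12)):
            separation = True
    except Exception:
        separation = True
    if separation:
        coef, cov = _ridge_logit(x, y)
        beta1 = float(coef[1])
        se = float(np.sqrt(cov[1, 1]))
        p_value = 2.0 * float(stats.norm.sf(abs(beta1 / se))) if se > 0 else np.nan
        llf = lln = None
    elif inference == "lr" and llf is not None:
        p_value = float(stats.chi2.sf(2.0 * (llf - lln), df=1))

    ci_lo, ci_hi = beta1 - 1.959963984540054 * se, beta1 + 1.959963984540054 * se
    # the fitted probability is strictly monotone in beta1 * x, so its AUC
    # equals the AUC of beta1 * x (all-tie convention covers beta1 == 0)
    auc = roc_auc(beta1 * x, y)
    met = bool(np.isfinite(p_value) and p_value < alpha and np.sign(beta1) == sign)
    return AssociationResult(layer=layer, score_type=score_type, beta1=beta1,
                             ci_lo=ci_lo, ci_hi=ci_hi, p_value=p_value, auc=auc,
                             criterion_met=met, expected_sign=sign,
                             separation_flagged=separation)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional multiple-testing correction)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def associate_layers(table_pos: pd.DataFrame, side_labels: pd.Series,
                     score_type: str = "pdss") -> pd.DataFrame:
    """Convenience wrapper: one association fit per layer from a frame of
    per-side scores (columns = layer codes)."""
    rows = []
    y = side_labels.to_numpy().astype(int)
    for layer in LAYER_CODES:
        if layer not in table_pos.columns:
            continue
        res = logistic_association(table_pos[layer].to_numpy(), y,
                                   layer=layer, score_type=score_type)
        rows.append(res.to_row())
    return pd.DataFrame(rows)
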