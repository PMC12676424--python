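"""End-to-end pipeline: simulate -> train -> explain -> faithfulness ->
sanity -> associate, with every artifact written as flat CSV stamped with
the seed and config hash that produced it."""

from __future__ import annotations

import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash, stage_seed
from .faithfulness import compare_rankers, random_ranker, saliency_ranker, volume_ranker
from .models import load_model, save_model
from .phantoms import PhantomConfig, generate_cohort, load_cohort, write_cohort
from .saliency import interaction_matrix, saliency_scores
from .training import TrainConfig, aggregate_predictions, build_dataset, predict_dataset, train
from .validation import associate_layers, randomization_sanity

__all__ = ["run_pipeline", "StageError"]

log = logging.getLogger("layerlens")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stamp(frame: pd.DataFrame, config: RunConfig, seed: int) -> pd.DataFrame:
    frame = frame.copy()
    frame["seed"] = seed
    frame["config_hash"] = config_hash(config)
    return frame


def _write(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order; any failure aborts with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    # -- simulate ----------------------------------------------------------
    try:
        stage("simulate")
        if config.cohort_dir is not None:
            cohort_dir = Path(config.cohort_dir)
            if not (cohort_dir / "manifest.csv").exists():
                raise FileNotFoundError(f"no manifest in {cohort_dir}")
            cohort = load_cohort(cohort_dir)
        else:
            pc = PhantomConfig(**config.phantom.model_dump(),
                               seed=stage_seed(config, "simulate"))
            cohort = generate_cohort(pc)
            write_cohort(cohort, out / "cohort")
    except Exception as e:
        raise StageError("simulate", e) from e

    # -- train -------------------------------------------------------------
    try:
        stage("train")
        tb = config.training
        dataset = build_dataset(cohort, tb.modalities, tb.target)
        if config.model_dir is not None:
            model = load_model(config.model_dir)
            history = None
        else:
            tc = TrainConfig(
                epochs=tb.epochs, f_min=tb.f_min, ema_momentum=tb.ema_momentum,
                learning_rate=tb.learning_rate, batch_size=tb.batch_size,
                seed=stage_seed(config, "train"), classifier=tb.classifier,
                generator=tb.generator, n_slabs=tb.n_slabs,
            )
            model, state, history = train(dataset, tc)
            save_model(model, out / "model")
            _write(_stamp(history.to_frame(), config, tc.seed),
                   out / "training_history.csv")
            diff = pd.DataFrame(
                [{"sample_id": k, "difficulty": v}
                 for k, v in state.snapshot().items()])
            _write(_stamp(diff, config, tc.seed), out / "difficulty_state.csv")
        preds = predict_dataset(model, dataset)
        _write(_stamp(preds, config, config.seed), out / "predictions_scan.csv")
        for level in ("side", "visit", "patient"):
            _write(_stamp(aggregate_predictions(preds, level), config, config.seed),
                   out / f"predictions_{level}.csv")
    except StageError:
        raise
    except Exception as e:
        raise StageError("train", e) from e

    pairs = [(sid, v, cohort.label_maps[sid])
             for sid, v in zip(dataset.sample_ids, dataset.values)]

    # -- explain -----------------------------------------------------------
    try:
        stage("explain")
        table = saliency_scores(model, pairs, ci_method=config.saliency.ci_method)
        _write(_stamp(table.deltas, config, config.seed), out / "saliency_deltas.csv")
        _write(_stamp(table.summary(), config, config.seed), out / "saliency_table.csv")
        inter = interaction_matrix(
            model, pairs, eps=config.saliency.eps,
            signed_correlation=config.saliency.signed_correlation)
        for name, frame in inter.to_frames().items():
            _write(frame, out / f"interaction_{name}.csv")
    except Exception as e:
        raise StageError("explain", e) from e

    # -- faithfulness ------------------------------------------------------
    try:
        stage("faithfulness")
        rankers = {}
        for name in config.faithfulness.rankers:
            if name == "saliency":
                rankers[name] = saliency_ranker(model, pairs)
            elif name == "random":
                rankers[name] = random_ranker(stage_seed(config, "faithfulness"))
            elif name == "volume":
                rankers[name] = volume_ranker()
            else:
                raise ValueError(f"unknown ranker {name!r}")
        per_scan, summary = compare_rankers(model, pairs, rankers,
                                            eps=config.saliency.eps)
        _write(_stamp(per_scan, config, config.seed), out / "faithfulness_per_scan.csv")
        _write(_stamp(summary, config, config.seed), out / "faithfulness_summary.csv")
    except Exception as e:
        raise StageError("faithfulness", e) from e

    # -- sanity ------------------------------------------------------------
    try:
        stage("sanity")
        rows = []
        for r in range(config.sanity_replicates):
            rep = randomization_sanity(model, pairs,
                                       seed=stage_seed(config, f"sanity-{r}"))
            rows.append({"replicate": r, "mean_trained": rep.mean_trained,
                         "mean_randomized": rep.mean_randomized,
                         "collapse_ratio": rep.collapse_ratio,
                         "ratio_defined": rep.ratio_defined})
        _write(_stamp(pd.DataFrame(rows), config, config.seed), out / "sanity.csv")
    except Exception as e:
        raise StageError("sanity", e) from e

    # -- associate ---------------------------------------------------------
    try:
        stage("associate")
        manifest = dataset.manifest
        merged = table.deltas.merge(manifest, left_on="scan_id", right_on="scan_id")
        merged["positive_part"] = np.maximum(merged["delta"], 0.0)
        per_side = merged.pivot_table(index=["patient_id", "visit", "side"],
                                      columns="layer", values="positive_part",
                                      aggfunc="mean")
        side_y = (manifest.assign(pos=manifest["scan_label"] != "control")
                  .groupby(["patient_id", "visit", "side"])["pos"].max())
        side_y = side_y.reindex(per_side.index)
        if side_y.nunique() < 2:
            log.warning("single-class sides; association skipped")
        else:
            assoc = associate_layers(per_side.reset_index(drop=True), side_y,
                                     score_type="pdss")
            _write(_stamp(assoc, config, config.seed), out / "association.csv")
    except Exception as e:
        raise StageError("associate", e) from e

    stage("done")
    return out
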