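"""End-to-end pipeline: simulate -> preprocess -> train -> evaluate ->
prescribe, with a run manifest binding the artifacts together."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import CohortSpec, generate_cohort, write_cohort_csv
from .config import RunConfig, serialize_config
from .extractor import ExtractorConfig, save_checkpoint, train_extractor
from .gbm import GBMConfig, fit_gbm, predict_proba, save_gbm
from .preprocess import make_folds, records_to_compact, standardize, tensorize
from .prescribe import map_prescription, metric_shap, rank_deficiencies
from .trial import evaluate_cv

log = logging.getLogger("fitrx")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def extractor_config_from(cfg: RunConfig) -> ExtractorConfig:
    e = cfg.extractor
    return ExtractorConfig(
        conv_filters=tuple(e.conv_filters),
        kernel=e.kernel,
        stride=e.stride,
        heads=e.heads,
        attn_dropout=e.attn_dropout,
        lambda_attn=e.lambda_attn,
        metric_weights=tuple(e.metric_weights),
        lr=e.lr,
        l2=e.l2,
        hidden_noise=e.hidden_noise,
        patience=e.patience,
        max_epochs=e.max_epochs,
        batch_size=e.batch_size,
        seed=cfg.seed,
    )


def gbm_config_from(cfg: RunConfig) -> GBMConfig:
    g = cfg.gbm
    return GBMConfig(
        n_trees=g.n_trees,
        learning_rate=g.learning_rate,
        num_leaves=g.num_leaves,
        lambda_l1=g.lambda_l1,
        lambda_l2=g.lambda_l2,
        one_vs_rest=g.one_vs_rest,
        seed=cfg.seed,
    )


def metric_summaries(X_compact: np.ndarray) -> np.ndarray:
    """Collapse the compact matrix to the four per-metric summaries used by
    the attribution layer: total run time, pull-ups, sit-ups, shuttle time."""
    return np.column_stack(
        [X_compact[:, :15].sum(axis=1), X_compact[:, 15], X_compact[:, 16], X_compact[:, 17]]
    )


def summaries_to_compact(s: np.ndarray) -> np.ndarray:
    """Expand metric summaries back to a flat-pace compact matrix (the lap
    profile is unobserved at prescription time, so laps are set to the even
    split of the run total)."""
    laps = np.repeat(s[:, [0]] / 15.0, 15, axis=1)
    return np.hstack([laps, s[:, 1:]])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and write all artifacts + manifest."""
    t0 = time.time()
    run_dir = Path(cfg.out_dir) / cfg.config_hash()
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    (run_dir / "config.json").write_text(serialize_config(cfg))

    def stage(name):
        def deco(fn):
            start = time.time()
            log.info("stage %s (seed=%d)", name, cfg.seed)
            try:
                out = fn()
            except Exception:
                manifest["stages"][name] = {"status": "failed"}
                (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                log.error("stage %s failed; manifest written", name)
                raise
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - start, 3),
            }
            return out
        return deco

    @stage("simulate")
    def records():
        spec = CohortSpec(n=cfg.cohort.n, class_proportions=cfg.cohort.class_proportions,
                          seed=cfg.seed)
        recs = generate_cohort(spec)
        write_cohort_csv(recs, run_dir / "cohort.csv", spec)
        manifest["input_hashes"] = {"cohort.csv": _sha256(run_dir / "cohort.csv")}
        return recs

    @stage("preprocess")
    def folds():
        X, y = records_to_compact(records)
        plan = make_folds(X, y, n_folds=cfg.cv.folds, smote_k=cfg.smote.k,
                          noise_sigma=cfg.noise.sigma, seed=cfg.seed)
        plan.write_manifest_csv(run_dir / "augmentation_manifest.csv")
        return X, y, plan

    X, y, plan = folds

    @stage("evaluate")
    def report():
        rep = evaluate_cv(X, y, plan, extractor_config_from(cfg), gbm_config_from(cfg))
        (run_dir / "report.json").write_text(
            json.dumps(
                {
                    "pooled_accuracy": rep.pooled_accuracy,
                    "pooled_macro_f1": rep.pooled_macro_f1,
                    "pooled_macro_auc": rep.pooled_macro_auc,
                    "per_fold": rep.per_fold.to_dict(orient="records"),
                    "confusion": rep.confusion.tolist(),
                },
                indent=2,
            )
        )
        np.savetxt(run_dir / "confusion.csv", rep.confusion, fmt="%d", delimiter=",")
        return rep

    @stage("train_final")
    def final_models():
        # final extractor + GBM on a single stratified split (fold 0)
        fold = plan.folds[0]
        model, _ = train_extractor(
            tensorize(fold.X_train), fold.y_train,
            tensorize(fold.X_val), fold.y_val,
            extractor_config_from(cfg),
        )
        save_checkpoint(model, run_dir / "extractor.ckpt")
        z = model.embed_views(tensorize(fold.X_train))
        gbm = fit_gbm(z, fold.y_train, gbm_config_from(cfg))
        save_gbm(gbm, run_dir / "gbm.model",
                 extractor_hash=_sha256(run_dir / "extractor.ckpt.npz"))
        return fold, model, gbm

    fold, model, gbm = final_models

    @stage("prescribe")
    def plans():
        # prescriptions for the first few validation subjects
        stats = fold.stats
        Xval = X[fold.val_idx]
        background = metric_summaries(X)

        def pipeline_fn(summaries):
            compact = summaries_to_compact(summaries)
            std, _ = standardize(compact, stats)
            z = model.embed_views(tensorize(std))
            return predict_proba(gbm, z)

        out = []
        for i in range(min(3, len(Xval))):
            attr = metric_shap(pipeline_fn, metric_summaries(Xval[[i]])[0], background)
            defs = rank_deficiencies(attr)
            plan_i = map_prescription(defs, emphasis_load=cfg.prescription.emphasis_load)
            out.append({
                "subject": int(fold.val_idx[i]),
                "predicted_class": attr.predicted_class.name,
                "contributions": attr.contributions,
                "deficiencies": defs,
                "plan": json.loads(plan_i.to_json()),
            })
        (run_dir / "plans.json").write_text(json.dumps(out, indent=2))
        return out

    manifest["total_seconds"] = round(time.time() - t0, 3)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "run_dir": run_dir,
        "report": report,
        "plans": plans,
        "manifest": manifest,
    }
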