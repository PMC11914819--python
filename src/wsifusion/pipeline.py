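"""End-to-end orchestration: cohort splitting, per-level training, fusion,
metrics, the slide-level statistical suite, and artifact writing.

A run consumes a cohort manifest (slide_id, label, path), walks every slide
through aligned-triple extraction and filtering, trains one reference
classifier per pyramid level (or substitutes a ground-truth oracle
backend), grid-searches the fusion weights, and writes a results bundle:
patch manifest, per-level and combined metrics, fusion weights, threshold
curves, and the beta/bootstrap statistics.  Every stage is seeded from
named streams derived from the experiment seed, so a rerun with the same
seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import classifier as clf
from . import evaluation as ev
from .filtering import FilterConfig, circular_mask, keep_triple
from .fusion import FusionWeights, GridSearchResult, grid_search_weights, normalized_weights
from .pyramid import PyramidImage, aligned_patch_triples, load_pyramid, read_triple
from .synthetic_wsi import CLASSES

logger = logging.getLogger(__name__)

N_LEVELS = 3


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs up to the stage remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(seed: int, stream: str) -> int:
    """Named, independent integer seed stream below 2**31."""
    tag = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence((int(seed), tag))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Everything a run needs; defaults mirror the full-scale protocol
    (512-px patches, 8192-px display regions of 256-px tiles)."""

    mode: str = "train_test"  # or "kfold"
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    k: int = 4
    patch_size: int = 512
    stride: int | None = None
    tile_size: int = 256
    region_size: int = 8192
    filter: FilterConfig = field(default_factory=FilterConfig)
    train: clf.TrainConfig = field(default_factory=clf.TrainConfig)
    fusion_step: float = 0.001
    grid_pool: str = "validation"  # or "all": the all-patches procedure
    seed: int = 0
    tie_break: str = "MEN"

    def __post_init__(self) -> None:
        if self.mode not in ("train_test", "kfold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.grid_pool not in ("validation", "all"):
            raise ValueError(f"unknown grid_pool {self.grid_pool!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ratios"] = list(self.ratios)
        return d


def synthetic_study_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Desk-scale profile for the synthetic cohorts: 2048-px slides carry
    128-px coarsest rasters, so patches shrink to 64 px (stride 32) and the
    display regions to one whole slide of 32-px tiles.  The fusion weights
    are searched over the full extracted-patch pool."""
    defaults = dict(
        patch_size=64,
        stride=16,
        tile_size=32,
        region_size=2048,
        grid_pool="all",
        seed=seed,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


# --------------------------------------------------------------------------
# Splitting


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    raw = [r * n for r in ratios]
    counts = [int(np.floor(v)) for v in raw]
    for _ in range(n - sum(counts)):
        i = int(np.argmax([v - c for v, c in zip(raw, counts)]))
        counts[i] += 1
        raw[i] = counts[i]  # do not pick the same slot twice
    return counts


def split_cohort(manifest: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Slide-level, class-stratified split assignment.

    Returns the manifest with a ``split`` column: train/val/test for a
    train-test run, fold0..fold{k-1} for k-fold.  Deterministic in the
    experiment seed; no slide ever appears in two splits.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "split"))
    out = manifest.copy().reset_index(drop=True)
    out["split"] = ""
    for label in sorted(out["label"].unique()):
        idx = out.index[out["label"] == label].to_numpy()
        order = rng.permutation(len(idx))
        if config.mode == "train_test":
            n_tr, n_val, n_te = _largest_remainder(len(idx), config.ratios)
            names = ["train"] * n_tr + ["val"] * n_val + ["test"] * n_te
        else:
            if len(idx) < config.k:
                raise ValueError(
                    f"class {label} has {len(idx)} slides, fewer than k={config.k}"
                )
            names = [f"fold{i % config.k}" for i in range(len(idx))]
        for pos, name in zip(order, names):
            out.loc[idx[pos], "split"] = name
    assert out["slide_id"].is_unique, "slide leakage: duplicated slide ids"
    return out


# --------------------------------------------------------------------------
# Patch extraction


@dataclass
class PatchTable:
    """Flat table of kept patch triples: features per level plus bookkeeping."""

    slide_id: list[str]
    label: list[str]
    split: list[str]
    triple_id: list[int]
    features: list[np.ndarray]  # one (3, 26) block per kept triple
    manifest_rows: list[dict]  # full per-window manifest incl. dropped triples

    @property
    def n(self) -> int:
        return len(self.triple_id)

    def feature_matrix(self, level: int, mask: np.ndarray | None = None) -> np.ndarray:
        X = np.stack([f[level] for f in self.features]) if self.features else np.empty((0, clf.N_FEATURES))
        return X if mask is None else X[mask]

    def mask_for(self, splits: set[str]) -> np.ndarray:
        return np.array([s in splits for s in self.split], dtype=bool)


def extract_patches(
    split_manifest: pd.DataFrame, cohort_dir: Path, config: ExperimentConfig
) -> PatchTable:
    """Walk every slide: aligned triples, filtering (the level-0 window
    decides for the triple), optional circular masking, feature extraction."""
    table = PatchTable([], [], [], [], [], [])
    for row in split_manifest.itertuples(index=False):
        pyramid = load_pyramid(cohort_dir / row.path)
        triples = aligned_patch_triples(pyramid, config.patch_size, config.stride)
        for triple in triples:
            patches = read_triple(pyramid, triple)
            kept, reason = keep_triple(patches, config.filter)
            for w in triple.windows:
                table.manifest_rows.append(
                    {
                        "slide_id": row.slide_id,
                        "triple_id": triple.triple_id,
                        "level": w.level,
                        "x": w.x,
                        "y": w.y,
                        "size": w.size,
                        "kept_flag": int(kept),
                        "reason": reason,
                    }
                )
            if not kept:
                continue
            if config.filter.circular_mask_enabled:
                patches = [circular_mask(p, config.filter.mask_fill) for p in patches]
            feats = np.stack([clf.extract_features(p) for p in patches])
            table.slide_id.append(row.slide_id)
            table.label.append(row.label)
            table.split.append(row.split)
            table.triple_id.append(triple.triple_id)
            table.features.append(feats)
    logger.info(
        "extracted %d kept triples from %d slides", table.n, len(split_manifest)
    )
    return table


# --------------------------------------------------------------------------
# Training and prediction


def _train_and_predict(
    table: PatchTable, config: ExperimentConfig, backend: str
) -> tuple[np.ndarray, list[clf.ReferenceModel] | None]:
    """Per-level MEN probabilities for every kept triple, shape (3, n).

    Reference backend: train-test mode trains one model per level on the
    train split and predicts everywhere; k-fold trains per fold on the
    complement and predicts out of fold, pooling held-out predictions.
    Oracle backend: probabilities are the ground-truth one-hot.
    """
    n = table.n
    labels = np.array(table.label)
    if backend == "oracle":
        p_men = np.tile((labels == "MEN").astype(np.float64), (N_LEVELS, 1))
        return p_men, None
    if backend != "reference":
        raise ValueError(f"unknown backend {backend!r}")

    p_men = np.full((N_LEVELS, n), np.nan)
    models: list[clf.ReferenceModel] = []
    if config.mode == "train_test":
        train_mask = table.mask_for({"train"})
        if train_mask.sum() == 0:
            raise ValueError("no training patches after filtering")
        for lvl in range(N_LEVELS):
            model = clf.fit_reference(
                table.feature_matrix(lvl, train_mask), labels[train_mask], config.train
            )
            probs = clf.predict_proba_features(model, table.feature_matrix(lvl))
            p_men[lvl] = probs[:, 0]
            models.append(model)
        return p_men, models
    # k-fold: pooled out-of-fold predictions
    splits = np.array(table.split)
    for fold in range(config.k):
        held = splits == f"fold{fold}"
        rest = ~held
        if held.sum() == 0:
            continue
        for lvl in range(N_LEVELS):
            model = clf.fit_reference(
                table.feature_matrix(lvl, rest), labels[rest], config.train
            )
            probs = clf.predict_proba_features(model, table.feature_matrix(lvl, held))
            p_men[lvl, held] = probs[:, 0]
            if fold == 0:
                models.append(model)
    return p_men, models or None


def _pool_masks(table: PatchTable, config: ExperimentConfig) -> dict[str, np.ndarray]:
    """Evaluation pools: the fusion-search pool and the held-out pool."""
    n = table.n
    all_mask = np.ones(n, dtype=bool)
    if config.mode == "kfold":
        return {"fusion_pool": all_mask, "eval": all_mask}
    fusion = table.mask_for({"val"}) if config.grid_pool == "validation" else all_mask
    if fusion.sum() == 0:
        fusion = all_mask
    return {"fusion_pool": fusion, "eval": table.mask_for({"test"})}


def _patch_predictions(
    p_men: np.ndarray, weights: FusionWeights, tie_break: str
) -> tuple[np.ndarray, np.ndarray]:
    """(per-level predicted-MEN booleans (3, n), combined booleans (n,))."""
    level_pred = p_men >= 0.5
    combined_score = weights.as_array() @ p_men
    if tie_break == "MEN":
        combined = combined_score >= 0.5
    else:
        combined = combined_score > 0.5
    return level_pred, combined


def _metrics_block(
    pred_men: np.ndarray, labels: np.ndarray
) -> dict:
    preds = np.where(pred_men, "MEN", "SFT")
    counts = ev.confusion_counts(list(preds), list(labels))
    return ev.compute_metrics(counts).rounded()


# --------------------------------------------------------------------------
# Results bundle


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    n_triples: int
    n_kept: int
    per_level_acc: dict
    combined_acc: dict
    weights: FusionWeights
    grid_accuracy: float
    normalized_acc_weights: FusionWeights | None
    metrics: dict
    beta_men: ev.BetaParams | None
    beta_sft: ev.BetaParams | None
    t_at_j_max: float | None
    j_max: float | None
    slide_accuracy: float | None
    slide_fractions: list[ev.SlideFraction]
    bootstrap: dict
    p_fp: float | None
    p_fn: float | None
    confidences: dict


def run_experiment(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: ExperimentConfig | None = None,
    backend: str = "reference",
    visualize: bool = False,
) -> ExperimentResult:
    """Execute every stage and write the results bundle to ``out_dir``.

    Stages: extract -> split -> train -> fuse -> evaluate (-> visualize).
    Any stage failure aborts with a stage-tagged error; artifacts written by
    earlier stages are retained.
    """
    config = config or ExperimentConfig()
    manifest_path = Path(manifest_path)
    cohort_dir = manifest_path.parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    with stage("split"):
        manifest = pd.read_csv(manifest_path)
        split_manifest = split_cohort(manifest, config)
        split_manifest.to_csv(out_dir / "split.csv", index=False)

    with stage("extract"):
        table = extract_patches(split_manifest, cohort_dir, config)
        pd.DataFrame(table.manifest_rows).to_csv(out_dir / "patches.csv", index=False)
        if table.n == 0:
            raise ValueError("no patches survived filtering")

    with stage("train"):
        p_men, models = _train_and_predict(table, config, backend)
        if models:
            for lvl, model in enumerate(models):
                model.save(out_dir / f"model_level{lvl}.json")

    labels = np.array(table.label)
    y_men = labels == "MEN"

    with stage("fuse"):
        pools = _pool_masks(table, config)
        fmask = pools["fusion_pool"]
        search = grid_search_weights(
            [p_men[lvl, fmask] for lvl in range(N_LEVELS)],
            list(labels[fmask]),
            step=config.fusion_step,
            tie_break=config.tie_break,
        )
        weights = search.weights
        level_acc_pool = [
            float(np.mean((p_men[lvl, fmask] >= 0.5) == y_men[fmask]))
            for lvl in range(N_LEVELS)
        ]
        norm_weights = (
            normalized_weights(level_acc_pool) if min(level_acc_pool) > 0 else None
        )
        (out_dir / "weights.json").write_text(
            weights.to_json(search={"step": search.step, "accuracy": search.accuracy})
        )

    with stage("evaluate"):
        level_pred, combined_pred = _patch_predictions(p_men, weights, config.tie_break)
        per_level_acc: dict = {}
        combined_acc: dict = {}
        metrics: dict = {}
        for pool_name, mask in pools.items():
            if mask.sum() == 0:
                continue
            metrics[pool_name] = {
                f"level{lvl}": _metrics_block(level_pred[lvl, mask], labels[mask])
                for lvl in range(N_LEVELS)
            }
            metrics[pool_name]["combined"] = _metrics_block(
                combined_pred[mask], labels[mask]
            )
            per_level_acc[pool_name] = [
                100.0 * float(np.mean(level_pred[lvl, mask] == y_men[mask]))
                for lvl in range(N_LEVELS)
            ]
            combined_acc[pool_name] = 100.0 * float(
                np.mean(combined_pred[mask] == y_men[mask])
            )

        # slide-level suite over all slides' combined decisions
        fractions: list[ev.SlideFraction] = []
        tuples: list[ev.SlideTuples] = []
        sid_arr = np.array(table.slide_id)
        for sid in split_manifest["slide_id"]:
            sel = sid_arr == sid
            if sel.sum() == 0:
                logger.warning("slide %s has no kept patches; skipped", sid)
                continue
            true = labels[sel][0]
            decisions = np.where(combined_pred[sel], "MEN", "SFT")
            fractions.append(ev.slide_fraction(list(decisions), sid, true))
            tuples.append(
                ev.SlideTuples(
                    true_label=true,
                    level0_men=level_pred[0, sel],
                    aggregate_men=combined_pred[sel],
                )
            )

        beta_men = beta_sft = None
        t_jmax = j_max = slide_acc = None
        boot: dict = {}
        p_fp = p_fn = None
        men_fr = [f for f in fractions if f.true_label == "MEN"]
        sft_fr = [f for f in fractions if f.true_label == "SFT"]
        try:
            # group fits use Jeffreys-smoothed fractions so a perfectly
            # classified group (all raw fractions 0 or 1) stays fittable
            beta_men = ev.fit_beta_mle([ev.jeffreys_fraction(f) for f in men_fr])
            beta_sft = ev.fit_beta_mle([ev.jeffreys_fraction(f) for f in sft_fr])
            curve = ev.threshold_curves(beta_men, beta_sft)
            t_jmax, j_max = curve.t_at_j_max, curve.j_max
            slide_calls = [
                "MEN" if ev.jeffreys_fraction(f) >= t_jmax else "SFT" for f in fractions
            ]
            slide_acc = 100.0 * float(
                np.mean([c == f.true_label for c, f in zip(slide_calls, fractions)])
            )
            pd.DataFrame(
                {
                    "t": curve.thresholds,
                    "SEN": curve.sen,
                    "SPC": curve.spc,
                    "PRC": curve.prc,
                    "J": curve.j,
                }
            ).to_csv(out_dir / "threshold_curves.csv", index=False)
            for name, group in (("MEN", men_fr), ("SFT", sft_fr)):
                ci = ev.bootstrap_beta_ci(
                    [(f.n_men, f.n_sft) for f in group],
                    b=1000,
                    seed=derive_seed(config.seed, f"bootstrap-{name}"),
                )
                boot[name] = {
                    "alpha": ci.estimate.alpha,
                    "beta": ci.estimate.beta,
                    "alpha_ci": list(ci.alpha_ci),
                    "beta_ci": list(ci.beta_ci),
                    "n_failures": ci.n_failures,
                }
        except ValueError as exc:
            logger.warning("beta suite unavailable: %s", exc)
        try:
            p_fp, p_fn = ev.superiority_test(
                tuples, b=999, seed=derive_seed(config.seed, "superiority")
            )
        except ValueError as exc:
            logger.warning("superiority test unavailable: %s", exc)

        stats_obj = {
            "beta": {
                "MEN": None if beta_men is None else {"alpha": beta_men.alpha, "beta": beta_men.beta},
                "SFT": None if beta_sft is None else {"alpha": beta_sft.alpha, "beta": beta_sft.beta},
            },
            "t_at_j_max": t_jmax,
            "j_max": j_max,
            "slide_accuracy": slide_acc,
            "bootstrap": boot,
            "superiority": {"p_fp": p_fp, "p_fn": p_fn},
            "slide_fractions": [
                {
                    "slide_id": f.slide_id,
                    "n_men": f.n_men,
                    "n_sft": f.n_sft,
                    "p_men": f.p_men,
                    "true_label": f.true_label,
                }
                for f in fractions
            ],
        }
        (out_dir / "stats.json").write_text(json.dumps(stats_obj, sort_keys=True, indent=1))
        (out_dir / "metrics.json").write_text(json.dumps(metrics, sort_keys=True, indent=1))

    confidences: dict = {}
    if visualize:
        with stage("visualize"):
            confidences = visualize_slides(
                split_manifest, cohort_dir, out_dir, config, weights, models, backend
            )

    run_manifest = {
        "config": config.to_dict(),
        "backend": backend,
        "seeds": {
            "experiment": config.seed,
            "split": derive_seed(config.seed, "split"),
            "bootstrap_MEN": derive_seed(config.seed, "bootstrap-MEN"),
            "bootstrap_SFT": derive_seed(config.seed, "bootstrap-SFT"),
            "superiority": derive_seed(config.seed, "superiority"),
        },
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "timings_s": timings,
        "n_triples": int(len({(r["slide_id"], r["triple_id"]) for r in table.manifest_rows})),
        "n_kept": table.n,
    }
    (out_dir / "run.json").write_text(json.dumps(run_manifest, sort_keys=True, indent=1))

    return ExperimentResult(
        config=config,
        n_triples=run_manifest["n_triples"],
        n_kept=table.n,
        per_level_acc=per_level_acc,
        combined_acc=combined_acc,
        weights=weights,
        grid_accuracy=search.accuracy,
        normalized_acc_weights=norm_weights,
        metrics=metrics,
        beta_men=beta_men,
        beta_sft=beta_sft,
        t_at_j_max=t_jmax,
        j_max=j_max,
        slide_accuracy=slide_acc,
        slide_fractions=fractions,
        bootstrap=boot,
        p_fp=p_fp,
        p_fn=p_fn,
        confidences=confidences,
    )


def _slide_backends(
    models: list[clf.ReferenceModel] | None,
    backend: str,
    true_label: str,
    config: ExperimentConfig,
) -> list:
    if backend == "oracle":
        return [clf.OracleBackend(true_label)] * N_LEVELS
    assert models is not None
    return [
        clf.ReferenceBackend(
            m,
            apply_circular_mask=config.filter.circular_mask_enabled,
            mask_fill=config.filter.mask_fill,
        )
        for m in models
    ]


def visualize_slides(
    split_manifest: pd.DataFrame,
    cohort_dir: Path,
    out_dir: Path,
    config: ExperimentConfig,
    weights: FusionWeights,
    models: list[clf.ReferenceModel] | None,
    backend: str = "reference",
) -> dict:
    """Regional decisions, overlay PNGs and per-slide confidence scores."""
    overlay_dir = Path(out_dir) / "overlays"
    overlay_dir.mkdir(parents=True, exist_ok=True)
    confidences: dict[str, float] = {}
    for row in split_manifest.itertuples(index=False):
        pyramid = load_pyramid(Path(cohort_dir) / row.path)
        backends = _slide_backends(models, backend, row.label, config)
        w0, h0 = pyramid.level_dimensions(0)
        regions = []
        for ry in range(0, h0 - config.region_size + 1, config.region_size):
            for rx in range(0, w0 - config.region_size + 1, config.region_size):
                regions.append(
                    ev.region_decision(
                        pyramid,
                        backends,
                        weights,
                        (rx, ry, config.region_size),
                        tile_size=config.tile_size,
                        tie_break=config.tie_break,
                    )
                )
        if not regions:
            continue
        confidences[row.slide_id] = ev.confidence_score(regions, row.label)
        overlay = ev.render_overlay(pyramid, regions)
        Image.fromarray(overlay).save(overlay_dir / f"{row.slide_id}.png")
    (Path(out_dir) / "confidence.json").write_text(
        json.dumps(confidences, sort_keys=True, indent=1)
    )
    return confidences
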