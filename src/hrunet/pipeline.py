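"""End-to-end orchestration: phantom generation -> augmentation ->
k-fold cross-validated training -> held-out evaluation, plus the
HAC-count ablation harness.

Held-out evaluation always runs on original, un-augmented images; the
augmented pool exists only inside each fold's training loop.  Every
artifact is reproducible from the RunConfig alone: phantom seeds, fold
assignment and training order all derive from the configured seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import build_training_set
from .metrics import MetricRecord, evaluate_pair, summarize_records
from .model import ModelConfig, hac_placement_for_count
from .phantom import PhantomParams, PhantomSample, generate_dataset
from .train import TrainConfig, make_folds, train_fold

__all__ = ["RunConfig", "CrossvalReport", "run_crossval", "run_ablation"]

log = logging.getLogger("hrunet")


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_images: int = 40
    ablation_hac_counts: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    output_dir: str | None = None
    log_level: str = "INFO"
    max_steps_per_fold: int | None = None   # scaled-down desk runs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d


@dataclass
class CrossvalReport:
    records: list[MetricRecord]          # one per image, evaluation on its fold
    fold_of_image: np.ndarray
    summary: dict[str, tuple[float, float]]
    histories: list[list[float]]
    models: list | None = None

    def per_fold_summaries(self) -> list[dict]:
        out = []
        for f in range(int(self.fold_of_image.max()) + 1):
            recs = [r for r, ff in zip(self.records, self.fold_of_image) if ff == f]
            out.append(summarize_records(recs))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (r, f) in enumerate(zip(self.records, self.fold_of_image)):
            rows.append({"image": i, "fold": int(f), "dice": r.dice, "iou": r.iou,
                         "acc": r.acc, "mhd": r.mhd, "area_gt": r.area_gt,
                         "area_pred": r.area_pred, "delta_tpa": r.delta_tpa})
        return pd.DataFrame(rows)


def _validate_samples(samples: list[PhantomSample], model_config: ModelConfig):
    shapes = {s.image.shape for s in samples}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent image sizes across dataset: {sorted(shapes)}")
    (H, W), = shapes
    if (H, W) != (model_config.in_height, model_config.in_width):
        raise ValueError(f"dataset size {H}x{W} does not match model config "
                         f"{model_config.in_height}x{model_config.in_width}")


def run_crossval(config: RunConfig, samples: list[PhantomSample] | None = None,
                 keep_models: bool = False) -> CrossvalReport:
    """Cross-validated train/evaluate cycle over phantom (or given) samples.

    Returns per-image metric records from each image's held-out fold,
    the pooled mean +/- SD summary, and per-fold loss histories.  With
    ``config.output_dir`` set, writes ``metrics.csv``, ``summary.csv``
    and a ``manifest.json`` capturing every seed.
    """
    logging.basicConfig(level=config.log_level)
    if samples is None:
        samples = generate_dataset(config.n_images, config.phantom)
    _validate_samples(samples, config.model)
    n, k = len(samples), config.train.folds
    plan = make_folds(n, k, seed=config.train.seed)

    records: list[MetricRecord | None] = [None] * n
    histories, models = [], []
    for f in range(k):
        tr_idx = plan.train_indices(f)
        te_idx = plan.test_indices(f)
        pool = build_training_set([samples[i] for i in tr_idx])
        log.info("fold %d/%d: %d originals -> %d augmented pairs, %d held out",
                 f + 1, k, len(tr_idx), len(pool), len(te_idx))
        model, hist = train_fold(pool, config.train, config.model,
                                 max_steps=config.max_steps_per_fold)
        histories.append(hist)
        for i in te_idx:
            # evaluation sees the original image only, never augmented views
            pred = model.predict_mask(samples[i].image[None, None])[0]
            records[i] = evaluate_pair(samples[i].plaque_mask, pred)
        if keep_models:
            models.append(model)
        log.info("fold %d/%d done: final loss %.4f", f + 1, k, hist[-1])

    report = CrossvalReport(
        records=records, fold_of_image=plan.fold_assignments,
        summary=summarize_records(records), histories=histories,
        models=models if keep_models else None,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(out / "metrics.csv", index=False)
        pd.DataFrame([
            {"metric": m, "mean": mu, "sd": sd}
            for m, (mu, sd) in report.summary.items()
        ]).to_csv(out / "summary.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(config.to_dict(), indent=2))
    return report


def run_ablation(config: RunConfig,
                 samples: list[PhantomSample] | None = None) -> pd.DataFrame:
    """One cross-validation per HAC placement count; Dice table as output.

    Counts index the deepest-first placement order (res4, res3, res2,
    res1, conv_block, input-resolution stage); count 0 is the plain
    RU-Net baseline without any HAC.
    """
    if not config.ablation_hac_counts:
        raise ValueError("ablation_hac_counts must be non-empty")
    if samples is None:
        samples = generate_dataset(config.n_images, config.phantom)
    rows = []
    for count in config.ablation_hac_counts:
        placement = hac_placement_for_count(count)   # validates the count
        mcfg = ModelConfig.from_dict({**config.model.to_dict(),
                                      "hac_placement": list(placement)})
        sub = RunConfig(phantom=config.phantom, train=config.train, model=mcfg,
                        n_images=config.n_images, output_dir=None,
                        log_level=config.log_level,
                        max_steps_per_fold=config.max_steps_per_fold)
        report = run_crossval(sub, samples=samples)
        row = {"hacs": count}
        for m, (mu, sd) in report.summary.items():
            row[f"{m}_mean"] = mu
            row[f"{m}_sd"] = sd
        rows.append(row)
        log.info("ablation HACs=%d: Dice %.3f +/- %.3f", count,
                 row["dice_mean"], row["dice_sd"])
    df = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "ablation.csv", index=False)
    return df
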