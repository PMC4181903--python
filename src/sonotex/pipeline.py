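"""End-to-end pipeline: simulate -> preprocess -> extract -> select ->
train -> evaluate, for every requested feature set.

The study design it orchestrates: a 60-case pool (30 normal, 10 fatty,
10 cirrhosis, 10 hepatomegaly) carries the training dynamics through an
internal stratified 80/10/10 train/validation/test split, while a separate
40-case held-out set (20 normal / 20 abnormal) provides the "testing" row
of the comparison table.  All randomness flows from per-stage seeds derived
from one master seed, so a run is a pure function of its
:class:`PipelineConfig`.

Segmentation: ``segmentation="snake"`` runs the greedy active contour on
each case (initialized from the mask bounding box's inscribed ellipse);
``"mask"`` (the default) uses the generator's ground-truth polygon, which
the snake reproduces to Jaccard >= 0.9 — the cheap route for repeated
whole-pipeline experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arff import read_arff, write_arff
from .evaluation import MetricSet, compare_feature_sets, confusion, metrics, roc
from .features import FEATURE_SETS, build_feature_table
from .image import read_image
from .mlp import TextureMLP, TrainConfig, predict, split_data
from .preprocess import (SnakeConfig, background_subtract, contour_to_mask,
                         crop_roi, inscribed_ellipse_contour, snake_segment)
from .selection import SearchConfig, select_features
from .synthetic import LabeledCase, generate_dataset, write_dataset

__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline", "read_image",
           "write_arff", "read_arff", "segment_case"]


@dataclass
class PipelineConfig:
    """One structured configuration drives a full run."""

    # training-pool composition (the 60-sonogram study analogue)
    n_normal: int = 30
    n_fatty: int = 10
    n_cirrhosis: int = 10
    n_hepatomegaly: int = 10
    # held-out testing set: 20 normal / 20 abnormal
    heldout_normal: int = 20
    heldout_fatty: int = 7
    heldout_cirrhosis: int = 7
    heldout_hepatomegaly: int = 6
    image_size: int = 128
    master_seed: int = 0
    feature_sets: tuple[str, ...] = FEATURE_SETS
    segmentation: str = "mask"           # "mask" | "snake"
    selection_method: str = "genetic"
    split_proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_hidden: int = 10
    min_validation_accuracy: float = 0.9
    max_restarts: int = 5
    write_images: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["feature_sets"] = list(self.feature_sets)
        d["split_proportions"] = list(self.split_proportions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["feature_sets"] = tuple(d["feature_sets"])
        d["split_proportions"] = tuple(d["split_proportions"])
        return PipelineConfig(**d)

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage seeds derived deterministically from the master
        seed (all below 2**31)."""
        ss = np.random.SeedSequence(self.master_seed)
        vals = ss.generate_state(4) % (2**31 - 1)
        return {
            "pool_data": int(vals[0]),
            "heldout_data": int(vals[1]),
            "selection": int(vals[2]),
            "training": int(vals[3]),
        }


@dataclass
class PipelineRun:
    """Everything a run produced, in memory."""

    config: PipelineConfig
    pool_cases: list[LabeledCase]
    heldout_cases: list[LabeledCase]
    tables: dict[str, pd.DataFrame]
    heldout_tables: dict[str, pd.DataFrame]
    selections: dict[str, list[str]]
    results: dict[str, object]
    train_metrics: dict[str, MetricSet]
    test_metrics: dict[str, MetricSet]
    roc_auc: dict[str, float]
    comparison: pd.DataFrame

    @property
    def best_feature_set(self) -> str:
        return self.comparison.loc[self.comparison["best"]].iloc[0]["feature_set"]

    @property
    def best_test_accuracy(self) -> float:
        return float(self.comparison["test_accuracy"].max())


def segment_case(case: LabeledCase, config: SnakeConfig | None = None) -> LabeledCase:
    """Re-derive a case's mask with the snake: crop to the true mask's
    padded bounding box, deform the inscribed ellipse, fill, and exclude
    the background."""
    rows = np.flatnonzero(case.mask.any(axis=1))
    cols = np.flatnonzero(case.mask.any(axis=0))
    pad = 6
    h, w = case.image.shape
    top = max(0, rows[0] - pad)
    left = max(0, cols[0] - pad)
    height = min(h, rows[-1] + pad + 1) - top
    width = min(w, cols[-1] + pad + 1) - left
    cropped = crop_roi(case.image, (top, left, height, width))
    init = inscribed_ellipse_contour(height, width)
    contour = snake_segment(cropped, init, config)
    mask = contour_to_mask(contour, height, width)
    segmented = background_subtract(cropped, mask)
    return replace_case_image(case, segmented)


def replace_case_image(case: LabeledCase, image) -> LabeledCase:
    new = LabeledCase(image=image, class_label=case.class_label,
                      binary_label=case.binary_label,
                      liver_length=case.liver_length, seed=case.seed,
                      case_id=case.case_id)
    return new


def _preprocess(cases: list[LabeledCase], config: PipelineConfig) -> list[LabeledCase]:
    if config.segmentation == "mask":
        return [replace_case_image(c, background_subtract(c.image, c.mask))
                for c in cases]
    if config.segmentation == "snake":
        return [segment_case(c) for c in cases]
    raise ValueError(f"unknown segmentation mode {config.segmentation!r}")


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineRun:
    """Execute all stages; optionally persist artifacts under ``outdir``."""
    config = config or PipelineConfig()
    seeds = config.stage_seeds()

    pool = generate_dataset(
        config.n_normal, config.n_fatty, config.n_cirrhosis,
        config.n_hepatomegaly, master_seed=seeds["pool_data"],
        height=config.image_size, width=config.image_size,
    )
    heldout = generate_dataset(
        config.heldout_normal, config.heldout_fatty, config.heldout_cirrhosis,
        config.heldout_hepatomegaly, master_seed=seeds["heldout_data"],
        height=config.image_size, width=config.image_size,
    )
    for c in heldout:
        c.case_id = "heldout_" + c.case_id

    pool_pp = _preprocess(pool, config)
    heldout_pp = _preprocess(heldout, config)

    tables: dict[str, pd.DataFrame] = {}
    heldout_tables: dict[str, pd.DataFrame] = {}
    selections: dict[str, list[str]] = {}
    fit_results: dict[str, object] = {}
    train_metrics: dict[str, MetricSet] = {}
    test_metrics: dict[str, MetricSet] = {}
    roc_auc: dict[str, float] = {}

    # the mixed panel contains every family, so extract it once per case
    # and slice the per-family tables out of it
    from .features import feature_names

    pool_mixed = build_feature_table(pool_pp, "MIXED")
    heldout_mixed = build_feature_table(heldout_pp, "MIXED")

    for fs in config.feature_sets:
        cols = list(feature_names(fs)) + ["case_id", "class"]
        table = pool_mixed[cols].copy()
        ho_table = heldout_mixed[cols].copy()
        tables[fs] = table
        heldout_tables[fs] = ho_table

        sel_cfg = SearchConfig(method=config.selection_method,
                               seed=seeds["selection"])
        selected = select_features(table, sel_cfg)
        selections[fs] = selected.names

        sel_cols = selected.names + ["case_id", "class"]
        split = split_data(table, config.split_proportions,
                           seed=seeds["training"])
        model = TextureMLP.from_dataframe(table[sel_cols],
                                          n_hidden=config.n_hidden)
        res = model.fit_until(
            split=split,
            config=TrainConfig(n_hidden=config.n_hidden, seed=seeds["training"]),
            min_accuracy=config.min_validation_accuracy,
            max_restarts=config.max_restarts,
        )
        fit_results[fs] = res

        # training row: the whole pool, as the study reports its 60 samples
        pred_pool = predict(res, table[sel_cols])
        train_metrics[fs] = metrics(confusion(table["class"], pred_pool["predicted"]))
        pred_ho = predict(res, ho_table[sel_cols])
        test_metrics[fs] = metrics(confusion(ho_table["class"], pred_ho["predicted"]))
        roc_auc[fs] = roc(pred_ho["score_abnormal"], ho_table["class"]).auc

    comparison = compare_feature_sets(
        {fs: (train_metrics[fs], test_metrics[fs]) for fs in config.feature_sets}
    )

    run = PipelineRun(
        config=config, pool_cases=pool, heldout_cases=heldout,
        tables=tables, heldout_tables=heldout_tables, selections=selections,
        results=fit_results, train_metrics=train_metrics,
        test_metrics=test_metrics, roc_auc=roc_auc, comparison=comparison,
    )
    if outdir is not None:
        _persist(run, Path(outdir), seeds)
    return run


def _persist(run: PipelineRun, outdir: Path, seeds: dict[str, int]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = run.config
    cfg.to_yaml(outdir / "config.yaml")
    manifest = {
        "master_seed": cfg.master_seed,
        "stage_seeds": seeds,
        "feature_sets": list(cfg.feature_sets),
        "package": "sonotex 0.1.0",
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    if cfg.write_images:
        write_dataset(run.pool_cases, outdir / "pool")
        write_dataset(run.heldout_cases, outdir / "heldout")
    for fs in cfg.feature_sets:
        write_arff(run.tables[fs], outdir / f"features_{fs.lower()}.arff")
        run.tables[fs].to_csv(outdir / f"features_{fs.lower()}.csv", index=False)
        write_arff(run.heldout_tables[fs], outdir / f"heldout_{fs.lower()}.arff")
        run.heldout_tables[fs].to_csv(outdir / f"heldout_{fs.lower()}.csv", index=False)
        sel_report = {
            "feature_set": fs,
            "method": cfg.selection_method,
            "seed": seeds["selection"],
            "selected": run.selections[fs],
        }
        (outdir / f"selection_{fs.lower()}.json").write_text(
            json.dumps(sel_report, indent=2))
        run.results[fs].to_json(outdir / f"model_{fs.lower()}.json")
        run.results[fs].trace.to_csv(outdir / f"trace_{fs.lower()}.csv", index=False)
        report = {
            "train": run.train_metrics[fs].as_percent(2),
            "test": run.test_metrics[fs].as_percent(2),
            "test_auc": run.roc_auc[fs],
        }
        (outdir / f"report_{fs.lower()}.json").write_text(json.dumps(report, indent=2))
    run.comparison.to_csv(outdir / "comparison.csv", index=False)
    cmp_round = run.comparison.copy()
    for col in cmp_round.columns:
        if col not in ("feature_set", "best"):
            cmp_round[col] = cmp_round[col].round(2)
    header = "| " + " | ".join(cmp_round.columns) + " |"
    sep = "|" + "|".join("---" for _ in cmp_round.columns) + "|"
    body = ["| " + " | ".join(str(v) for v in row) + " |"
            for row in cmp_round.itertuples(index=False)]
    (outdir / "comparison.md").write_text("\n".join([header, sep] + body) + "\n")
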