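"""End-to-end orchestration: volumes -> networks -> features -> models ->
explanations -> anatomical report.

A single YAML-loadable :class:`PipelineConfig` drives every stage; all
randomness descends from one seed, so a rerun with the same config writes
byte-identical fold assignments, feature matrices and selections.  Each
stage persists its artifacts as it completes, so a failure leaves partial
outputs for debugging and names the failing stage.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .atlas_report import map_patches_to_regions, region_map_to_frame, region_report
from .classify import (
    CVScheme,
    cross_validate,
    make_folds,
    prediction_agreement,
    summarize_performance,
)
from .connectome import build_network, save_edge_list
from .core import FeatureMatrix
from .explainability import (
    ExplainConfig,
    ImportanceRanking,
    MULTICLASS,
    compare_all_rankings,
    class_ranking,
    explain_fold,
    explanations_to_frame,
    global_ranking,
    one_vs_rest_scope,
)
from .feature_selection import SelectionConfig, select_and_retrain
from .graph_metrics import assemble_features
from .parcellation import save_grid, tile_patches
from .synthetic_cohort import SyntheticCohortSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    seed: int = 0
    cohort: SyntheticCohortSpec | None = None
    input_manifest: str | None = None
    input_mask: str | None = None
    input_atlas: tuple[str, str] | None = None  # (labels.nii.gz, names.tsv)
    patch_dims_mm: tuple[float, float, float] = (10.0, 15.0, 20.0)
    overlap_threshold: float = 0.10
    link_threshold: float = 0.3
    n_folds: int = 10
    n_repeats: int = 50
    classifiers: tuple[str, ...] = ("RF",)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    report_top_k: int = 30
    write_networks: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("cohort") is not None:
            c = dict(kwargs["cohort"])
            for key in ("grid_shape", "voxel_size_mm", "patch_dims_mm"):
                if key in c:
                    c[key] = tuple(c[key])
            if "affected_patches" in c:
                c["affected_patches"] = {
                    k: frozenset(v) for k, v in c["affected_patches"].items()
                }
            kwargs["cohort"] = SyntheticCohortSpec(**c)
        if "selection" in kwargs and isinstance(kwargs["selection"], dict):
            kwargs["selection"] = SelectionConfig(**kwargs["selection"])
        if "explain" in kwargs and isinstance(kwargs["explain"], dict):
            kwargs["explain"] = ExplainConfig(**kwargs["explain"])
        for key in ("patch_dims_mm",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "classifiers" in kwargs:
            kwargs["classifiers"] = tuple(kwargs["classifiers"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cohort is not None:
            d["cohort"]["affected_patches"] = {
                k: sorted(int(i) for i in v)
                for k, v in self.cohort.affected_patches.items()
            }
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class PipelineResult:
    """In-memory handles to what :func:`run_pipeline` computed."""

    out_dir: Path
    grid: object
    features: FeatureMatrix
    records: pd.DataFrame
    performance: object
    selections: list
    explanations: list
    rankings: dict[str, ImportanceRanking]
    region_table: pd.DataFrame | None
    region_list: list[str] | None


def _derive_scheme(config: PipelineConfig) -> CVScheme:
    return CVScheme(
        n_folds=config.n_folds,
        n_repeats=config.n_repeats,
        base_seed=config.seed,
    )


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute every stage in order, persisting artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        # ------------------------------------------------ cohort
        stage = "cohort"
        t0 = time.time()
        if config.cohort is not None:
            spec = config.cohort
            cohort = generate_cohort(spec)
            volumes, mask, atlas = cohort.volumes, cohort.mask, cohort.atlas
            grid = cohort.grid
        else:
            if config.input_manifest is None or config.input_mask is None:
                raise ValueError(
                    "config needs either a synthetic cohort spec or an "
                    "input manifest + mask"
                )
            mask = pio.load_mask(config.input_mask)
            volumes = pio.load_cohort(config.input_manifest, mask)
            atlas = (
                pio.load_atlas(*config.input_atlas)
                if config.input_atlas
                else None
            )
            grid = None
        timings[stage] = time.time() - t0

        # ------------------------------------------------ parcellation
        stage = "parcellation"
        t0 = time.time()
        if grid is None:
            grid = tile_patches(
                mask,
                config.patch_dims_mm,
                overlap_threshold=config.overlap_threshold,
                voxel_size_mm=volumes[0].voxel_size_mm,
            )
        save_grid(grid, out / "grid.tsv")
        timings[stage] = time.time() - t0

        # ------------------------------------------------ connectome
        stage = "connectome"
        t0 = time.time()
        nets = [build_network(v, grid, config.link_threshold) for v in volumes]
        if config.write_networks:
            net_dir = out / "networks"
            net_dir.mkdir(exist_ok=True)
            for net in nets:
                save_edge_list(net, net_dir / f"{net.subject_id}.tsv")
        timings[stage] = time.time() - t0

        # ------------------------------------------------ features
        stage = "graph_metrics"
        t0 = time.time()
        features = assemble_features(
            nets, grid, [v.class_label for v in volumes]
        )
        pio.save_features(
            features,
            out / "features.csv",
            sidecar={
                "link_threshold": config.link_threshold,
                "n_patches": len(grid),
                "config_hash": config.config_hash(),
            },
        )
        timings[stage] = time.time() - t0

        # ------------------------------------------------ classification
        stage = "classify"
        t0 = time.time()
        scheme = _derive_scheme(config)
        fold_rows = []
        for repeat in range(scheme.n_repeats):
            assignment = make_folds(features.labels, scheme, repeat)
            for sid, f in zip(features.subject_ids, assignment):
                fold_rows.append({"subject_id": sid, "repeat": repeat, "fold": int(f)})
        pd.DataFrame(fold_rows).to_csv(out / "folds.csv", index=False)
        records = cross_validate(features, scheme, config.classifiers)
        records.to_csv(out / "predictions.csv", index=False)
        performance = summarize_performance(records)
        performance.accuracy.to_csv(out / "accuracy.csv", index=False)
        performance.auc.to_csv(out / "auc.csv", index=False)
        performance.roc_curves.to_csv(out / "roc_curves.csv", index=False)
        for name, mat in performance.confusion.items():
            mat.to_csv(out / f"confusion_{name}.csv")
        if {"RF", "SVM"} <= set(config.classifiers):
            agree = prediction_agreement(
                records[records.classifier == "RF"],
                records[records.classifier == "SVM"],
            )
            pd.DataFrame(
                [{"class": c, "pearson_r": r} for c, r in agree.items()]
            ).to_csv(out / "agreement_RF_SVM.csv", index=False)
        timings[stage] = time.time() - t0

        # ------------------------------------------------ selection + explanation
        stage = "feature_selection"
        t0 = time.time()
        selections, explanations = nested_selection_and_explanation(
            features, scheme, config
        )
        sel_frames = []
        for sel in selections:
            t = sel.table.copy()
            t.insert(0, "repeat", sel.repeat)
            t.insert(1, "fold", sel.fold)
            sel_frames.append(t)
        pd.concat(sel_frames, ignore_index=True).to_csv(
            out / "selections.tsv", sep="\t", index=False
        )
        explanations_to_frame(explanations).to_csv(
            out / "explanations.csv", index=False
        )
        timings[stage] = time.time() - t0

        # ------------------------------------------------ rankings
        stage = "explainability"
        t0 = time.time()
        rankings: dict[str, ImportanceRanking] = {
            "global": global_ranking(explanations)
        }
        for cls in features.classes():
            rankings[cls] = class_ranking(explanations, cls)
        for name, ranking in rankings.items():
            pd.DataFrame(
                {
                    "feature": ranking.ranked_features,
                    "mean_abs_shap": [
                        ranking.scores[f] for f in ranking.ranked_features
                    ],
                }
            ).to_csv(out / f"ranking_{name}.tsv", sep="\t", index=False)
        compare_all_rankings(rankings).to_csv(
            out / "ranking_comparisons.csv", index=False
        )
        timings[stage] = time.time() - t0

        # ------------------------------------------------ atlas report
        stage = "atlas_report"
        t0 = time.time()
        region_table = region_list = None
        if atlas is not None:
            region_map = map_patches_to_regions(grid, atlas, mask)
            region_map_to_frame(region_map).to_csv(
                out / "region_map.tsv", sep="\t", index=False
            )
            region_table, region_list = region_report(
                rankings["global"], region_map, top_k=config.report_top_k
            )
            region_table.to_csv(out / "region_report.csv", index=False)
            (out / "regions.txt").write_text("\n".join(region_list) + "\n")
            for cls in features.classes():
                if rankings[cls].ranked_features:
                    tbl, _ = region_report(
                        rankings[cls], region_map, top_k=config.report_top_k
                    )
                    tbl.to_csv(out / f"region_report_{cls}.csv", index=False)
        timings[stage] = time.time() - t0

        manifest = {
            "config": _plain(config.to_dict()),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return PipelineResult(
        out_dir=out,
        grid=grid,
        features=features,
        records=records,
        performance=performance,
        selections=selections,
        explanations=explanations,
        rankings=rankings,
        region_table=region_table,
        region_list=region_list,
    )


def nested_selection_and_explanation(
    features: FeatureMatrix,
    scheme: CVScheme,
    config: PipelineConfig,
):
    """The per-fold MDA selection, reduced-model retraining and Shapley pass.

    Runs with the same fold assignments as the classification stage.  The
    selection is computed once per fold from the multiclass forest and the
    three one-vs-rest reduced models reuse that feature subset.
    """
    labels = np.asarray(features.labels)
    sids = np.asarray(features.subject_ids)
    classes = features.classes()
    sel_cfg = SelectionConfig(
        n_permutations=config.selection.n_permutations,
        percentile=config.selection.percentile,
        alpha=config.selection.alpha,
        n_estimators=config.selection.n_estimators,
        reduced_estimators=config.selection.reduced_estimators,
        fallback_top=config.selection.fallback_top,
        base_seed=config.seed,
    )
    exp_cfg = ExplainConfig(
        background_size=config.explain.background_size,
        n_permutations=config.explain.n_permutations,
        explain_target=config.explain.explain_target,
        base_seed=config.seed,
    )
    selections = []
    explanations = []
    name_index = {f: i for i, f in enumerate(features.feature_names)}
    for repeat in range(scheme.n_repeats):
        assignment = make_folds(features.labels, scheme, repeat)
        for fold in range(scheme.n_folds):
            test = assignment == fold
            train = ~test
            sel = select_and_retrain(
                features.values[train],
                labels[train],
                features.feature_names,
                sel_cfg,
                repeat=repeat,
                fold=fold,
            )
            selections.append(sel)
            cols = [name_index[f] for f in sel.selected_features]
            explanations.extend(
                explain_fold(
                    sel.reduced_model,
                    features.values[np.ix_(train, cols)],
                    labels[train],
                    features.values[np.ix_(test, cols)],
                    sids[test],
                    labels[test],
                    sel.selected_features,
                    repeat,
                    fold,
                    exp_cfg,
                    classes=classes,
                )
            )
    return selections, explanations
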