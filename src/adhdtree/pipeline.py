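"""Two-stage expert-in-the-loop pipeline: blind process, then knowledge-guided.

The blind process runs fully automatically: ensemble CFS over the complete
feature table (phenotypes + 116 ROI variances) reduces the training set to
the relevant features, LOOCV tunes the minimum leaf size m, a tree is grown
at the chosen m, and the held-out test cohort is evaluated.  Its artifacts
(rendered tree, selection frequencies, decision chains) are what a domain
expert reviews; the review itself is a human step, not automated here.

The knowledge-guided process retrains after expert input: feature selection
is skipped and the table is restricted to an expert ROI set (by default
gender + the 26 limbic-system regions) before tuning and training.

A phenotype variant rebuilds the blind model with all four phenotypic
attributes alongside the blind-selected ROI features, to expose phenotypics
that may act as overfitting factors.

All stages derive their seeds deterministically from one global seed, so a
run record can be regenerated bit-identically from its config echo.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .cfs_ensemble import EnsembleConfig, ensemble_select
from .cohort_io import Cohort, CohortError, limbic_roi_set, load_atlas, read_cohort
from .evaluation import evaluate
from .feature_extraction import (
    DEFAULT_PHENOTYPES,
    build_feature_table,
    parse_roi_feature,
)
from .model_selection import kfold_accuracy, select_m
from .tree_induction import grow, model_to_dict, predict, predict_table, render


@dataclass
class PipelineConfig:
    train_dir: str = None
    test_dir: str = None
    out_dir: str = None
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    m_min: int = 5
    m_max: int = 20
    kfold_k: int = 4
    expert_rois: tuple = None  # None -> packaged limbic set
    guided_phenotypes: tuple = ("gender",)
    retune_variant: bool = True  # re-tune m in the phenotype variant
    tr_seconds: float = 2.0
    seed: int = 0

    def describe(self) -> dict:
        d = dataclasses.asdict(self)
        d["expert_rois"] = list(self.expert_rois) if self.expert_rois else None
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunRecord:
    stage: str
    status: str  # "ok" | "failed_selection"
    seed: int
    config: dict
    selected_features: list = None
    selection_frequency: dict = None
    chosen_m: int = None
    loocv_curve: dict = None
    model: dict = None
    tree_text: str = None
    train_eval: dict = None
    test_eval: dict = None
    cv_mean_pct: float = None
    cv_sd_pct: float = None
    log: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


def _load_cohorts(config: PipelineConfig, train: Cohort, test: Cohort):
    if train is None:
        if config.train_dir is None:
            raise CohortError("no training cohort: pass one or set train_dir")
        train = read_cohort(config.train_dir, tr_seconds=config.tr_seconds, role="training")
    if test is None:
        if config.test_dir is None:
            raise CohortError("no test cohort: pass one or set test_dir")
        test = read_cohort(config.test_dir, tr_seconds=config.tr_seconds, role="test")
    return train, test


def _finish_stage(
    record: RunRecord,
    config: PipelineConfig,
    train_table,
    test_table,
) -> RunRecord:
    """Shared tail of every stage: tune m, grow, evaluate, CV summary."""
    report = select_m(train_table, config.m_min, config.m_max)
    record.chosen_m = report.chosen_m
    record.loocv_curve = {str(m): a for m, a in report.accuracies.items()}
    record.log.append(
        f"LOOCV over m in [{config.m_min}, {config.m_max}]: chose m={report.chosen_m}"
    )
    model = grow(train_table, report.chosen_m)
    atlas = load_atlas()
    record.model = model_to_dict(model)
    record.tree_text = render(model, atlas=atlas, fmt="text")
    record.train_eval = evaluate(predict_table(model, train_table), list(train_table.labels)).to_dict()
    record.test_eval = evaluate(predict_table(model, test_table), list(test_table.labels)).to_dict()
    mean, sd = kfold_accuracy(
        train_table,
        report.chosen_m,
        k=config.kfold_k,
        seed=stage_seed(config.seed, record.stage + ":kfold"),
    )
    record.cv_mean_pct = 100.0 * mean
    record.cv_sd_pct = 100.0 * sd
    record.status = "ok"
    return record


def run_blind(config: PipelineConfig, train: Cohort = None, test: Cohort = None) -> RunRecord:
    """The blind process: ensemble CFS on all features, then tune/train/test."""
    train, test = _load_cohorts(config, train, test)
    record = RunRecord(stage="blind", status="running", seed=config.seed, config=config.describe())
    record.log.append(f"training cohort: {len(train)} subjects {train.counts()}")
    record.log.append(f"test cohort: {len(test)} subjects {test.counts()}")
    full = build_feature_table(train, roi_subset=None, phenotypes=DEFAULT_PHENOTYPES)
    record.log.append(f"full feature table: {full.n} x {len(full.feature_names)}")
    ens = dataclasses.replace(config.ensemble, seed=stage_seed(config.seed, "blind:ensemble"))
    selection = ensemble_select(full, ens)
    record.selection_frequency = dict(selection.frequency)
    record.selected_features = list(selection.selected)
    record.log.append(
        f"ensemble CFS kept {len(selection.selected)} of {len(full.feature_names)} features"
    )
    if not selection.selected:
        record.status = "failed_selection"
        record.log.append("no feature reached the aggregation threshold")
        return record
    reduced_train = full.subset_features(selection.selected)
    selected_rois = sorted(
        r for r in (parse_roi_feature(f) for f in selection.selected) if r is not None
    )
    selected_phenos = tuple(f for f in selection.selected if parse_roi_feature(f) is None)
    test_table = build_feature_table(test, roi_subset=selected_rois, phenotypes=selected_phenos)
    test_table = test_table.subset_features(list(selection.selected))
    return _finish_stage(record, config, reduced_train, test_table)


def run_guided(
    config: PipelineConfig,
    roi_ids=None,
    phenotypes=None,
    train: Cohort = None,
    test: Cohort = None,
) -> RunRecord:
    """The knowledge-guided process: expert ROI restriction, no selection."""
    train, test = _load_cohorts(config, train, test)
    if roi_ids is None:
        roi_ids = config.expert_rois if config.expert_rois else limbic_roi_set()
    roi_ids = tuple(int(r) for r in roi_ids)
    if not roi_ids:
        raise CohortError("guided run needs a non-empty expert ROI set")
    if phenotypes is None:
        phenotypes = config.guided_phenotypes
    record = RunRecord(stage="guided", status="running", seed=config.seed, config=config.describe())
    record.log.append(f"expert ROI set: {len(roi_ids)} regions; phenotypes: {list(phenotypes)}")
    train_table = build_feature_table(train, roi_subset=roi_ids, phenotypes=phenotypes)
    test_table = build_feature_table(test, roi_subset=roi_ids, phenotypes=phenotypes)
    record.selected_features = list(train_table.feature_names)
    record.log.append(f"guided feature table: {train_table.n} x {len(train_table.feature_names)}")
    return _finish_stage(record, config, train_table, test_table)


def run_phenotype_variant(
    config: PipelineConfig,
    blind_record: RunRecord,
    train: Cohort = None,
    test: Cohort = None,
) -> RunRecord:
    """Retrain the blind model with all phenotypics added to its ROI features."""
    if blind_record.status != "ok":
        raise CohortError("phenotype variant requires a completed blind run")
    train, test = _load_cohorts(config, train, test)
    rois = sorted(
        r
        for r in (parse_roi_feature(f) for f in blind_record.selected_features)
        if r is not None
    )
    record = RunRecord(
        stage="phenotype_variant", status="running", seed=config.seed, config=config.describe()
    )
    record.log.append(f"blind-selected ROIs: {rois}; adding all phenotypic features")
    train_table = build_feature_table(train, roi_subset=rois, phenotypes=DEFAULT_PHENOTYPES)
    test_table = build_feature_table(test, roi_subset=rois, phenotypes=DEFAULT_PHENOTYPES)
    record.selected_features = list(train_table.feature_names)
    if config.retune_variant:
        return _finish_stage(record, config, train_table, test_table)
    # reuse the blind stage's m instead of re-tuning
    m = blind_record.chosen_m
    record.chosen_m = m
    model = grow(train_table, m)
    atlas = load_atlas()
    record.model = model_to_dict(model)
    record.tree_text = render(model, atlas=atlas, fmt="text")
    record.train_eval = evaluate(predict_table(model, train_table), list(train_table.labels)).to_dict()
    record.test_eval = evaluate(predict_table(model, test_table), list(test_table.labels)).to_dict()
    mean, sd = kfold_accuracy(
        train_table, m, k=config.kfold_k, seed=stage_seed(config.seed, "phenotype_variant:kfold")
    )
    record.cv_mean_pct = 100.0 * mean
    record.cv_sd_pct = 100.0 * sd
    record.status = "ok"
    return record


def write_record(record: RunRecord, out_dir) -> None:
    """Write a stage's artifacts (JSON record + text tree) to a run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{record.stage}_record.json").write_text(record.to_json() + "\n")
    if record.tree_text is not None:
        (out / f"{record.stage}_tree.txt").write_text(record.tree_text + "\n")


def decision_chain_text(model_dict: dict, features: dict, atlas=None) -> str:
    """Human-readable decision chain for one subject under a stored model."""
    from .tree_induction import model_from_dict, _display_name

    model = model_from_dict(model_dict)
    label, chain = predict(model, features)
    steps = [
        f"{_display_name(f, atlas)} {op} {v:.6g}" if op != "==" else f"{_display_name(f, atlas)} == {v}"
        for f, op, v in chain
    ]
    return " -> ".join(steps + [label]) if steps else label
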