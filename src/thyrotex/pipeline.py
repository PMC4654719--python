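"""End-to-end orchestration: ADC -> texture table -> selection -> LDA ->
evaluation, for in-memory nodule lists or file-backed manifests.

``run_training`` reproduces the model-building protocol: extract the
full texture catalogue per slice, nominate 10 features per filter
criterion, merge into a ranked candidate list, backward-eliminate to
the subset with the lowest resubstitution LDA error, train the cutoff,
and report slice- and nodule-level (lowest-scoring-slice) metrics.
``run_test`` applies the frozen model — features, standardization,
weights, and cutoff — to an independent cohort without touching any
held-out statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adc import compute_adc, roi_mean_adc, weighted_mean_adc, ROISummary
from .evaluation import (ConfusionCounts, misclassification_rate, roc_auc,
                         sens_spec_ci, welch_t_test)
from .lda import (LDAModel, choose_cutoff, classify_nodules_lowest_slice,
                  classify_slices, fit_lda, mdf1_scores)
from .selection import backward_eliminate, combine_rankings, rank_features
from .simulate import SyntheticNodule
from .texture import TextureConfig, extract_all

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one analysis run."""

    texture: TextureConfig = field(default_factory=TextureConfig)
    k_each: int = 10             # per-criterion shortlist size
    noise_floor: float = 0.0     # signal rectification level for ADC
    source: str = "adc"          # texture source raster: "adc" | "dwi"
    seed: int = 0


def nodule_adc_summaries(nodule: SyntheticNodule,
                         noise_floor: float = 0.0) -> list[ROISummary]:
    """Per-slice ROI mean ADC summaries for one nodule."""
    out = []
    for pair, roi in zip(nodule.slices, nodule.rois):
        adc = compute_adc(pair, noise_floor=noise_floor)
        s = roi_mean_adc(adc, roi)
        s.nodule_id = nodule.nodule_id
        s.slice_id = pair.slice_id
        out.append(s)
    return out


def nodule_weighted_adc(nodule: SyntheticNodule,
                        noise_floor: float = 0.0) -> float:
    """Area-weighted mean ADC pooled over a nodule's slices."""
    return weighted_mean_adc(nodule_adc_summaries(nodule, noise_floor))


def adc_analysis(nodules: list[SyntheticNodule],
                 noise_floor: float = 0.0) -> dict:
    """The mean-ADC comparison: per-class pooled means and a Welch t
    test of the per-nodule weighted means, plus an ADC-only ROC."""
    wm = {"benign": [], "malignant": []}
    for nod in nodules:
        wm[nod.label].append(nodule_weighted_adc(nod, noise_floor))
    t, df, p = welch_t_test(wm["benign"], wm["malignant"])
    # low ADC indicates malignancy, so score with the negated ADC
    scores = np.array([-v for lab in ("benign", "malignant") for v in wm[lab]])
    labels = np.array([0] * len(wm["benign"]) + [1] * len(wm["malignant"]))
    roc = roc_auc(scores, labels)
    return {
        "weighted_mean_adc_benign": float(np.mean(wm["benign"])),
        "weighted_mean_adc_malignant": float(np.mean(wm["malignant"])),
        "t": t, "df": df, "p_value": p,
        "adc_auc": roc.auc, "adc_auc_ci95": roc.ci95,
        "per_nodule": wm,
    }


def build_feature_table(nodules: list[SyntheticNodule],
                        config: RunConfig | None = None) -> pd.DataFrame:
    """Extract the texture catalogue for every slice of every nodule.

    Texture is read from the ADC map by default (``config.source`` may
    select the raw DW raster instead).  Slices with any undefined
    feature are excluded from the table with a logged reason, mirroring
    a study's exclusion bookkeeping; columns undefined on every slice
    (e.g. a wavelet scale larger than all ROIs) are dropped instead.
    """
    if config is None:
        config = RunConfig()
    rows = []
    for nod in nodules:
        for pair, roi in zip(nod.slices, nod.rois):
            if config.source == "adc":
                raster = compute_adc(pair, config.noise_floor).values
            elif config.source == "dwi":
                raster = pair.sb
            else:
                raise ValueError(f"unknown texture source {config.source!r}")
            feats = extract_all(raster, roi, config.texture)
            row = {"nodule_id": nod.nodule_id, "slice_id": pair.slice_id,
                   "label": nod.label}
            row.update(feats)
            rows.append(row)
    table = pd.DataFrame(rows)
    feat_cols = [c for c in table.columns
                 if c not in ("nodule_id", "slice_id", "label")]
    all_nan = [c for c in feat_cols if table[c].isna().all()]
    if all_nan:
        log.info("dropping %d feature(s) undefined on every slice: %s",
                 len(all_nan), all_nan)
        table = table.drop(columns=all_nan)
        feat_cols = [c for c in feat_cols if c not in all_nan]
    bad = table[feat_cols].isna().any(axis=1)
    if bad.any():
        for sid in table.loc[bad, "slice_id"]:
            log.info("excluding slice %s: undefined feature(s)", sid)
        table = table.loc[~bad].reset_index(drop=True)
    return table


@dataclass
class TrainingResult:
    table: pd.DataFrame
    rankings: dict
    candidates: list[str]
    error_curve: dict[int, float]
    model: LDAModel
    slice_predictions: list
    nodule_predictions: list
    metrics: dict


@dataclass
class TestResult:
    table: pd.DataFrame
    slice_predictions: list
    nodule_predictions: list
    metrics: dict


def _classification_metrics(scores: np.ndarray, labels: np.ndarray,
                            calls: np.ndarray,
                            nodule_calls: list, nodule_labels: list) -> dict:
    correct = int(np.sum(calls == labels))
    counts = ConfusionCounts(
        tp=int(np.sum((calls == 1) & (labels == 1))),
        fp=int(np.sum((calls == 1) & (labels == 0))),
        tn=int(np.sum((calls == 0) & (labels == 0))),
        fn=int(np.sum((calls == 0) & (labels == 1))),
    )
    roc = roc_auc(scores, labels)
    nod_correct = int(sum(c == t for c, t in zip(nodule_calls, nodule_labels)))
    m = {
        "n_slices": int(len(labels)),
        "slices_correct": correct,
        "slice_misclassification_pct": misclassification_rate(correct, len(labels)),
        "slice_auc": roc.auc,
        "slice_auc_ci95": roc.ci95,
        "n_nodules": len(nodule_labels),
        "nodules_correct": nod_correct,
        "nodule_accuracy_pct": 100.0 * nod_correct / len(nodule_labels),
    }
    m.update(sens_spec_ci(counts))
    return m


def _evaluate(model: LDAModel, table: pd.DataFrame):
    labels = (table["label"].to_numpy() == "malignant").astype(int)
    scores = mdf1_scores(model, table)
    slice_preds = classify_slices(model, table)
    calls = np.array([1 if p.call == "malignant" else 0 for p in slice_preds])
    nodule_preds = classify_nodules_lowest_slice(slice_preds, model.mdf1_cutoff)
    truth = table.drop_duplicates("nodule_id").set_index("nodule_id")["label"]
    nodule_labels = [truth[p.nodule_id] for p in nodule_preds]
    nodule_calls = [p.call for p in nodule_preds]
    metrics = _classification_metrics(scores, labels, calls,
                                      nodule_calls, nodule_labels)
    return slice_preds, nodule_preds, metrics


def train_from_table(table: pd.DataFrame,
                     config: RunConfig | None = None) -> TrainingResult:
    """Feature selection + LDA + cutoff from a labeled feature table."""
    if config is None:
        config = RunConfig()
    n_per_class = table.drop_duplicates("nodule_id")["label"].value_counts()
    if n_per_class.get("benign", 0) < 2 or n_per_class.get("malignant", 0) < 2:
        raise ValueError("need at least 2 nodules per class to train")
    rankings = {m: rank_features(table, m, k=config.k_each)
                for m in ("fisher", "mutual_information", "poe_acc")}
    combined = combine_rankings(rankings["fisher"],
                                rankings["mutual_information"],
                                rankings["poe_acc"], k_each=config.k_each)
    selected = backward_eliminate(table, combined.candidates)
    model = fit_lda(table, selected.subset)
    labels = (table["label"].to_numpy() == "malignant").astype(int)
    model.mdf1_cutoff = choose_cutoff(mdf1_scores(model, table), labels)
    slice_preds, nodule_preds, metrics = _evaluate(model, table)
    return TrainingResult(table=table, rankings=rankings,
                          candidates=combined.candidates,
                          error_curve=selected.error_curve,
                          model=model, slice_predictions=slice_preds,
                          nodule_predictions=nodule_preds, metrics=metrics)


def run_training(nodules: list[SyntheticNodule],
                 config: RunConfig | None = None) -> TrainingResult:
    """Full training pass from nodules: extract, select, fit, evaluate."""
    if config is None:
        config = RunConfig()
    table = build_feature_table(nodules, config)
    return train_from_table(table, config)


def run_test(nodules: list[SyntheticNodule], model: LDAModel,
             config: RunConfig | None = None) -> TestResult:
    """Apply a frozen model to an independent cohort."""
    if config is None:
        config = RunConfig()
    table = build_feature_table(nodules, config)
    return test_from_table(table, model)


def test_from_table(table: pd.DataFrame, model: LDAModel) -> TestResult:
    slice_preds, nodule_preds, metrics = _evaluate(model, table)
    return TestResult(table=table, slice_predictions=slice_preds,
                      nodule_predictions=nodule_preds, metrics=metrics)
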