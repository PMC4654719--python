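"""Two-class Fisher linear discriminant with MDF1 scoring.

The model z-scores each selected feature with training statistics,
projects onto w proportional to S_w^-1 (mu_mal - mu_ben) with pooled
within-class covariance S_w (ridge-shrunk if ill-conditioned), and
normalizes w to unit length.  The scalar projection is the "most
discriminant factor 1" (MDF1); the offset centers the pooled training
projection at zero, so a trained cutoff lies near 0.  Orientation is
fixed so malignant slices score high: a slice is called malignant iff
MDF1 > cutoff.

Nodules are classified by their lowest-scoring slice: the nodule's MDF1
is the minimum over its slices, so a single high-scoring slice cannot
flip a nodule to malignant — a deliberately conservative rule that
suppresses false positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class LDAModel:
    features: list[str]
    means: np.ndarray          # per-feature training mean
    sds: np.ndarray            # per-feature training SD (> 0 after guard)
    weights: np.ndarray        # unit-norm projection, malignant side positive
    offset: float              # centers pooled projected mean at 0
    mdf1_cutoff: float = 0.0   # malignant iff MDF1 > cutoff
    shrinkage: float = 0.0     # ridge actually applied to S_w

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("means", "sds", "weights"):
            d[k] = list(map(float, d[k]))
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LDAModel":
        d = json.loads(text)
        for k in ("means", "sds", "weights"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class SlicePrediction:
    nodule_id: str
    slice_id: str
    mdf1: float
    call: str  # "benign" | "malignant"


@dataclass
class NodulePrediction:
    nodule_id: str
    min_mdf1: float
    call: str


def _design(table: pd.DataFrame, features: list[str]) -> np.ndarray:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks model features: {missing}")
    return table[features].to_numpy(dtype=float)


def fit_lda(table: pd.DataFrame, subset: list[str],
            max_condition: float = 1e8) -> LDAModel:
    """Fit the two-class Fisher discriminant on the selected features.

    Within-class covariance is pooled over both classes; if its
    condition number exceeds ``max_condition``, a ridge lambda*I is
    added, stepping lambda up from 1e-8 by decades.  The weight vector
    is scaled to unit norm and oriented so the malignant training mean
    projects higher than the benign one.
    """
    labels = (table["label"].to_numpy() == "malignant").astype(int)
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each class needs >= 2 slices")
    X = _design(table, subset)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        # constant features carry no information; neutralize rather than fail
        sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds

    mu_b = Z[labels == 0].mean(axis=0)
    mu_m = Z[labels == 1].mean(axis=0)
    n = len(labels)
    Sw = np.zeros((Z.shape[1], Z.shape[1]))
    for c, mu in ((0, mu_b), (1, mu_m)):
        D = Z[labels == c] - mu
        Sw += D.T @ D
    Sw /= max(n - 2, 1)

    lam = 0.0
    Sw_reg = Sw
    if np.linalg.cond(Sw) > max_condition:
        lam = 1e-8
        while True:
            Sw_reg = Sw + lam * np.eye(Sw.shape[0])
            if np.linalg.cond(Sw_reg) <= max_condition:
                break
            lam *= 10
            if lam > 1e8:
                raise np.linalg.LinAlgError(
                    "within-class covariance singular after maximal shrinkage")
    w = np.linalg.solve(Sw_reg, mu_m - mu_b)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise np.linalg.LinAlgError("degenerate discriminant direction")
    w = w / norm
    if w @ mu_m < w @ mu_b:
        w = -w
    offset = -float(Z.mean(axis=0) @ w)
    return LDAModel(features=list(subset), means=means, sds=sds,
                    weights=w, offset=offset, shrinkage=lam)


def mdf1_scores(model: LDAModel, table: pd.DataFrame) -> np.ndarray:
    """MDF1 = w . z(x) + offset for every row of the table."""
    X = _design(table, model.features)
    Z = (X - model.means) / model.sds
    return Z @ model.weights + model.offset


def choose_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff minimizing training misclassification under the rule
    "malignant iff score > cutoff".

    Candidate thresholds are midpoints between adjacent distinct sorted
    scores plus sentinels below/above all scores; ties in error are
    broken by maximizing Youden's J, then by preferring the midpoint
    between class-adjacent scores (first in candidate order).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = [uniq[0] - 1.0]
    cands += list((uniq[:-1] + uniq[1:]) / 2.0)
    cands.append(uniq[-1] + 1.0)
    n_pos = max((labels == 1).sum(), 1)
    n_neg = max((labels == 0).sum(), 1)
    best = None
    for c in cands:
        pred = (scores > c).astype(int)
        err = np.mean(pred != labels)
        tpr = np.sum((pred == 1) & (labels == 1)) / n_pos
        fpr = np.sum((pred == 1) & (labels == 0)) / n_neg
        key = (err, -(tpr - fpr))
        if best is None or key < best[0]:
            best = (key, float(c))
    return best[1]


def classify_slices(model: LDAModel, table: pd.DataFrame) -> list[SlicePrediction]:
    """Score each slice and call it by the MDF1 cutoff rule."""
    scores = mdf1_scores(model, table)
    preds = []
    for (_, row), s in zip(table.iterrows(), scores):
        call = "malignant" if s > model.mdf1_cutoff else "benign"
        preds.append(SlicePrediction(nodule_id=str(row.get("nodule_id", "")),
                                     slice_id=str(row.get("slice_id", "")),
                                     mdf1=float(s), call=call))
    return preds


def classify_nodules_lowest_slice(predictions: list[SlicePrediction],
                                  cutoff: float) -> list[NodulePrediction]:
    """Aggregate slice scores to nodule calls via the minimum MDF1."""
    groups: dict[str, list[float]] = {}
    order: list[str] = []
    for p in predictions:
        if p.nodule_id not in groups:
            groups[p.nodule_id] = []
            order.append(p.nodule_id)
        groups[p.nodule_id].append(p.mdf1)
    if any(len(v) == 0 for v in groups.values()) or not groups:
        raise ValueError("every nodule needs >= 1 slice prediction")
    out = []
    for nid in order:
        lo = min(groups[nid])
        out.append(NodulePrediction(
            nodule_id=nid, min_mdf1=float(lo),
            call="malignant" if lo > cutoff else "benign"))
    return out
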