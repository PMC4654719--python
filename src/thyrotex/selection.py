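"""Three-criterion feature ranking and backward elimination.

Mirrors the MaZda/b11 workflow: each of three filter criteria — Fisher
coefficient, mutual information with the class label, and POE+ACC
(probability of classification error plus average correlation with
already-selected features) — nominates its top-k features (k=10 by
default); the union (up to 30 candidates) is ordered by mean
within-method rank; nested head subsets of that order are then evaluated
by resubstitution LDA misclassification and the subset with the lowest
rate wins (ties go to the smaller subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: feature-table metadata columns, everything else is a feature
META_COLUMNS = ("nodule_id", "slice_id", "label")


@dataclass
class FeatureRanking:
    method: str
    ranking: list[tuple[str, float]]  # (feature, score), best first

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.ranking]


@dataclass
class SelectedSubset:
    candidates: list[str]              # combined-rank order, best first
    subset: list[str]                  # final features
    error_curve: dict[int, float] = field(default_factory=dict)
    error_rate: float = float("nan")


def split_table(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into its feature matrix and 0/1 label vector
    (benign=0, malignant=1)."""
    feats = table.drop(columns=[c for c in META_COLUMNS if c in table.columns])
    labels = (table["label"].to_numpy() == "malignant").astype(int)
    return feats, labels


def fisher_coefficient(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-class Fisher ratio F = (mu1 - mu0)^2 / (s1^2 + s0^2).

    Class variances are unbiased.  Zero pooled variance with equal means
    gives 0; with distinct means, +inf.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a, b = values[labels == 0], values[labels == 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 samples")
    num = (a.mean() - b.mean()) ** 2
    den = a.var(ddof=1) + b.var(ddof=1)
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / den)


def mutual_information(values: np.ndarray, labels: np.ndarray,
                       n_bins: int = 10) -> float:
    """Mutual information (nats) between an equal-frequency-binned
    feature and the class label.

    A constant feature (single occupied bin) carries zero information.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        return 0.0
    binned = np.clip(np.searchsorted(edges, values, side="right") - 1,
                     0, len(edges) - 2)
    n = len(values)
    mi = 0.0
    for b in np.unique(binned):
        pb = np.mean(binned == b)
        for c in np.unique(labels):
            pbc = np.mean((binned == b) & (labels == c))
            if pbc > 0:
                mi += pbc * np.log(pbc / (pb * np.mean(labels == c)))
    return float(max(mi, 0.0))


def _poe(values: np.ndarray, labels: np.ndarray) -> float:
    """Resubstitution error of a nearest-class-mean classifier on a
    standardized single feature."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    m0 = z[labels == 0].mean()
    m1 = z[labels == 1].mean()
    pred = (np.abs(z - m1) < np.abs(z - m0)).astype(int)
    return float(np.mean(pred != labels))


def rank_features(table: pd.DataFrame, method: str, k: int = 10) -> FeatureRanking:
    """Rank all features of a labeled table by one filter criterion.

    ``fisher`` and ``mutual_information`` rank globally (larger better);
    ``poe_acc`` runs the greedy forward selection and reports the first
    k features in selection order (scores are POE + ACC at selection
    time, smaller better).  Ties are broken by column (registry) order.
    """
    feats, labels = split_table(table)
    if method == "fisher":
        scores = [(c, fisher_coefficient(feats[c].to_numpy(), labels))
                  for c in feats.columns]
        order = sorted(range(len(scores)), key=lambda i: (-scores[i][1], i))
        return FeatureRanking("fisher", [scores[i] for i in order])
    if method == "mutual_information":
        scores = [(c, mutual_information(feats[c].to_numpy(), labels))
                  for c in feats.columns]
        order = sorted(range(len(scores)), key=lambda i: (-scores[i][1], i))
        return FeatureRanking("mutual_information", [scores[i] for i in order])
    if method == "poe_acc":
        return poe_acc_rank(table, k=k)
    raise ValueError(f"unknown ranking method {method!r}")


def poe_acc_rank(table: pd.DataFrame, k: int = 10) -> FeatureRanking:
    """Greedy POE+ACC forward selection.

    The first feature minimizes POE; each subsequent feature minimizes
    POE(f) + ACC(f, selected), where ACC is the mean absolute Pearson
    correlation with already-selected features.  Ties are broken by
    column order.
    """
    feats, labels = split_table(table)
    cols = list(feats.columns)
    if len(cols) < k:
        raise ValueError(f"need >= {k} features, got {len(cols)}")
    X = feats.to_numpy(dtype=float)
    poe = np.array([_poe(X[:, j], labels) for j in range(len(cols))])
    # correlations on standardized columns; constant columns correlate 0
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0
    corr = np.abs(Z.T @ Z) / len(labels)

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(len(cols)))
    for _ in range(k):
        best_j, best_s = None, None
        for j in remaining:
            s = poe[j]
            if selected:
                s = s + float(np.mean(corr[j, selected]))
            if best_s is None or s < best_s - 1e-15:
                best_j, best_s = j, s
        selected.append(best_j)
        scores.append(float(best_s))
        remaining.remove(best_j)
    return FeatureRanking("poe_acc",
                          [(cols[j], s) for j, s in zip(selected, scores)])


def combine_rankings(r_fisher: FeatureRanking, r_mi: FeatureRanking,
                     r_poe: FeatureRanking, k_each: int = 10) -> SelectedSubset:
    """Union of the three top-k lists, ordered by mean within-method rank.

    A feature absent from a method's top-k receives rank k+1 there; ties
    are broken by the Fisher score (larger first), then by Fisher rank.
    """
    tops = {
        "fisher": r_fisher.features[:k_each],
        "mutual_information": r_mi.features[:k_each],
        "poe_acc": r_poe.features[:k_each],
    }
    fisher_score = dict(r_fisher.ranking)
    union: list[str] = []
    for lst in tops.values():
        for f in lst:
            if f not in union:
                union.append(f)

    def mean_rank(f: str) -> float:
        ranks = []
        for lst in tops.values():
            ranks.append(lst.index(f) + 1 if f in lst else k_each + 1)
        return float(np.mean(ranks))

    fisher_order = {f: i for i, f in enumerate(r_fisher.features)}
    ordered = sorted(union, key=lambda f: (mean_rank(f),
                                           -fisher_score.get(f, 0.0),
                                           fisher_order.get(f, len(fisher_order))))
    return SelectedSubset(candidates=ordered, subset=list(ordered))


def backward_eliminate(table: pd.DataFrame, candidates: list[str],
                       classifier=None) -> SelectedSubset:
    """Pick the head subset of the candidate order with the lowest
    resubstitution LDA misclassification rate on slices.

    Evaluates top-m for m = len(candidates) down to 2; ties prefer the
    smallest m.  Subsets where the LDA fit degenerates (singular
    within-class covariance even after shrinkage) are skipped.
    """
    from .lda import fit_lda, classify_slices, choose_cutoff

    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate features")
    labels = (table["label"].to_numpy() == "malignant").astype(int)
    curve: dict[int, float] = {}
    for m in range(len(candidates), 1, -1):
        subset = candidates[:m]
        try:
            model = fit_lda(table, subset)
            scores = np.array([p.mdf1 for p in classify_slices(model, table)])
            model.mdf1_cutoff = choose_cutoff(scores, labels)
            calls = (scores > model.mdf1_cutoff).astype(int)
            curve[m] = float(np.mean(calls != labels))
        except np.linalg.LinAlgError:
            continue
    if not curve:
        raise RuntimeError("LDA degenerate for every candidate subset size")
    best_m = min(curve, key=lambda m: (curve[m], m))
    return SelectedSubset(candidates=list(candidates),
                          subset=candidates[:best_m],
                          error_curve=curve,
                          error_rate=curve[best_m])
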