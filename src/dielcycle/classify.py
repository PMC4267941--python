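"""Predicting phase of cyclic expression from promoter motif presence.

Two classifiers mirror the two natural baselines for asking whether pCREs
carry phase information.  The *naive* classifier scores a gene by how many
of a phase's motifs occur in its promoter (and calls it positive when at
least one does).  The *max-margin* classifier is a linear SVM on the full
gene x motif presence matrix with a grid search over the margin penalty C
and the training negative:positive ratio R (implemented by seeded
subsampling of negatives in each training fold), evaluated by stratified
10-fold cross-validated AUC-ROC.  A survey runs the SVM over many small
gene clusters (phase-expression or phase-function) and counts how many are
classifiable above an AUC threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .enrichment import enrich_per_phase

__all__ = [
    "rank_metrics",
    "pcre_enrichment",
    "ClassifierReport",
    "naive_phase_classifier",
    "svm_phase_classifier",
    "cluster_classification_survey",
    "DEFAULT_C_GRID",
    "DEFAULT_R_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 0.5, 1, 1.5, 2.0)
DEFAULT_R_GRID = (0.25, 0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4)


def rank_metrics(
    scores: np.ndarray, labels: np.ndarray, predictions: np.ndarray | None = None
) -> dict:
    """AUC-ROC (rank statistic with tie correction) and F-measure.

    The AUC is the Mann-Whitney U of positive over negative scores divided
    by ``n_pos * n_neg`` — identical to trapezoidal integration of the ROC
    curve.  The F-measure is computed at the supplied binary operating
    point (default: ``scores >= 1``, the >= 1-site rule of the naive
    classifier).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    auc = u / (n_pos * n_neg)
    pred = scores >= 1 if predictions is None else np.asarray(predictions, bool)
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {"auc": float(auc), "f_measure": float(f),
            "n_pos": n_pos, "n_neg": n_neg}


def pcre_enrichment(
    presence: pd.DataFrame,
    phase_of_gene: pd.Series,
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-phase motif enrichment and most-significant-phase assignment.

    ``presence`` is the genes x motifs boolean matrix; each motif's
    presence set is tested for over-representation in every phase cluster
    against all cycling genes (Fisher + BH per phase).  Each motif is then
    assigned the phase where its adjusted p is smallest, ties broken toward
    the earlier ZT.  Motifs present in no promoter raise.
    """
    if (presence.sum(axis=0) == 0).any():
        empty = presence.columns[presence.sum(axis=0) == 0]
        raise ValueError(f"motifs present in zero promoters: {list(empty)}")
    common = presence.index.intersection(phase_of_gene.index)
    pres = presence.loc[common]
    annotation = (
        pres.stack()[lambda s: s]
        .reset_index()
        .iloc[:, :2]
        .set_axis(["gene_id", "term_id"], axis=1)
    )
    table = enrich_per_phase(
        phase_of_gene.loc[common], annotation, background=background, alpha=alpha
    )
    # assignment: minimal adjusted p, then earlier phase
    order = table.sort_values(["p_adj", "phase"], kind="stable")
    assignment = order.groupby("term_id", sort=True)["phase"].first()
    assignment.index.name = "motif_id"
    return table, assignment


@dataclass
class ClassifierReport:
    """Cross-validated performance of one phase/cluster classifier."""

    label: object
    auc_mean: float
    auc_folds: list[float] = field(default_factory=list)
    f_measure: float = np.nan
    C: float | None = None
    R: float | None = None
    n_pos: int = 0
    n_neg: int = 0
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.auc_mean <= 1:
            raise ValueError("AUC must lie in [0, 1]")


def naive_phase_classifier(
    presence: pd.DataFrame,
    motif_phase: pd.Series,
    phase_of_gene: pd.Series,
) -> list[ClassifierReport]:
    """Count-of-phase-motifs classifier, one report per phase.

    For each phase, a gene's score is the number of that phase's assigned
    motifs present in its promoter (used for the AUC ranking); the
    operating point for the F-measure is the literal >= 1 motif rule.
    """
    common = presence.index.intersection(phase_of_gene.index)
    pres = presence.loc[common]
    labels_all = phase_of_gene.loc[common]
    reports = []
    for zt in sorted(motif_phase.unique()):
        motifs = motif_phase.index[motif_phase == zt]
        scores = pres[motifs].sum(axis=1).to_numpy(float)
        labels = (labels_all == zt).to_numpy()
        m = rank_metrics(scores, labels)
        reports.append(
            ClassifierReport(
                label=zt, auc_mean=m["auc"], f_measure=m["f_measure"],
                n_pos=m["n_pos"], n_neg=m["n_neg"],
            )
        )
    return reports


def _subsample_negatives(
    train_idx: np.ndarray, y: np.ndarray, ratio: float, rng: np.random.Generator
) -> np.ndarray:
    pos = train_idx[y[train_idx]]
    neg = train_idx[~y[train_idx]]
    want = int(round(ratio * pos.size))
    if want < 1:
        want = 1
    if want < neg.size:
        neg = rng.choice(neg, size=want, replace=False)
    return np.concatenate([pos, neg])


def svm_phase_classifier(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    C_grid=DEFAULT_C_GRID,
    R_grid=DEFAULT_R_GRID,
    folds: int = 10,
    seed: int = 0,
    label: object = None,
) -> ClassifierReport:
    """Grid-searched linear SVM on presence features, one-vs-rest.

    For every (C, R) pair, stratified ``folds``-fold cross validation is
    run; in each training fold the negatives are subsampled (seeded) to a
    negative:positive ratio of R, a linear max-margin classifier is fit,
    and the held-out fold is scored by its decision function.  The pair
    with the best mean AUC is reported, together with the F-measure at the
    decision boundary and the features receiving nonzero weight in a final
    fit on all data.
    """
    X = features.to_numpy(float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < folds or n_neg < folds:
        folds = max(2, min(n_pos, n_neg))
        warnings.warn(f"too few examples for 10 folds; using {folds}")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best = None
    for C in C_grid:
        for R in R_grid:
            aucs, f_parts = [], []
            fold_rng = np.random.default_rng(rng.integers(2**31))
            for train_idx, test_idx in splits:
                sel = _subsample_negatives(train_idx, y, R, fold_rng)
                clf = LinearSVC(C=C, dual="auto")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X[sel], y[sel])
                dec = clf.decision_function(X[test_idx])
                if y[test_idx].all() or not y[test_idx].any():
                    continue  # unscoreable fold (tiny classes)
                m = rank_metrics(dec, y[test_idx], predictions=dec >= 0)
                aucs.append(m["auc"])
                f_parts.append(m["f_measure"])
            if not aucs:
                continue
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[0]:
                best = (mean_auc, C, R, aucs, float(np.mean(f_parts)))
    if best is None:
        raise ValueError("grid infeasible: no fold had both classes")
    mean_auc, C, R, aucs, f = best
    final_rng = np.random.default_rng(seed + 1)
    sel = _subsample_negatives(np.arange(len(y)), y, R, final_rng)
    clf = LinearSVC(C=C, dual="auto")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X[sel], y[sel])
    weights = pd.Series(clf.coef_[0], index=features.columns, name="weight")
    return ClassifierReport(
        label=label, auc_mean=mean_auc, auc_folds=aucs, f_measure=f,
        C=C, R=R, n_pos=n_pos, n_neg=n_neg,
        weights=weights[weights != 0],
    )


def cluster_classification_survey(
    clusters: dict[object, set[str]],
    features: pd.DataFrame,
    universe: set[str] | None = None,
    auc_threshold: float = 0.7,
    min_positives: int = 8,
    n_cycling: int | None = None,
    **svm_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """SVM-classify every cluster against the remaining genes and tally.

    For each cluster the positives are its members (with features) and the
    negatives the rest of ``universe``.  Returns the per-cluster survey
    table and a summary with the count of clusters above ``auc_threshold``
    and the fraction of genes they cover (relative to ``n_cycling`` when
    given, else to the universe size).
    """
    universe = set(universe) if universe is not None else set(features.index)
    rows = []
    for label, members in clusters.items():
        pos = sorted(set(members) & universe & set(features.index))
        if len(pos) < min_positives:
            rows.append({"cluster": label, "n": len(pos), "auc": np.nan,
                         "skipped": "below minimum size"})
            continue
        genes = sorted(universe & set(features.index))
        X = features.loc[genes]
        y = pd.Series([g in set(pos) for g in genes], index=genes)
        report = svm_phase_classifier(X, y, label=label, **svm_kwargs)
        rows.append({"cluster": label, "n": len(pos), "auc": report.auc_mean,
                     "skipped": ""})
    survey = pd.DataFrame(rows, columns=["cluster", "n", "auc", "skipped"])
    above = survey[survey["auc"] > auc_threshold]
    covered = int(above["n"].sum())
    denom = n_cycling if n_cycling is not None else len(universe)
    summary = {
        "n_clusters": int(survey["auc"].notna().sum()),
        "n_above_threshold": int(len(above)),
        "genes_covered": covered,
        "coverage_pct": round(100 * covered / denom, 2) if denom else np.nan,
    }
    return survey, summary
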