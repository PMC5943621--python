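"""Multi-feature predictors over selected group-specific k-mers.

Redundant features are pruned greedily by Pearson correlation (higher-ASS
member of a correlated pair wins), survivors are ranked by Breiman-style
out-of-bag permutation importance over a bagged forest of decision trees,
and the top-n features feed a random-forest classifier.  A repeated
stratified cross-validation harness rebuilds the matrix, the sparsity filter
and both selection tracks inside every training fold, so held-out samples
never influence feature choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .io import SampleSheet
from .kmers import KmerVector
from .matrix import FeatureMatrix, build_matrix, filter_sparse, project_vectors
from .select import CASE_PRESENT, GroupSpecificFeature, select_features

__all__ = [
    "PredictorModel",
    "CVResult",
    "decorrelate",
    "rank_importance",
    "fit_rf",
    "fit_single_logical",
    "predict",
    "roc_auc",
    "cross_validate",
]


def _child_seeds(seed: int | None, n: int) -> list[int]:
    """Counter-based expansion of one pipeline seed (all below 2**31)."""
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def decorrelate(
    features: Sequence[GroupSpecificFeature],
    F: FeatureMatrix,
    pcc_max: float = 0.75,
    seed: int | None = None,
    max_candidates: int | None = None,
) -> list[GroupSpecificFeature]:
    """Greedy correlation pruning in descending-ASS order.

    A feature is kept iff |PCC| <= pcc_max against every feature already
    kept; of a correlated pair the higher-ASS member survives (deterministic
    replacement for random discarding).  Rows with zero variance correlate 0
    with everything.  ``max_candidates`` optionally caps the pass to the
    best-scored candidates.
    """
    feats = sorted(features, key=GroupSpecificFeature.sort_key)
    if max_candidates is not None:
        feats = feats[:max_candidates]
    if not feats:
        return []
    rows = F.index_of([f.kmer for f in feats])
    X = F.dense(rows)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    n = X.shape[1]
    kept_idx: list[int] = []
    for i in range(len(feats)):
        if kept_idx:
            r = Z[kept_idx] @ Z[i] / n
            if np.any(np.abs(r) > pcc_max):
                continue
        kept_idx.append(i)
    return [feats[i] for i in kept_idx]


def rank_importance(
    X: np.ndarray,
    labels: Sequence[int],
    features: Sequence[GroupSpecificFeature],
    n_trees: int = 500,
    seed: int | None = None,
) -> list[GroupSpecificFeature]:
    """Rank features by mean decrease in out-of-bag accuracy on permutation.

    Classic bagged-forest variable importance: each tree is fitted on a
    bootstrap sample; its OOB accuracy is compared with the accuracy after
    permuting one feature among the OOB rows, and decreases are averaged
    over trees.  Ties break by training ASS, then k-mer.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    n, f = X.shape
    if f != len(features):
        raise ValueError("X columns must align with features")
    if f < 2:
        return list(features)
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    imp = np.zeros(f)
    used = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            random_state=int(rng.integers(2**31))
        ).fit(X[boot], y[boot])
        y_oob = y[oob]
        base = float((tree.predict(X[oob]) == y_oob).mean())
        Xo = X[oob].copy()
        for j in range(f):
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[rng.permutation(oob.size)]
            acc = float((tree.predict(Xo) == y_oob).mean())
            imp[j] += base - acc
            Xo[:, j] = saved
        used += 1
    if used:
        imp /= used
    order = sorted(
        range(f), key=lambda j: (-imp[j], -features[j].ass_train, features[j].kmer)
    )
    return [features[j] for j in order]


@dataclass
class PredictorModel:
    """A fitted predictor over an ordered list of k-mer features."""

    model_kind: str  # "single-logical" | "single-logistic" | "random-forest"
    features: list[str]
    orientation: str | None = None
    coef: tuple[float, float] | None = None
    rf: RandomForestClassifier | None = None
    train_score: float | None = None
    seed: int | None = None


def fit_single_logical(feature: GroupSpecificFeature) -> PredictorModel:
    return PredictorModel(
        model_kind="single-logical",
        features=[feature.kmer],
        orientation=feature.orientation,
        train_score=feature.ass_train,
    )


def fit_rf(
    X: np.ndarray,
    labels: Sequence[int],
    features: Sequence[GroupSpecificFeature | str],
    n_trees: int = 500,
    seed: int | None = None,
) -> PredictorModel:
    """Random forest over the top-n selected k-mers (samples x features)."""
    y = np.asarray(labels).astype(int)
    names = [f.kmer if isinstance(f, GroupSpecificFeature) else str(f) for f in features]
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=_child_seeds(seed, 1)[0], n_jobs=1
    )
    rf.fit(np.asarray(X, dtype=float), y)
    _, auc = roc_auc(predict_with_rf(rf, X, y), y)
    return PredictorModel(
        model_kind="random-forest", features=names, rf=rf, train_score=auc, seed=seed
    )


def predict_with_rf(rf: RandomForestClassifier, X, y_classes_hint=None) -> np.ndarray:
    proba = rf.predict_proba(np.asarray(X, dtype=float))
    if proba.shape[1] == 1:  # degenerate single-class training fold
        return np.full(proba.shape[0], float(rf.classes_[0]))
    case_col = int(np.flatnonzero(rf.classes_ == 1)[0])
    return proba[:, case_col]


def predict(model: PredictorModel, X: np.ndarray) -> np.ndarray:
    """Per-sample case probability (or {0,1} for the logical predictor).

    ``X`` is (n_samples x n_features) aligned with ``model.features``; the
    caller projects new samples onto those rows (absent k-mer -> 0) — see
    :func:`kmersig.matrix.project_vectors`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.features):
        raise ValueError(
            f"got {X.shape[1]} feature columns, model has {len(model.features)}"
        )
    if model.model_kind == "single-logical":
        present = X[:, 0] > 0
        if model.orientation == CASE_PRESENT:
            return present.astype(float)
        return (~present).astype(float)
    if model.model_kind == "single-logistic":
        b0, b1 = model.coef
        return 1.0 / (1.0 + np.exp(-np.clip(b0 + b1 * X[:, 0], -35, 35)))
    if model.model_kind == "random-forest":
        return predict_with_rf(model.rf, X)
    raise ValueError(f"unknown model kind {model.model_kind!r}")


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """ROC points and AUC; AUC is the Mann-Whitney U statistic normalized by
    n_case * n_control, with ties given half credit."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("labels must contain both groups")
    ranks = stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - n_case * (n_case + 1) / 2.0) / (n_case * n_ctrl)
    # ROC points at every distinct threshold, descending
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    distinct = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_case]
    fpr = np.r_[0.0, fps[distinct] / n_ctrl]
    return np.column_stack([fpr, tpr]), float(auc)


@dataclass
class CVResult:
    """Aggregate of repeated stratified k-fold cross-validation."""

    runs: int
    folds: int
    per_run_auc: np.ndarray  # (runs,) mean fold AUC per run
    fold_auc: np.ndarray  # (runs, folds)
    mean_auc: float
    ci95: tuple[float, float]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray  # (runs, grid) per-run fold-averaged ROC
    fold_features: list  # [run][fold] -> list of selected k-mers (train side)
    seed: int | None = None


def cross_validate(
    vectors: Sequence[KmerVector],
    sheet: SampleSheet,
    config=None,
    runs: int | None = None,
    folds: int | None = None,
    seed: int | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV with per-fold feature selection.

    For every fold, matrix construction, sparsity filtering, both selection
    tracks, decorrelation, importance ranking and forest training see only
    that fold's training samples; held-out columns are projected onto the
    fold's selected rows afterwards.  Folds with an empty selection score
    every held-out sample 0.5.
    """
    from .pipeline import Config  # local import to avoid a cycle

    cfg = config if config is not None else Config()
    runs = cfg.runs if runs is None else runs
    folds = cfg.folds if folds is None else folds
    seed = cfg.seed if seed is None else seed
    labels = sheet.labels
    if min(sheet.n_case, sheet.n_control) < folds:
        raise ValueError(
            f"each group must have at least {folds} samples for {folds}-fold CV"
        )
    run_seeds = _child_seeds(seed, 2 * runs)
    grid = np.linspace(0.0, 1.0, 101)
    per_run_auc = np.zeros(runs)
    fold_auc = np.zeros((runs, folds))
    mean_tpr = np.zeros((runs, grid.size))
    fold_features: list[list[list[str]]] = []
    for r in range(runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=run_seeds[r])
        tprs = []
        run_feats: list[list[str]] = []
        for fi, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            scores, feats = _fit_predict_fold(
                [vectors[i] for i in tr],
                sheet.subset(tr),
                [vectors[i] for i in te],
                cfg,
                fold_seed=run_seeds[runs + r] + fi,
            )
            run_feats.append(feats)
            points, auc = roc_auc(scores, labels[te])
            fold_auc[r, fi] = auc
            tprs.append(_interp_roc(points, grid))
        per_run_auc[r] = fold_auc[r].mean()
        mean_tpr[r] = np.mean(tprs, axis=0)
        fold_features.append(run_feats)
    mean_auc = float(per_run_auc.mean())
    if runs > 1:
        half = float(
            stats.t.ppf(0.975, runs - 1) * per_run_auc.std(ddof=1) / np.sqrt(runs)
        )
    else:
        half = 0.0
    return CVResult(
        runs=runs,
        folds=folds,
        per_run_auc=per_run_auc,
        fold_auc=fold_auc,
        mean_auc=mean_auc,
        ci95=(mean_auc - half, mean_auc + half),
        fpr_grid=grid,
        mean_tpr=mean_tpr,
        fold_features=fold_features,
        seed=seed,
    )


def _interp_roc(points: np.ndarray, grid: np.ndarray) -> np.ndarray:
    fpr, tpr = points[:, 0], points[:, 1]
    return np.interp(grid, fpr, tpr)


def _fit_predict_fold(train_vectors, train_sheet, test_vectors, cfg, fold_seed):
    """Select features and fit the top-n forest on one training fold."""
    F = filter_sparse(build_matrix(train_vectors, train_sheet), cfg.sparsity)
    feats = select_features(
        F, theta1=cfg.theta1, theta2=cfg.theta2, theta3=cfg.theta3, metric=cfg.metric
    )
    names = [f.kmer for f in feats]
    if not feats:
        return np.full(len(test_vectors), 0.5), names
    kept = decorrelate(
        feats, F, pcc_max=cfg.pcc_max, seed=fold_seed,
        max_candidates=cfg.max_decorrelation_candidates,
    )
    rows = F.index_of([f.kmer for f in kept])
    X_tr = F.dense(rows).T
    ranked = rank_importance(
        X_tr, train_sheet.labels, kept, n_trees=cfg.n_trees, seed=fold_seed
    )
    top = ranked[: cfg.top_n]
    rows_top = F.index_of([f.kmer for f in top])
    model = fit_rf(
        F.dense(rows_top).T, train_sheet.labels, top,
        n_trees=cfg.n_trees, seed=fold_seed,
    )
    X_te = project_vectors(test_vectors, F.keys[rows_top], F.k)
    return predict(model, X_te), names
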