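"""Group-specific k-mer feature selection.

Two tracks, both evaluated on training samples only:

* **logical** — a k-mer's presence/absence is itself a classifier.  Its score
  is the ASS (average of sensitivity and specificity), maximized over the two
  possible orientations (presence predicts case, or presence predicts
  control), so ASS always lies in [0.5, 1].  K-mers with ASS >= theta1 are
  group-specific.  A Pearson chi-squared ranking (2x2 presence-by-group
  table, 1 df, no continuity correction) is available as an alternative
  metric and cuts the ranked list at the same size as the ASS cut.
* **numerical** — among rows *not* selected logically, the Wilcoxon rank-sum
  test keeps rows whose frequency distributions differ between groups
  (two-sided p <= theta2); each survivor is fitted with a one-covariate
  logistic regression and kept if its in-sample ASS >= theta3.

ASS ties in the output ordering break lexicographically by k-mer so that
selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .matrix import FeatureMatrix

__all__ = [
    "GroupSpecificFeature",
    "logicalize",
    "ass_logical",
    "chi2_logical",
    "select_logical",
    "wilcoxon_filter",
    "wilcoxon_pvalues",
    "logistic_ass",
    "select_numerical",
    "select_features",
    "write_features_tsv",
    "read_features_tsv",
]

CASE_PRESENT = "case-present"
CONTROL_PRESENT = "control-present"


@dataclass
class GroupSpecificFeature:
    """A selected k-mer with its track, orientation and training scores."""

    kmer: str
    track: str  # "logical" | "numerical"
    orientation: str  # CASE_PRESENT | CONTROL_PRESENT
    ass_train: float
    p_value: float | None = None
    selected_by: str = "ASS"  # "ASS" | "chi2"
    coef: tuple[float, float] | None = None  # (intercept, slope) for numerical

    def sort_key(self):
        return (-self.ass_train, self.kmer)


def logicalize(F: FeatureMatrix) -> sp.csr_matrix:
    """0/1 presence matrix: entry is 1 iff the frequency is positive."""
    return F.presence()


def _ass_from_counts(pres_case, pres_ctrl, n_case: int, n_ctrl: int):
    """Vectorized ASS over both orientations; returns (ass, case_present?)."""
    sens = pres_case / n_case
    spec = (n_ctrl - pres_ctrl) / n_ctrl
    ass_cp = (sens + spec) / 2.0  # presence predicts case
    ass = np.maximum(ass_cp, 1.0 - ass_cp)
    return ass, ass_cp >= 1.0 - ass_cp


def ass_logical(row: Sequence[float], labels: Sequence[int]) -> tuple[float, str]:
    """Best-orientation ASS of a single presence row.

    ``row`` is truthy where the k-mer is present; ``labels`` is 1 for case.
    Returns (ass, orientation) with ass in [0.5, 1].
    """
    row = np.asarray(row) > 0
    labels = np.asarray(labels).astype(int)
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("labels must contain both groups")
    pres_case = int(row[labels == 1].sum())
    pres_ctrl = int(row[labels == 0].sum())
    ass, cp = _ass_from_counts(
        np.array([pres_case]), np.array([pres_ctrl]), n_case, n_ctrl
    )
    return float(ass[0]), CASE_PRESENT if cp[0] else CONTROL_PRESENT


def _chi2_from_counts(pres_case, pres_ctrl, n_case: int, n_ctrl: int) -> np.ndarray:
    """Pearson chi-squared p-values on 2x2 presence-by-group tables (1 df)."""
    a = np.asarray(pres_case, dtype=float)  # case, present
    b = np.asarray(pres_ctrl, dtype=float)  # control, present
    c = n_case - a  # case, absent
    d = n_ctrl - b  # control, absent
    n = float(n_case + n_ctrl)
    row1 = a + b
    row0 = c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (row1 * row0 * n_case * n_ctrl)
    p = stats.chi2.sf(stat, df=1)
    degenerate = (row1 == 0) | (row0 == 0)
    p = np.where(degenerate, 1.0, p)
    return p


def chi2_logical(row: Sequence[float], labels: Sequence[int]) -> float:
    """Chi-squared p of one presence row; degenerate tables give p = 1."""
    row = np.asarray(row) > 0
    labels = np.asarray(labels).astype(int)
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("labels must contain both groups")
    p = _chi2_from_counts(
        np.array([row[labels == 1].sum()]),
        np.array([row[labels == 0].sum()]),
        n_case,
        n_ctrl,
    )
    return float(p[0])


def _presence_counts(F: FeatureMatrix, labels: np.ndarray):
    B = F.presence()
    pres_case = np.asarray(B[:, labels == 1].sum(axis=1)).ravel()
    pres_ctrl = np.asarray(B[:, labels == 0].sum(axis=1)).ravel()
    return pres_case, pres_ctrl


def select_logical(
    F: FeatureMatrix,
    labels: Sequence[int] | None = None,
    theta1: float = 0.8,
    metric: str = "ass",
) -> list[GroupSpecificFeature]:
    """All rows whose single-logical-feature predictor reaches ASS >= theta1.

    With ``metric="chi2"`` the list is instead the chi-squared ranking cut at
    the same size as the ASS cut (the two rankings are strongly concordant).
    Output is sorted by descending training ASS, then k-mer.
    """
    labels = F.labels if labels is None else np.asarray(labels).astype(int)
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("labels must contain both groups")
    pres_case, pres_ctrl = _presence_counts(F, labels)
    ass, cp = _ass_from_counts(pres_case, pres_ctrl, n_case, n_ctrl)
    kmers = F.kmers
    n_ass = int((ass >= theta1).sum())
    if metric == "ass":
        idx = np.flatnonzero(ass >= theta1)
        pvals = [None] * idx.size
        by = "ASS"
    elif metric == "chi2":
        p = _chi2_from_counts(pres_case, pres_ctrl, n_case, n_ctrl)
        order = np.lexsort((kmers, p))
        idx = order[:n_ass]
        pvals = p[idx].tolist()
        by = "chi2"
    else:
        raise ValueError(f"metric must be 'ass' or 'chi2', got {metric!r}")
    feats = [
        GroupSpecificFeature(
            kmer=str(kmers[i]),
            track="logical",
            orientation=CASE_PRESENT if cp[i] else CONTROL_PRESENT,
            ass_train=float(ass[i]),
            p_value=pv if pv is None else float(pv),
            selected_by=by,
        )
        for i, pv in zip(idx, pvals)
    ]
    feats.sort(key=GroupSpecificFeature.sort_key)
    return feats


# -- Wilcoxon rank-sum -------------------------------------------------------


@lru_cache(maxsize=8)
def _exact_u_pvalues(n1: int, n2: int) -> np.ndarray:
    """Two-sided p-value of every U in [0, n1*n2] under the exact null.

    Counts of rank-sum subsets via the standard recurrence
    K(i, j, u) = K(i-1, j, u-j) + K(i, j-1, u); evaluated once per group-size
    pair so the per-row cost is a table lookup.
    """
    m = n1 * n2
    prev = [np.zeros(m + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1.0
    for i in range(1, n1 + 1):
        cur = [np.zeros(m + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n2 + 1):
            cur[j][:] = cur[j - 1]
            cur[j][j:] += prev[j][: m + 1 - j]
        prev = cur
    pmf = prev[n2] / prev[n2].sum()
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(U >= u)
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def wilcoxon_pvalues(X: np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """Two-sided rank-sum p-value per row of a dense (rows x samples) matrix.

    Both group sizes <= 10 and no ties in the row: exact Mann-Whitney U null
    distribution.  Otherwise: normal approximation with tie correction and
    continuity correction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels).astype(int)
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("labels must contain both groups")
    n = n_case + n_ctrl

    ranks = stats.rankdata(X, axis=1)
    r_case = ranks[:, labels == 1].sum(axis=1)
    U = r_case - n_case * (n_case + 1) / 2.0
    mu = n_case * n_ctrl / 2.0

    # tie correction: sum over tied groups of (t^3 - t), per row
    Xs = np.sort(X, axis=1)
    same = Xs[:, 1:] == Xs[:, :-1]
    # run lengths of equal values
    tie_term = np.zeros(X.shape[0])
    if same.any():
        for i in np.flatnonzero(same.any(axis=1)):
            _, counts = np.unique(Xs[i], return_counts=True)
            t = counts[counts > 1].astype(float)
            tie_term[i] = float((t**3 - t).sum())
    var = n_case * n_ctrl / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U - mu) - 0.5) / np.sqrt(var)
    z = np.where(np.abs(U - mu) <= 0.5, 0.0, z)
    p = np.where(var > 0, 2.0 * stats.norm.sf(z), 1.0)
    p = np.minimum(p, 1.0)

    if n_case <= 10 and n_ctrl <= 10:
        tie_free = ~same.any(axis=1)
        if tie_free.any():
            table = _exact_u_pvalues(n_case, n_ctrl)
            u_int = np.rint(U[tie_free]).astype(int)
            p[tie_free] = table[u_int]
    return p


def wilcoxon_filter(
    F: FeatureMatrix,
    labels: Sequence[int] | None = None,
    theta2: float = 0.01,
    rows: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(row indices with p <= theta2, their p-values)."""
    labels = F.labels if labels is None else np.asarray(labels).astype(int)
    if rows is None:
        rows = np.arange(F.n_features)
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        return rows, np.empty(0)
    p = wilcoxon_pvalues(F.dense(rows), labels)
    keep = p <= theta2
    return rows[keep], p[keep]


# -- single-numerical-feature logistic regression ----------------------------


def _fit_logistic_many(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 60, tol: float = 1e-10
):
    """Newton/IRLS fit of p = sigmoid(b0 + b1*x) for every row of X.

    Returns (B, converged): B has shape (rows, 2).  ``ridge`` penalizes the
    slope only.  Rows that diverge keep their last finite estimate and are
    flagged unconverged.
    """
    R, N = X.shape
    b0 = np.zeros(R)
    b1 = np.zeros(R)
    active = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        xa = X[active]
        eta = b0[active, None] + b1[active, None] * xa
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        resid = p - y[None, :]
        g0 = resid.sum(axis=1)
        g1 = (resid * xa).sum(axis=1) + ridge * b1[active]
        h00 = w.sum(axis=1) + 1e-12
        h01 = (w * xa).sum(axis=1)
        h11 = (w * xa * xa).sum(axis=1) + ridge + 1e-12
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.maximum(np.abs(d0), np.abs(d1)), 0, None)
        d0 = np.clip(d0, -50, 50)
        d1 = np.clip(d1, -1e7, 1e7)
        b0[active] -= d0
        b1[active] -= d1
        done = step < tol
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    converged = ~active & np.isfinite(b0) & np.isfinite(b1)
    # runaway coefficients signal separation even if the step shrank
    converged &= (np.abs(b0) < 1e4) & (np.abs(b1) * np.maximum(np.abs(X).max(axis=1), 1e-300) < 1e4)
    return np.column_stack([b0, b1]), converged


def _logistic_ass_many(X: np.ndarray, y: np.ndarray, ridge_fallback: float = 1e-4):
    """(ass, B) for every row; non-converged rows are ridge-refitted."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(float)
    B, conv = _fit_logistic_many(X, y)
    if (~conv).any():
        Bf, _ = _fit_logistic_many(X[~conv], y, ridge=ridge_fallback)
        B[~conv] = Bf
    eta = B[:, [0]] + B[:, [1]] * X
    pred = eta >= 0.0  # p >= 0.5
    n_case = (y == 1).sum()
    n_ctrl = (y == 0).sum()
    sens = (pred & (y == 1)[None, :]).sum(axis=1) / n_case
    spec = (~pred & (y == 0)[None, :]).sum(axis=1) / n_ctrl
    return (sens + spec) / 2.0, B


def logistic_ass(
    row: Sequence[float], labels: Sequence[int]
) -> tuple[float, tuple[float, float]]:
    """In-sample ASS of the one-covariate logistic predictor for one row.

    Predicts case iff the fitted probability >= 0.5.  Complete separation
    falls back to a ridge-penalized fit (slope penalty 1e-4) so perfectly
    separating rows return ASS = 1 instead of erroring.
    """
    labels = np.asarray(labels).astype(int)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("labels must contain both groups")
    ass, B = _logistic_ass_many(np.asarray(row, dtype=float)[None, :], labels)
    return float(ass[0]), (float(B[0, 0]), float(B[0, 1]))


def select_numerical(
    F: FeatureMatrix,
    labels: Sequence[int] | None = None,
    theta2: float = 0.01,
    theta3: float = 0.8,
    exclude: Iterable[str] | None = None,
) -> list[GroupSpecificFeature]:
    """Wilcoxon filter then logistic-ASS selection on the numerical track.

    Rows named in ``exclude`` (normally the logical selection) are skipped:
    a k-mer appears in at most one track.  Sorted like the logical track.
    """
    labels = F.labels if labels is None else np.asarray(labels).astype(int)
    kmers = F.kmers
    mask = np.ones(F.n_features, dtype=bool)
    if exclude:
        excl = set(exclude)
        mask &= ~np.isin(kmers, list(excl))
    rows = np.flatnonzero(mask)
    cand, pvals = wilcoxon_filter(F, labels, theta2=theta2, rows=rows)
    if cand.size == 0:
        return []
    Xc = F.dense(cand)
    ass, B = _logistic_ass_many(Xc, labels)
    keep = ass >= theta3
    mean_case = Xc[:, labels == 1].mean(axis=1)
    mean_ctrl = Xc[:, labels == 0].mean(axis=1)
    feats = [
        GroupSpecificFeature(
            kmer=str(kmers[cand[i]]),
            track="numerical",
            orientation=CASE_PRESENT if mean_case[i] >= mean_ctrl[i] else CONTROL_PRESENT,
            ass_train=float(ass[i]),
            p_value=float(pvals[i]),
            selected_by="ASS",
            coef=(float(B[i, 0]), float(B[i, 1])),
        )
        for i in np.flatnonzero(keep)
    ]
    feats.sort(key=GroupSpecificFeature.sort_key)
    return feats


def select_features(
    F: FeatureMatrix,
    theta1: float = 0.8,
    theta2: float = 0.01,
    theta3: float = 0.8,
    metric: str = "ass",
    labels: Sequence[int] | None = None,
) -> list[GroupSpecificFeature]:
    """Both tracks combined, logical first within equal ASS."""
    logical = select_logical(F, labels=labels, theta1=theta1, metric=metric)
    numerical = select_numerical(
        F,
        labels=labels,
        theta2=theta2,
        theta3=theta3,
        exclude=[f.kmer for f in logical],
    )
    feats = logical + numerical
    feats.sort(key=GroupSpecificFeature.sort_key)
    return feats


# -- persistence -------------------------------------------------------------

_TSV_HEADER = "kmer\ttrack\torientation\tass\tp_value\tselected_by\tintercept\tslope"


def write_features_tsv(features: Sequence[GroupSpecificFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for f in features:
            p = "" if f.p_value is None else f"{f.p_value:.6g}"
            b0 = "" if f.coef is None else f"{f.coef[0]:.10g}"
            b1 = "" if f.coef is None else f"{f.coef[1]:.10g}"
            fh.write(
                f"{f.kmer}\t{f.track}\t{f.orientation}\t{f.ass_train:.6g}\t{p}\t{f.selected_by}\t{b0}\t{b1}\n"
            )


def read_features_tsv(path) -> list[GroupSpecificFeature]:
    feats = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            kmer, track, orient, ass, p, by = parts[:6]
            coef = None
            if len(parts) >= 8 and parts[6] != "":
                coef = (float(parts[6]), float(parts[7]))
            feats.append(
                GroupSpecificFeature(
                    kmer=kmer,
                    track=track,
                    orientation=orient,
                    ass_train=float(ass),
                    p_value=float(p) if p else None,
                    selected_by=by,
                    coef=coef,
                )
            )
    return feats
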