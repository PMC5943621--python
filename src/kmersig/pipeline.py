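"""End-to-end orchestration: count -> matrix -> select -> classify -> assemble.

A single :class:`Config` holds every threshold exactly once; all stochastic
steps expand one pipeline seed through a counter-based scheme.  The
train/validate/test runner keeps feature preprocessing and selection strictly
on the training sheet — validation and test columns are only ever projected
onto the selected rows afterwards — and emits a JSON-serializable report with
per-stage funnel counters (k-mers in/out at each filter) and full provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .assemble import assemble_kmers, contig_report
from .classify import (
    CVResult,
    cross_validate,
    decorrelate,
    fit_rf,
    predict,
    rank_importance,
    roc_auc,
)
from .io import SampleSheet, iter_reads
from .kmers import KmerVector, count_kmers, import_counts, write_counts
from .matrix import FeatureMatrix, build_matrix, filter_sparse, project_vectors
from .select import CASE_PRESENT, GroupSpecificFeature, select_features

__all__ = ["Config", "count_samples", "select_training_features",
           "run_train_validate_test", "run_cv", "write_report"]

logger = logging.getLogger("kmersig")


@dataclass
class Config:
    """All pipeline thresholds in one place.

    k defaults to 40 (documented validity band 30-40); theta1/theta3 are ASS
    thresholds for the logical and numerical tracks, theta2 the Wilcoxon
    p-value cut, pcc_max the decorrelation bound, top_n the forest width.
    """

    k: int = 40
    min_count: int = 2
    sparsity: float = 0.8
    theta1: float = 0.8
    theta2: float = 0.01
    theta3: float = 0.8
    pcc_max: float = 0.75
    top_n: int = 10
    n_trees: int = 500
    min_contig_len: int = 200
    runs: int = 20
    folds: int = 10
    seed: int = 0
    metric: str = "ass"
    max_decorrelation_candidates: int | None = 5000

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("theta1", "theta3"):
            v = getattr(self, name)
            if not (0.5 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0.5, 1], got {v}")
        if not (0.0 < self.theta2 <= 1.0):
            raise ValueError(f"theta2 must be in (0, 1], got {self.theta2}")
        if not (0.0 < self.sparsity < 1.0):
            raise ValueError(f"sparsity must be in (0, 1), got {self.sparsity}")
        if self.metric not in {"ass", "chi2"}:
            raise ValueError(f"metric must be 'ass' or 'chi2', got {self.metric!r}")

    @classmethod
    def preset(cls, name: str, **overrides) -> "Config":
        """'strict' (theta1=theta3=0.8, theta2=0.01) or 'relaxed'
        (theta1=theta3=0.75, theta2=0.05) for complex-disease settings."""
        if name == "strict":
            base = cls()
        elif name == "relaxed":
            base = cls(theta1=0.75, theta2=0.05, theta3=0.75)
        else:
            raise ValueError(f"unknown preset {name!r}")
        return replace(base, **overrides)

    # -- key=value file -----------------------------------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "Config":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                if val == "None":
                    kwargs[key] = None
                elif key in {"sparsity", "theta1", "theta2", "theta3", "pcc_max"}:
                    kwargs[key] = float(val)
                elif key == "metric":
                    kwargs[key] = val
                else:
                    kwargs[key] = int(val)
        return cls(**kwargs)


def _file_signature(paths: Sequence[str]) -> str:
    h = hashlib.sha256()
    for p in paths:
        st = Path(p).stat()
        h.update(f"{p}:{st.st_size}:{int(st.st_mtime)}".encode())
    return h.hexdigest()[:16]


def count_samples(
    sheet: SampleSheet, k: int, min_count: int = 2, cache_dir=None
) -> list[KmerVector]:
    """Count every sample on the sheet, with an optional content-addressed
    dump cache: a stage rerun with unchanged inputs is a no-op."""
    vectors = []
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for entry in sheet.entries:
        meta = {
            "k": k,
            "min_count": min_count,
            "signature": _file_signature(entry.paths),
        }
        if cache:
            dump = cache / f"{entry.sample_id}.counts.tsv"
            meta_path = cache / f"{entry.sample_id}.counts.json"
            if dump.exists() and meta_path.exists():
                with open(meta_path) as fh:
                    if json.load(fh) == meta:
                        logger.info("count cache hit for %s", entry.sample_id)
                        vectors.append(
                            import_counts(dump, k=k, min_count=min_count,
                                          sample_id=entry.sample_id)
                        )
                        continue
        v = count_kmers(iter_reads(entry.paths), k, min_count, sample_id=entry.sample_id)
        logger.info("counted %s: %d k-mers (total %d)", entry.sample_id, len(v), v.total_count)
        if cache:
            write_counts(v, dump)
            with open(meta_path, "w") as fh:
                json.dump(meta, fh)
        vectors.append(v)
    return vectors


def select_training_features(
    vectors: Sequence[KmerVector], sheet: SampleSheet, cfg: Config
) -> tuple[FeatureMatrix, list[GroupSpecificFeature], dict]:
    """Matrix build + sparsity filter + both selection tracks, training only.

    Returns the filtered matrix, the combined feature list and the stage
    funnel counters."""
    F = build_matrix(vectors, sheet)
    stages = {"kmers_in_matrix": int(F.n_features)}
    Ff = filter_sparse(F, cfg.sparsity)
    stages["kmers_after_sparsity_filter"] = int(Ff.n_features)
    feats = select_features(
        Ff, theta1=cfg.theta1, theta2=cfg.theta2, theta3=cfg.theta3, metric=cfg.metric
    )
    stages["selected_logical"] = sum(1 for f in feats if f.track == "logical")
    stages["selected_numerical"] = sum(1 for f in feats if f.track == "numerical")
    stages["selected_total"] = len(feats)
    logger.info("selection funnel: %s", stages)
    return Ff, feats, stages


def _feature_ass_on(
    feats: Sequence[GroupSpecificFeature], X: np.ndarray, labels: np.ndarray
) -> list[float]:
    """ASS of each trained single-feature predictor on projected samples.

    Orientation (logical) and coefficients (numerical) are frozen from
    training, so the value can fall below 0.5 on a poorly transferring
    feature."""
    out = []
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    for i, f in enumerate(feats):
        x = X[:, i]
        if f.track == "logical":
            pred = (x > 0) if f.orientation == CASE_PRESENT else (x <= 0)
        else:
            b0, b1 = f.coef if f.coef else (0.0, 0.0)
            pred = (b0 + b1 * x) >= 0
        sens = float((pred & (labels == 1)).sum() / n_case)
        spec = float((~pred & (labels == 0)).sum() / n_ctrl)
        out.append((sens + spec) / 2.0)
    return out


def run_train_validate_test(
    cfg: Config,
    train: tuple[SampleSheet, Sequence[KmerVector]],
    validation: tuple[SampleSheet, Sequence[KmerVector]] | None = None,
    test: tuple[SampleSheet, Sequence[KmerVector]] | None = None,
) -> dict:
    """Full supervised run: selection on train only, evaluation everywhere.

    Reports each selected feature's single-feature ASS on every split, the
    top-n random-forest AUC on every split, and the contigs assembled from
    the selected k-mers per track."""
    train_sheet, train_vectors = train
    splits = {"train": (train_sheet, list(train_vectors))}
    if validation is not None:
        splits["validation"] = (validation[0], list(validation[1]))
    if test is not None:
        splits["test"] = (test[0], list(test[1]))
    seen: set[str] = set()
    for name, (sh, _) in splits.items():
        overlap = seen & set(sh.sample_ids)
        if overlap:
            raise ValueError(f"sample(s) {sorted(overlap)[:5]} appear in multiple splits")
        seen |= set(sh.sample_ids)

    F, feats, stages = select_training_features(train_vectors, train_sheet, cfg)
    report: dict = {
        "config": asdict(cfg),
        "version": __version__,
        "stages": stages,
        "splits": {name: len(sh) for name, (sh, _) in splits.items()},
    }
    if not feats:
        report["status"] = "no-features-selected"
        report["features"] = []
        return report
    report["status"] = "ok"

    names = [f.kmer for f in feats]
    rows = F.index_of(names)
    ass_per_split: dict[str, list[float]] = {}
    proj: dict[str, np.ndarray] = {}
    for name, (sh, vecs) in splits.items():
        X = project_vectors(vecs, F.keys[rows], F.k)
        proj[name] = X
        ass_per_split[name] = _feature_ass_on(feats, X, sh.labels)
    report["features"] = [
        {
            "kmer": f.kmer,
            "track": f.track,
            "orientation": f.orientation,
            "ass": {split: ass_per_split[split][i] for split in splits},
            "p_value": f.p_value,
        }
        for i, f in enumerate(feats)
    ]

    kept = decorrelate(
        feats, F, pcc_max=cfg.pcc_max, seed=cfg.seed,
        max_candidates=cfg.max_decorrelation_candidates,
    )
    stages["after_decorrelation"] = len(kept)
    rows_kept = F.index_of([f.kmer for f in kept])
    ranked = rank_importance(
        F.dense(rows_kept).T, train_sheet.labels, kept,
        n_trees=cfg.n_trees, seed=cfg.seed,
    )
    top = ranked[: cfg.top_n]
    report["top_features"] = [f.kmer for f in top]
    rows_top = F.index_of([f.kmer for f in top])
    model = fit_rf(
        F.dense(rows_top).T, train_sheet.labels, top,
        n_trees=cfg.n_trees, seed=cfg.seed,
    )
    auc = {}
    for name, (sh, vecs) in splits.items():
        Xs = project_vectors(vecs, F.keys[rows_top], F.k)
        _, auc[name] = roc_auc(predict(model, Xs), sh.labels)
    report["rf_auc"] = auc

    contigs = {}
    for track in ("logical", "numerical"):
        kms = [f.kmer for f in feats if f.track == track]
        if not kms:
            continue
        asm = assemble_kmers(kms, min_len=cfg.min_contig_len, track=track)
        contigs[track] = contig_report(asm, kms)
        contigs[track]["sequences"] = [c.sequence for c in asm]
    report["contigs"] = contigs
    return report


def run_cv(cfg: Config, sheet: SampleSheet, vectors: Sequence[KmerVector]) -> CVResult:
    """Repeated stratified CV with per-fold selection (no leakage)."""
    return cross_validate(vectors, sheet, config=cfg)


def write_report(report: dict, path) -> None:
    """Deterministic JSON (sorted keys) so equal runs are byte-identical."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
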