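"""Score selected k-mers and contigs against simulated ground truth.

A selected k-mer "matches" a truth category when it (or its reverse
complement) occurs as an exact substring fully inside one of the category's
regions (strict containment by default; "overlap" counts any intersection).
Precision is the matched fraction of the selection; recall is the fraction
of category-region positions covered by at least one occurrence of any
selected k-mer.  For the logical track, strain-level precision uses the
whole case-only genome as the region (a selected k-mer straddling the
boundary of a replaced block still lies on the case-specific strain), while
recall is measured on the case-specific regions proper.

Contig "coverage" is exact-substring pseudo-alignment of reads: per-position
read depth divided by (n_reads / 1e6), with log(coverage + 1) as the
heat-map value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assemble import Contig
from .io import CASE, SampleSheet
from .kmers import canonical, encode_kmers, reverse_complement, _canonical_codes_1d, _BASE_LUT
from .simulate import CommunityTruth

__all__ = [
    "GenomeIndex",
    "EvalReport",
    "kmer_precision_recall",
    "evaluate_selection",
    "contig_coverage",
    "heatmap_export",
]


class GenomeIndex:
    """Canonical k-mer occurrence index over the truth genomes."""

    def __init__(self, truth: CommunityTruth, k: int):
        self.truth = truth
        self.k = k
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for g in truth.genomes:
            b = _BASE_LUT[np.frombuffer(g.sequence.upper().encode(), dtype=np.uint8)]
            # position-indexed canonical codes (no invalid bases in simulation)
            W = len(g.sequence) - k + 1
            codes = np.empty(W, dtype=np.uint64)
            full = _canonical_codes_1d(b, k)
            if full.size != W:
                raise ValueError(f"genome {g.name} contains non-ACGT characters")
            codes[:] = full
            self._codes[g.name] = codes
            self._order[g.name] = np.argsort(codes, kind="stable")

    def occurrences(self, kmer_codes: np.ndarray, genome: str):
        """(positions, kmer_index) of every occurrence in one genome."""
        codes = self._codes[genome]
        order = self._order[genome]
        sorted_codes = codes[order]
        left = np.searchsorted(sorted_codes, kmer_codes, side="left")
        right = np.searchsorted(sorted_codes, kmer_codes, side="right")
        n_occ = right - left
        if n_occ.sum() == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        kmer_idx = np.repeat(np.arange(kmer_codes.size), n_occ)
        flat = np.concatenate(
            [order[l:r] for l, r in zip(left, right) if r > l]
        )
        return flat, kmer_idx


def _encode_selection(kmers: Sequence[str], k: int) -> np.ndarray:
    return encode_kmers([canonical(km) for km in kmers], k)


def kmer_precision_recall(
    kmers: Sequence[str],
    truth: CommunityTruth,
    category: str,
    containment: str = "strict",
    index: GenomeIndex | None = None,
) -> tuple[float | None, float]:
    """Precision and recall of a k-mer selection against one truth category.

    precision = matched selected k-mers / total selected (None if empty
    selection); recall = fraction of category-region positions covered by at
    least one occurrence of any selected k-mer.
    """
    if category not in truth.regions:
        raise KeyError(f"unknown truth category {category!r}")
    regions = truth.regions[category]
    kmers = list(kmers)
    if not kmers:
        return None, 0.0
    k = len(kmers[0])
    if index is None:
        index = GenomeIndex(truth, k)
    codes = _encode_selection(kmers, k)

    by_genome: dict[str, list[tuple[int, int]]] = {}
    for g, s, e in regions:
        by_genome.setdefault(g, []).append((s, e))

    matched = np.zeros(len(kmers), dtype=bool)
    covered = 0
    total = 0
    for g, ivs in by_genome.items():
        ivs = sorted(ivs)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        total += int((ends - starts).sum())
        pos, kidx = index.occurrences(codes, g)
        if pos.size:
            if containment == "strict":
                j = np.searchsorted(starts, pos, side="right") - 1
                jc = np.clip(j, 0, len(ivs) - 1)
                inside = (j >= 0) & (pos + k <= ends[jc])
            elif containment == "overlap":
                j = np.searchsorted(ends, pos, side="right")
                jc = np.clip(j, 0, len(ivs) - 1)
                inside = (j < len(ivs)) & (starts[jc] < pos + k)
            else:
                raise ValueError("containment must be 'strict' or 'overlap'")
            np.logical_or.at(matched, kidx[inside], True)
            # positional coverage: any overlap of an occurrence covers bases
            cover = np.zeros(index._codes[g].size + k, dtype=np.int64)
            np.add.at(cover, pos, 1)
            np.add.at(cover, pos + k, -1)
            depth = np.cumsum(cover)
            for s, e in ivs:
                covered += int((depth[s:e] > 0).sum())
    precision = float(matched.mean())
    recall = covered / total if total else 0.0
    return precision, recall


@dataclass
class EvalReport:
    """Per-category precision/recall for each selection track."""

    per_category: dict = field(default_factory=dict)  # (track, category) -> metrics
    counts: dict = field(default_factory=dict)
    unmatched: dict = field(default_factory=dict)

    def metric(self, track: str, category: str, which: str):
        return self.per_category[(track, category)][which]

    def to_dict(self) -> dict:
        return {
            "per_category": {
                f"{t}/{c}": m for (t, c), m in sorted(self.per_category.items())
            },
            "counts": dict(self.counts),
            "unmatched": dict(self.unmatched),
        }


def evaluate_selection(
    features,
    truth: CommunityTruth,
    k: int | None = None,
) -> EvalReport:
    """Score the logical and numerical tracks against every truth category.

    ``features`` is the list of GroupSpecificFeature from selection (or a
    mapping track -> k-mer list).  Adds a derived "differential-regions"
    category (differential genome plus common regions) matching the
    two-group differential-abundance target of the numerical track.
    """
    if isinstance(features, dict):
        tracks = {t: list(kms) for t, kms in features.items()}
    else:
        tracks = {}
        for f in features:
            tracks.setdefault(f.track, []).append(f.kmer)
    if k is None:
        for kms in tracks.values():
            if kms:
                k = len(kms[0])
                break
    if k is None:
        raise ValueError("empty selection: cannot infer k")
    index = GenomeIndex(truth, k)

    # derived category: all differentially abundant regions between groups
    truth_regions = dict(truth.regions)
    if "differential" in truth_regions and "common" in truth_regions:
        truth_regions["differential-regions"] = (
            truth.regions["differential"] + truth.regions["common"]
        )
    aug = CommunityTruth(
        genomes=truth.genomes,
        shared_fraction=truth.shared_fraction,
        fold_change=truth.fold_change,
        profiles=truth.profiles,
        regions=truth_regions,
        seed=truth.seed,
    )

    report = EvalReport()
    for track, kms in sorted(tracks.items()):
        report.counts[track] = len(kms)
        if not kms:
            continue
        codes = _encode_selection(kms, k)
        hit_any = np.zeros(len(kms), dtype=bool)
        for g in truth.genome_names:
            _, kidx = index.occurrences(codes, g)
            hit_any[np.unique(kidx)] = True
        report.unmatched[track] = int((~hit_any).sum())
        for category in sorted(truth_regions):
            precision, recall = kmer_precision_recall(
                kms, aug, category, index=index
            )
            report.per_category[(track, category)] = {
                "precision": precision,
                "recall": recall,
            }
    return report


def contig_coverage(
    contigs: Sequence[Contig], readset, normalize: bool = True
) -> dict[str, np.ndarray]:
    """Per-position pseudo-alignment depth of one sample over each contig.

    Every read fully contained (forward or reverse complement) in a contig
    adds 1 to the positions it spans; depth is divided by n_reads / 1e6.
    """
    reads = readset.reads if hasattr(readset, "reads") else list(readset)
    n_reads = len(reads)
    out: dict[str, np.ndarray] = {}
    for c in contigs:
        delta = np.zeros(c.length + 1, dtype=np.int64)
        seq = c.sequence
        for r in reads:
            for probe in (r, reverse_complement(r)):
                start = 0
                while True:
                    i = seq.find(probe, start)
                    if i < 0:
                        break
                    delta[i] += 1
                    delta[i + len(probe)] -= 1
                    start = i + 1
                if probe == reverse_complement(probe):
                    break  # palindromic read: avoid double counting
        depth = np.cumsum(delta[:-1]).astype(float)
        if normalize:
            depth /= max(n_reads, 1) / 1e6
        out[c.id] = depth
    return out


def heatmap_export(
    coverages: dict[str, dict[str, np.ndarray]],
    sheet: SampleSheet,
    tsv_path,
    png_path=None,
) -> pd.DataFrame:
    """Sample x concatenated-contig-position matrix of log(coverage + 1).

    Rows are controls first, then cases (matching the healthy-on-top layout
    of the coverage heat maps this reproduces); always writes TSV, and a PNG
    when matplotlib is available and a path is given.
    """
    ordered = [e.sample_id for e in sheet.entries if e.group != CASE] + [
        e.sample_id for e in sheet.entries if e.group == CASE
    ]
    contig_ids = sorted({cid for cov in coverages.values() for cid in cov})
    columns = []
    for cid in contig_ids:
        L = len(next(iter(coverages.values()))[cid])
        columns.extend(f"{cid}:{i}" for i in range(L))
    rows = []
    for sid in ordered:
        cov = coverages[sid]
        rows.append(np.concatenate([np.log1p(cov[cid]) for cid in contig_ids]))
    df = pd.DataFrame(rows, index=ordered, columns=columns)
    df.to_csv(tsv_path, sep="\t", index_label="sample_id")
    if png_path is not None:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:
            return df
        fig, ax = plt.subplots(figsize=(10, 4))
        ax.imshow(df.values, aspect="auto", cmap="viridis", interpolation="nearest")
        ax.set_xlabel("contig position")
        ax.set_ylabel("samples (controls on top)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return df
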