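"""Normalized k-mer feature matrices across training samples.

Per-sample counts become within-sample relative frequencies (each column sums
to 1), columns are merged over the union of observed canonical k-mers (rows
sorted lexicographically), and highly sparse rows — k-mers absent from more
than ``sparsity`` of the control samples AND of the case samples — are
removed.  Column normalization is not recomputed after row filtering.

Row keys are stored as uint64 2-bit codes for k <= 32 (code order equals
lexicographic order) or as a sorted string array otherwise.
"""

from __future__ import annotations

import json
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .io import SampleSheet
from .kmers import KmerVector, decode_codes, encode_kmers, sorted_unique

__all__ = ["FeatureMatrix", "normalize", "build_matrix", "filter_sparse", "project_vectors"]


def normalize(vector: KmerVector) -> dict[str, float]:
    """Within-sample relative frequency of every stored k-mer (sums to 1)."""
    total = vector.total_count
    if total <= 0:
        raise ValueError(f"sample {vector.sample_id!r}: empty k-mer vector")
    return {km: c / total for km, c in vector.counts.items()}


def _vector_arrays(v: KmerVector) -> tuple[np.ndarray, np.ndarray]:
    """(sorted keys, frequencies) with keys as codes (k<=32) or '<U' strings."""
    total = v.total_count
    if total <= 0:
        raise ValueError(f"sample {v.sample_id!r}: empty k-mer vector")
    if v.k <= 32:
        codes, counts = v.arrays()
        return codes, counts / total
    keys = np.array(sorted(v.counts), dtype=f"<U{v.k}")
    freqs = np.array([v.counts[km] for km in keys], dtype=float) / total
    return keys, freqs


class FeatureMatrix:
    """Sparse m x N matrix of normalized k-mer frequencies with group labels."""

    def __init__(
        self,
        keys: np.ndarray,
        k: int,
        X: sp.csr_matrix,
        sheet: SampleSheet,
        provenance: dict | None = None,
    ):
        self._keys = keys  # sorted; uint64 codes or '<U{k}' strings
        self.k = int(k)
        self.X = X.tocsr()
        self.sheet = sheet
        self.provenance = dict(provenance or {})
        if self.X.shape != (len(keys), len(sheet)):
            raise ValueError("matrix shape does not match keys x samples")

    # -- views --------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def kmers(self) -> np.ndarray:
        """Row k-mers as unicode strings, in stored (lexicographic) order."""
        if self._keys.dtype == np.uint64:
            return decode_codes(self._keys, self.k)
        return self._keys

    @property
    def keys(self) -> np.ndarray:
        return self._keys

    @property
    def labels(self) -> np.ndarray:
        return self.sheet.labels

    def row(self, i: int) -> np.ndarray:
        return np.asarray(self.X[i].todense()).ravel()

    def dense(self, rows: Sequence[int] | None = None) -> np.ndarray:
        if rows is None:
            return np.asarray(self.X.todense())
        return np.asarray(self.X[np.asarray(rows, dtype=int)].todense())

    def presence(self) -> sp.csr_matrix:
        """Boolean sparse indicator of f > 0 (the logicalized matrix)."""
        B = self.X.copy()
        B.data = np.ones_like(B.data)
        return B

    def index_of(self, kmers: Sequence[str]) -> np.ndarray:
        """Row indices of the given k-mers; KeyError if any is absent."""
        if self._keys.dtype == np.uint64:
            want = encode_kmers(list(kmers), self.k)
        else:
            want = np.asarray(list(kmers), dtype=self._keys.dtype)
        pos = np.searchsorted(self._keys, want)
        pos_clip = np.clip(pos, 0, len(self._keys) - 1)
        bad = (pos >= len(self._keys)) | (self._keys[pos_clip] != want)
        if bad.any():
            missing = [list(kmers)[i] for i in np.flatnonzero(bad)[:5]]
            raise KeyError(f"k-mers not in matrix rows: {missing}")
        return pos

    def take_rows(self, rows: Sequence[int], note: str | None = None) -> "FeatureMatrix":
        rows = np.asarray(rows, dtype=int)
        prov = dict(self.provenance)
        if note:
            prov.setdefault("filters", []).append(note)
        return FeatureMatrix(self._keys[rows], self.k, self.X[rows], self.sheet, prov)

    # -- persistence --------------------------------------------------------

    def to_tsv(self, path, sidecar_path=None) -> None:
        """Triplets ``kmer<TAB>sample_id<TAB>frequency`` + JSON sidecar."""
        kmers = self.kmers
        ids = self.sheet.sample_ids
        coo = self.X.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w") as fh:
            for i in order:
                fh.write(f"{kmers[coo.row[i]]}\t{ids[coo.col[i]]}\t{coo.data[i]:.12g}\n")
        if sidecar_path is None:
            sidecar_path = str(path) + ".json"
        sidecar = {
            "k": self.k,
            "samples": ids,
            "groups": [e.group for e in self.sheet.entries],
            "provenance": self.provenance,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, sidecar_path=None) -> "FeatureMatrix":
        from .io import SampleEntry

        if sidecar_path is None:
            sidecar_path = str(path) + ".json"
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        k = int(sidecar["k"])
        ids = sidecar["samples"]
        col_of = {s: j for j, s in enumerate(ids)}
        sheet = SampleSheet(
            [SampleEntry(s, g) for s, g in zip(ids, sidecar["groups"])]
        )
        kmers, cols, vals = [], [], []
        with open(path) as fh:
            for line in fh:
                km, sid, v = line.rstrip("\n").split("\t")
                kmers.append(km)
                cols.append(col_of[sid])
                vals.append(float(v))
        uniq = np.unique(np.asarray(kmers, dtype=f"<U{k}"))
        rows = np.searchsorted(uniq, np.asarray(kmers, dtype=f"<U{k}"))
        X = sp.coo_matrix(
            (vals, (rows, cols)), shape=(len(uniq), len(ids))
        ).tocsr()
        keys = encode_kmers(uniq.tolist(), k) if k <= 32 else uniq
        return cls(keys, k, X, sheet, sidecar.get("provenance"))


def build_matrix(vectors: Sequence[KmerVector], sheet: SampleSheet) -> FeatureMatrix:
    """Merge normalized per-sample vectors into the training feature matrix.

    Rows are the union of observed canonical k-mers (sorted); a k-mer absent
    from a sample is exactly 0 there.  Vectors align 1:1 with sheet entries.
    """
    if len(vectors) != len(sheet):
        raise ValueError(
            f"{len(vectors)} vectors vs {len(sheet)} sheet entries"
        )
    ks = {v.k for v in vectors}
    if len(ks) != 1:
        raise ValueError(f"vectors have mixed k: {sorted(ks)}")
    k = ks.pop()
    per_sample = [_vector_arrays(v) for v in vectors]
    all_keys = sorted_unique(np.concatenate([keys for keys, _ in per_sample]))
    rows_parts, cols_parts, data_parts = [], [], []
    for j, (keys, freqs) in enumerate(per_sample):
        rows_parts.append(np.searchsorted(all_keys, keys))
        cols_parts.append(np.full(keys.size, j, dtype=np.int64))
        data_parts.append(freqs)
    X = sp.coo_matrix(
        (
            np.concatenate(data_parts),
            (np.concatenate(rows_parts), np.concatenate(cols_parts)),
        ),
        shape=(all_keys.size, len(sheet)),
    ).tocsr()
    return FeatureMatrix(all_keys, k, X, sheet, {"built_from": len(vectors)})


def filter_sparse(F: FeatureMatrix, sparsity: float = 0.8) -> FeatureMatrix:
    """Drop rows absent in more than ``sparsity`` of controls AND of cases.

    The comparison ``zeros > sparsity * n_group`` is evaluated in rational
    arithmetic (Fraction of the decimal literal) so exact ties like
    0.8 * 10 = 8 are never lost to floating rounding.
    """
    if not (0 < sparsity < 1):
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    frac = Fraction(str(sparsity))
    labels = F.labels
    B = F.presence()
    pres_case = np.asarray(B[:, labels == 1].sum(axis=1)).ravel().astype(int)
    pres_ctrl = np.asarray(B[:, labels == 0].sum(axis=1)).ravel().astype(int)
    n_case = int((labels == 1).sum())
    n_ctrl = int((labels == 0).sum())
    zeros_case = n_case - pres_case
    zeros_ctrl = n_ctrl - pres_ctrl
    # zeros * den > num * n  <=>  zeros > sparsity * n
    drop = (zeros_case * frac.denominator > frac.numerator * n_case) & (
        zeros_ctrl * frac.denominator > frac.numerator * n_ctrl
    )
    keep = np.flatnonzero(~drop)
    out = F.take_rows(keep, note=f"sparsity<{sparsity}")
    out.provenance["sparsity"] = sparsity
    out.provenance["rows_before"] = int(F.n_features)
    out.provenance["rows_after"] = int(keep.size)
    return out


def project_vectors(
    vectors: Sequence[KmerVector],
    keys: np.ndarray,
    k: int,
) -> np.ndarray:
    """Dense (n_samples x m) frequency matrix of new samples on fixed rows.

    A k-mer absent from a sample is 0 — this is the explicit projection mode
    used for validation/test samples (rows were chosen on training data only).
    """
    out = np.zeros((len(vectors), len(keys)), dtype=float)
    if len(keys) == 0:
        return out
    order = np.argsort(keys, kind="stable")  # keys may be in feature order
    skeys = keys[order]
    for j, v in enumerate(vectors):
        if v.k != k:
            raise ValueError(f"vector k={v.k} != matrix k={k}")
        vkeys, vfreqs = _vector_arrays(v)
        pos = np.searchsorted(skeys, vkeys)
        pos_clip = np.clip(pos, 0, len(skeys) - 1)
        ok = (pos < len(skeys)) & (skeys[pos_clip] == vkeys)
        out[j, order[pos_clip[ok]]] = vfreqs[ok]
    return out
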