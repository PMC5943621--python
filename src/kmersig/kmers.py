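"""Canonical k-mer counting for shotgun metagenomic samples.

A k-mer and its reverse complement are treated as one object: every k-mer is
stored under its *canonical* form, the lexicographically smaller of the two
orientations.  Counting streams reads, skips any window containing a non-ACGT
base, and discards k-mers seen fewer than ``min_count`` times (singletons by
default) — low-count long k-mers are dominated by sequencing errors and make
presence/absence features unstable.

For k <= 32 counting runs on a 2-bit rolling encoder (numpy, one uint64 per
window); longer k falls back to a plain dictionary over strings.  Both paths
produce identical results.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "KmerVector",
    "reverse_complement",
    "canonical",
    "count_kmers",
    "theoretical_dim",
    "import_counts",
    "write_counts",
    "encode_kmers",
    "decode_codes",
    "InvalidAlphabetError",
    "EmptyInputError",
]


class InvalidAlphabetError(ValueError):
    """A sequence contained a character outside {A, C, G, T}."""


class EmptyInputError(ValueError):
    """An operation that requires sequence data received none."""


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")
_ACGT = frozenset("ACGT")

# byte -> 2-bit base code; 4 flags an invalid character
_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BASE_LUT[ord(_c)] = _i
    _BASE_LUT[ord(_c.lower())] = _i
_CHAR_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

_U2 = np.uint64(2)
_U3 = np.uint64(3)


def reverse_complement(seq: str) -> str:
    """Base-wise complement in reversed order (an involution)."""
    s = seq.upper()
    if not _ACGT.issuperset(s):
        bad = sorted(set(s) - _ACGT)
        raise InvalidAlphabetError(f"non-ACGT character(s) {bad} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    s = kmer.upper()
    return s if s <= rc else rc


def theoretical_dim(k: int) -> int:
    """Number of canonical k-mer classes over {A,C,G,T}.

    Even k admits 4^(k/2) reverse-complement palindromes (classes of size 1);
    odd k admits none, so every class has size 2.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


def encode_kmers(kmers: Sequence[str], k: int | None = None) -> np.ndarray:
    """Encode same-length ACGT strings to 2-bit uint64 codes (k <= 32)."""
    kmers = list(kmers)
    if not kmers:
        return np.empty(0, dtype=np.uint64)
    if k is None:
        k = len(kmers[0])
    if k > 32:
        raise ValueError("2-bit codes only support k <= 32")
    joined = "".join(kmers)
    if len(joined) != k * len(kmers):
        raise ValueError("k-mers have inconsistent lengths")
    b = _BASE_LUT[np.frombuffer(joined.upper().encode(), dtype=np.uint8)]
    if (b > 3).any():
        raise InvalidAlphabetError("non-ACGT character in k-mer")
    mat = b.reshape(len(kmers), k).astype(np.uint64)
    codes = np.zeros(len(kmers), dtype=np.uint64)
    for t in range(k):
        codes = (codes << _U2) | mat[:, t]
    return codes


def decode_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Decode uint64 codes back to unicode k-mer strings."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    for t in range(k):
        shift = np.uint64(2 * (k - 1 - t))
        out[:, t] = _CHAR_LUT[((codes >> shift) & _U3).astype(np.intp)]
    return out.reshape(codes.size, k).view(f"S{k}").ravel().astype(str)


def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of 2-bit codes."""
    codes = np.asarray(codes, dtype=np.uint64)
    rc = np.zeros_like(codes)
    for t in range(k):
        base = (codes >> np.uint64(2 * (k - 1 - t))) & _U3
        rc |= (base ^ _U3) << np.uint64(2 * t)
    return rc


def _canonical_codes_1d(b: np.ndarray, k: int) -> np.ndarray:
    """Canonical window codes of one encoded sequence (Horner over k)."""
    L = b.size
    W = L - k + 1
    if W <= 0:
        return np.empty(0, dtype=np.uint64)
    bb = (b & 3).astype(np.uint64)
    code = np.zeros(W, dtype=np.uint64)
    rc = np.zeros(W, dtype=np.uint64)
    for t in range(k):
        code = (code << _U2) | bb[t : t + W]
        rc |= (bb[t : t + W] ^ _U3) << np.uint64(2 * t)
    can = np.minimum(code, rc)
    bad = b > 3
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        n_bad = cs[k:] - cs[:W]
        can = can[n_bad == 0]
    return can


def _canonical_codes_2d(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical window codes for a batch of equal-length encoded reads.

    Rolls one column at a time so cost is O(n_reads * read_len) rather than
    O(n_reads * read_len * k).
    """
    n, L = mat.shape
    W = L - k + 1
    if W <= 0 or n == 0:
        return np.empty(0, dtype=np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1) if k < 32 else np.uint64(0xFFFFFFFFFFFFFFFF)
    shift = np.uint64(2 * (k - 1))
    code = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    run = np.zeros(n, dtype=np.int64)
    chunks: list[np.ndarray] = []
    for j in range(L):
        b = mat[:, j]
        bb = (b & 3).astype(np.uint64)
        code = ((code << _U2) | bb) & mask
        rc = (rc >> _U2) | ((bb ^ _U3) << shift)
        run = np.where(b > 3, 0, run + 1)
        if j >= k - 1:
            can = np.minimum(code, rc)
            valid = run >= k
            chunks.append(can.copy() if valid.all() else can[valid])
    return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)


def sorted_unique_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort-based unique with counts (fast path for large code arrays)."""
    if arr.size == 0:
        return arr.copy(), np.empty(0, dtype=np.int64)
    s = np.sort(arr)
    starts = np.flatnonzero(np.concatenate(([True], s[1:] != s[:-1])))
    counts = np.diff(np.concatenate((starts, [s.size]))).astype(np.int64)
    return s[starts], counts


def sorted_unique(arr: np.ndarray) -> np.ndarray:
    if arr.size == 0:
        return arr.copy()
    s = np.sort(arr)
    return s[np.concatenate(([True], s[1:] != s[:-1]))]


def _as_sequence(read) -> str:
    if isinstance(read, str):
        return read
    if isinstance(read, (bytes, bytearray)):
        return read.decode()
    seq = getattr(read, "seq", None)  # Bio.SeqRecord
    if seq is not None:
        return str(seq)
    raise TypeError(f"cannot interpret read of type {type(read)!r} as a sequence")


try:  # JIT rolling encoder; the numpy batch path below is the fallback
    import numba as _numba

    @_numba.njit(cache=True)
    def _roll_kernel(bases, bounds, k, out):  # pragma: no cover - compiled
        mask = np.uint64(0xFFFFFFFFFFFFFFFF)
        if k < 32:
            mask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
        shift = np.uint64(2 * (k - 1))
        two = np.uint64(2)
        three = np.uint64(3)
        n = 0
        for r in range(bounds.size - 1):
            code = np.uint64(0)
            rc = np.uint64(0)
            run = 0
            for i in range(bounds[r], bounds[r + 1]):
                b = bases[i]
                if b > 3:
                    run = 0
                    continue
                bb = np.uint64(b)
                code = ((code << two) | bb) & mask
                rc = (rc >> two) | ((bb ^ three) << shift)
                run += 1
                if run >= k:
                    if code < rc:
                        out[n] = code
                    else:
                        out[n] = rc
                    n += 1
        return n

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class KmerVector:
    """One sample's canonical k-mer -> count map.

    Counts are stored internally as parallel (code, count) arrays sorted by
    code for k <= 32 (code order equals lexicographic order); the ``counts``
    dict is materialized lazily.  Invariants: all keys canonical of length k,
    all counts >= the ``min_count`` the vector was built with, and
    ``total_count`` equals the sum of stored counts.
    """

    def __init__(
        self,
        sample_id: str,
        k: int,
        codes: np.ndarray | None = None,
        code_counts: np.ndarray | None = None,
        counts: Mapping[str, int] | None = None,
    ):
        self.sample_id = sample_id
        self.k = int(k)
        if codes is not None:
            self._codes = np.asarray(codes, dtype=np.uint64)
            self._code_counts = np.asarray(code_counts, dtype=np.int64)
            self._dict: dict[str, int] | None = None
        else:
            self._codes = None
            self._code_counts = None
            self._dict = dict(counts or {})

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_counts(
        cls, sample_id: str, k: int, counts: Mapping[str, int], validate: bool = True
    ) -> "KmerVector":
        if validate:
            for km, c in counts.items():
                if len(km) != k:
                    raise ValueError(f"k-mer {km!r} does not have length {k}")
                if canonical(km) != km:
                    raise ValueError(f"k-mer {km!r} is not canonical")
                if c < 1:
                    raise ValueError(f"count for {km!r} must be positive")
        if k <= 32 and counts:
            keys = sorted(counts)
            codes = encode_kmers(keys, k)
            cc = np.array([counts[km] for km in keys], dtype=np.int64)
            return cls(sample_id, k, codes=codes, code_counts=cc)
        return cls(sample_id, k, counts=counts)

    # -- views --------------------------------------------------------------

    @property
    def counts(self) -> dict[str, int]:
        if self._dict is None:
            keys = decode_codes(self._codes, self.k)
            self._dict = dict(zip(keys.tolist(), self._code_counts.tolist()))
        return self._dict

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted uint64 codes, int64 counts); encodes on demand for k <= 32."""
        if self._codes is None:
            if self.k > 32:
                raise ValueError("array view unavailable for k > 32")
            keys = sorted(self._dict)
            self._codes = encode_kmers(keys, self.k)
            self._code_counts = np.array(
                [self._dict[km] for km in keys], dtype=np.int64
            )
        return self._codes, self._code_counts

    @property
    def total_count(self) -> int:
        if self._codes is not None:
            return int(self._code_counts.sum())
        return sum(self._dict.values())

    def __len__(self) -> int:
        return self._codes.size if self._codes is not None else len(self._dict)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def __getitem__(self, kmer: str) -> int:
        return self.counts[kmer]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"KmerVector(sample_id={self.sample_id!r}, k={self.k}, "
            f"n_kmers={len(self)}, total_count={self.total_count})"
        )


def count_kmers(
    reads: Iterable, k: int, min_count: int = 2, sample_id: str = "sample"
) -> KmerVector:
    """Count canonical k-mers across a stream of reads.

    Windows containing any non-ACGT base are skipped (not substituted), reads
    shorter than k contribute nothing, and k-mers with fewer than ``min_count``
    occurrences are dropped after counting.  Raises :class:`EmptyInputError`
    on an empty stream; warns and returns an empty vector if every read is
    shorter than k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if k > 32:
        return _count_kmers_py(reads, k, min_count, sample_id)

    chunks: list[np.ndarray] = []
    n_reads = 0
    usable = 0

    if _HAVE_NUMBA:
        pending: list[str] = []
        pending_bases = 0

        def flush() -> None:
            nonlocal pending_bases
            if not pending:
                return
            raw = _BASE_LUT[
                np.frombuffer("".join(pending).upper().encode(), dtype=np.uint8)
            ]
            bounds = np.zeros(len(pending) + 1, dtype=np.int64)
            np.cumsum([len(s) for s in pending], out=bounds[1:])
            out = np.empty(raw.size, dtype=np.uint64)
            n = _roll_kernel(raw, bounds, k, out)
            if n:
                chunks.append(out[:n].copy())
            pending.clear()
            pending_bases = 0

        for read in reads:
            seq = _as_sequence(read)
            n_reads += 1
            if len(seq) < k:
                continue
            usable += 1
            pending.append(seq)
            pending_bases += len(seq)
            if pending_bases >= 8_000_000:
                flush()
        flush()
    else:
        buckets: dict[int, list[str]] = {}

        def flush_bucket(length: int) -> None:
            batch = buckets.pop(length, None)
            if not batch:
                return
            raw = np.frombuffer("".join(batch).upper().encode(), dtype=np.uint8)
            mat = _BASE_LUT[raw].reshape(len(batch), length)
            codes = _canonical_codes_2d(mat, k)
            if codes.size:
                chunks.append(codes)

        for read in reads:
            seq = _as_sequence(read)
            n_reads += 1
            L = len(seq)
            if L < k:
                continue
            usable += 1
            if L > 4096:
                b = _BASE_LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
                codes = _canonical_codes_1d(b, k)
                if codes.size:
                    chunks.append(codes)
            else:
                buckets.setdefault(L, []).append(seq)
                if len(buckets[L]) >= 8192:
                    flush_bucket(L)
        for L in list(buckets):
            flush_bucket(L)

    if n_reads == 0:
        raise EmptyInputError("no reads supplied to count_kmers")
    if usable == 0:
        warnings.warn(
            f"k={k} exceeds the length of every read; returning an empty vector",
            stacklevel=2,
        )
        return KmerVector(
            sample_id, k, codes=np.empty(0, np.uint64), code_counts=np.empty(0, np.int64)
        )
    if not chunks:
        return KmerVector(
            sample_id, k, codes=np.empty(0, np.uint64), code_counts=np.empty(0, np.int64)
        )
    allcodes = np.concatenate(chunks)
    uniq, cnt = sorted_unique_counts(allcodes)
    keep = cnt >= min_count
    return KmerVector(
        sample_id, k, codes=uniq[keep], code_counts=cnt[keep].astype(np.int64)
    )


def _count_kmers_py(reads, k: int, min_count: int, sample_id: str) -> KmerVector:
    # dictionary fallback for k > 32 (strings stay exact at any length)
    counts: dict[str, int] = {}
    n_reads = 0
    usable = 0
    for read in reads:
        seq = _as_sequence(read).upper()
        n_reads += 1
        if len(seq) < k:
            continue
        usable += 1
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if not _ACGT.issuperset(window):
                continue
            c = canonical(window)
            counts[c] = counts.get(c, 0) + 1
    if n_reads == 0:
        raise EmptyInputError("no reads supplied to count_kmers")
    if usable == 0:
        warnings.warn(
            f"k={k} exceeds the length of every read; returning an empty vector",
            stacklevel=3,
        )
    counts = {km: c for km, c in counts.items() if c >= min_count}
    return KmerVector(sample_id, k, counts=counts)


# -- count-dump interchange (DSK/Jellyfish text dialect) ---------------------


def write_counts(vector: KmerVector, path) -> None:
    """Write ``<canonical-kmer>\\t<count>`` lines sorted lexicographically."""
    with open(path, "w") as fh:
        if vector.k <= 32 and len(vector):
            codes, cc = vector.arrays()
            keys = decode_codes(codes, vector.k)
            for km, c in zip(keys, cc):
                fh.write(f"{km}\t{c}\n")
        else:
            for km in sorted(vector.counts):
                fh.write(f"{km}\t{vector.counts[km]}\n")


def import_counts(
    path, k: int | None = None, min_count: int = 2, sample_id: str | None = None
) -> KmerVector:
    """Read a ``kmer<TAB-or-space>count`` dump, canonicalizing and merging.

    Counts of a k-mer and its reverse complement are summed if both appear;
    ``min_count`` is applied after merging.  Malformed lines raise with the
    line number; mixed k-mer lengths are an error.
    """
    counts: dict[str, int] = {}
    seen_k: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'kmer count', got {line!r}")
            km, cnt_s = parts
            try:
                cnt = int(cnt_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: count {cnt_s!r} is not an integer")
            if cnt < 0:
                raise ValueError(f"{path}:{lineno}: negative count {cnt}")
            if seen_k is None:
                seen_k = len(km)
                if k is not None and seen_k != k:
                    raise ValueError(
                        f"{path}:{lineno}: k-mer length {seen_k} != expected k={k}"
                    )
            elif len(km) != seen_k:
                raise ValueError(
                    f"{path}:{lineno}: mixed k-mer lengths ({len(km)} vs {seen_k})"
                )
            try:
                c = canonical(km)
            except InvalidAlphabetError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}")
            counts[c] = counts.get(c, 0) + cnt
    if seen_k is None:
        raise EmptyInputError(f"{path}: empty count dump")
    counts = {km: c for km, c in counts.items() if c >= min_count}
    sid = sample_id if sample_id is not None else str(path)
    return KmerVector.from_counts(sid, seen_k, counts, validate=False)
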