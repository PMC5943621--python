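"""Exact-overlap unitig assembly of selected group-specific k-mers.

Selected k-mers are exact, error-filtered sequences, so contigs are built on
a bidirected overlap graph with exact (k-1)-base overlaps considered in both
orientations.  Maximal unambiguous paths (unitigs) are emitted; branching
nodes terminate contigs so no chimeric sequence is ever invented.  Output is
deterministic: traversal starts from lexicographically sorted k-mers, each
contig is reported in its canonical orientation (lexicographic min of the
sequence and its reverse complement) and contigs sort by descending length,
then sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import write_fasta
from .kmers import canonical, reverse_complement

__all__ = ["Contig", "assemble_kmers", "contig_report", "write_contigs_fasta"]

_BASES = "ACGT"


@dataclass
class Contig:
    """An assembled group-specific sequence."""

    id: str
    sequence: str
    n_kmers: int  # constituent selected k-mers (= length - k + 1)
    length: int
    track: str | None = None


def assemble_kmers(
    kmers: Iterable[str], min_len: int = 200, track: str | None = None
) -> list[Contig]:
    """Assemble same-length canonical k-mers into unitigs of >= min_len bases.

    Every length-k window of every emitted contig is in the input set, and
    each input k-mer is consumed by at most one contig.  Mixed k-mer lengths
    raise; an empty set yields an empty list.
    """
    kset: set[str] = set()
    k: int | None = None
    for km in kmers:
        s = km.upper()
        if k is None:
            k = len(s)
        elif len(s) != k:
            raise ValueError(f"mixed k-mer lengths: {len(s)} vs {k}")
        kset.add(canonical(s))
    if not kset:
        return []

    def fwd(s: str) -> list[str]:
        suffix = s[1:]
        return [suffix + b for b in _BASES if canonical(suffix + b) in kset]

    def bwd(s: str) -> list[str]:
        prefix = s[:-1]
        return [b + prefix for b in _BASES if canonical(b + prefix) in kset]

    visited: set[str] = set()
    sequences: list[str] = []
    for start in sorted(kset):
        if start in visited:
            continue
        visited.add(start)
        if start == reverse_complement(start):
            sequences.append(start)  # palindromic node: orientation ambiguous
            continue
        seq = start
        cur = start
        while True:  # extend right
            exts = fwd(cur)
            if len(exts) != 1:
                break
            nxt = exts[0]
            cn = canonical(nxt)
            if cn in visited or nxt == reverse_complement(nxt) or len(bwd(nxt)) != 1:
                break
            seq += nxt[-1]
            visited.add(cn)
            cur = nxt
        cur = start
        while True:  # extend left
            exts = bwd(cur)
            if len(exts) != 1:
                break
            prv = exts[0]
            cn = canonical(prv)
            if cn in visited or prv == reverse_complement(prv) or len(fwd(prv)) != 1:
                break
            seq = prv[0] + seq
            visited.add(cn)
            cur = prv
        sequences.append(seq)

    oriented = [min(s, reverse_complement(s)) for s in sequences]
    oriented.sort(key=lambda s: (-len(s), s))
    contigs = [
        Contig(
            id=f"contig_{i + 1}",
            sequence=s,
            n_kmers=len(s) - k + 1,
            length=len(s),
            track=track,
        )
        for i, s in enumerate(oriented)
        if len(s) >= min_len
    ]
    return contigs


def contig_report(contigs: Sequence[Contig], kmers: Iterable[str]) -> dict:
    """Summary of an assembly: counts, length distribution, placed fraction."""
    n_input = len({canonical(km.upper()) for km in kmers})
    lengths = [c.length for c in contigs]
    placed = sum(c.n_kmers for c in contigs)
    return {
        "n_contigs": len(contigs),
        "n_input_kmers": n_input,
        "kmers_placed": placed,
        "placed_fraction": placed / n_input if n_input else 0.0,
        "total_bases": sum(lengths),
        "min_length": min(lengths) if lengths else 0,
        "max_length": max(lengths) if lengths else 0,
        "mean_length": sum(lengths) / len(lengths) if lengths else 0.0,
    }


def write_contigs_fasta(contigs: Sequence[Contig], path) -> None:
    """FASTA with headers ``>contig_<n> len=<L> kmers=<m> [track=<t>]``."""

    def records():
        for c in contigs:
            name = f"{c.id} len={c.length} kmers={c.n_kmers}"
            if c.track:
                name += f" track={c.track}"
            yield name, c.sequence

    write_fasta(records(), path)
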