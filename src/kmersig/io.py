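"""Sample sheets and sequence-file readers.

The sample sheet is a TSV with columns ``sample_id``, ``group`` and a
comma-separated list of FASTA/FASTQ paths (plain or gzip).  Group tokens are
normalized: case/1/P/patient/disease -> ``case``; control/0/H/healthy -> ``control``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

CASE = "case"
CONTROL = "control"

_GROUP_ALIASES = {
    "case": CASE, "1": CASE, "p": CASE, "patient": CASE, "disease": CASE,
    "control": CONTROL, "0": CONTROL, "h": CONTROL, "healthy": CONTROL,
}


def normalize_group(token: str) -> str:
    key = token.strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValueError(f"unrecognized group label {token!r}")
    return _GROUP_ALIASES[key]


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    group: str
    paths: tuple[str, ...] = ()


@dataclass
class SampleSheet:
    """Ordered list of (sample_id, group, files); both groups non-empty."""

    entries: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample_id(s): {dup}")
        groups = {e.group for e in self.entries}
        if not {CASE, CONTROL} <= groups:
            raise ValueError("sample sheet must contain both case and control samples")

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        """1 for case, 0 for control, in sheet order."""
        return np.array([1 if e.group == CASE else 0 for e in self.entries], dtype=int)

    @property
    def n_case(self) -> int:
        return int(self.labels.sum())

    @property
    def n_control(self) -> int:
        return len(self.entries) - self.n_case

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, indices: Sequence[int]) -> "SampleSheet":
        return SampleSheet([self.entries[i] for i in indices])

    def relabeled(self, labels: Sequence[int]) -> "SampleSheet":
        """Same samples/paths with a new case/control assignment."""
        if len(labels) != len(self.entries):
            raise ValueError("label vector length mismatch")
        return SampleSheet(
            [
                SampleEntry(e.sample_id, CASE if l else CONTROL, e.paths)
                for e, l in zip(self.entries, labels)
            ]
        )

    # -- TSV ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        entries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].strip().lower() in {"sample_id", "sample", "id"}:
                    continue
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
                sid = parts[0].strip()
                group = normalize_group(parts[1])
                paths = tuple(
                    p.strip() for p in parts[2].split(",") if p.strip()
                ) if len(parts) > 2 and parts[2].strip() else ()
                entries.append(SampleEntry(sid, group, paths))
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tgroup\tpaths\n")
            for e in self.entries:
                fh.write(f"{e.sample_id}\t{e.group}\t{','.join(e.paths)}\n")


# -- sequence readers --------------------------------------------------------


def open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def sniff_format(path) -> str:
    """'fasta' or 'fastq', by extension then by first record character."""
    stem = str(path)
    if stem.endswith(".gz"):
        stem = stem[:-3]
    suffix = Path(stem).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    with open_text(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    raise ValueError(f"{path}: empty sequence file")


def iter_reads(paths: Sequence) -> Iterator[str]:
    """Yield read sequences (as strings) from FASTA/FASTQ files, gz or plain.

    Multiple files (e.g. paired-end mates) are simply concatenated: mates are
    extra reads of the same sample, no pairing logic.
    """
    for path in paths:
        fmt = sniff_format(path)
        with open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq)


def write_fasta(records: Iterator[tuple[str, str]], path, compress: bool | None = None) -> None:
    """Write (name, sequence) pairs; gzip if the path ends in .gz."""
    if compress is None:
        compress = str(path).endswith(".gz")
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
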