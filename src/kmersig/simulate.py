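"""Synthetic two-group metagenomic communities with known truth.

The community emulates a human-gut-like design: a set of background genomes
with identical central relative abundances in both groups, one
"shared-common" strain present in both groups, one "case-only" strain that
shares a configurable fraction (default 87%) of its sequence with the
shared-common strain and is present only in cases, and one "differential"
genome whose control:case central-abundance ratio is a configurable fold
change (default 3x).  Default central abundances follow the published gut
profile this design mirrors: shared-common 18%, case-only 6% (cases only),
differential 9%/3%, and eight backgrounds at 7, 16, 10, 10, 10, 8, 6 and 6%.

Per-sample abundances add half-normal noise — |Normal(0, sigma)| with sigma
equal to each genome's central abundance — and are renormalized to a valid
composition.  Reads are drawn with probability proportional to abundance
times genome length (abundances are cell proportions), uniform start and
strand, with optional i.i.d. substitution errors.  All randomness derives
from a single seed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import CASE, CONTROL, SampleEntry, SampleSheet, write_fasta

__all__ = [
    "Genome",
    "CommunityTruth",
    "ReadSet",
    "SimConfig",
    "make_community",
    "sample_abundances",
    "simulate_reads",
    "simulate_dataset",
    "write_fixture",
    "load_truth",
]

ROLE_BACKGROUND = "background"
ROLE_SHARED = "shared-common"
ROLE_CASE_ONLY = "case-only"
ROLE_DIFFERENTIAL = "differential"

# central relative abundances of the eight background genomes (both groups)
_BG_CENTRAL = (0.07, 0.16, 0.10, 0.10, 0.10, 0.08, 0.06, 0.06)
_SHARED_CENTRAL = 0.18
_CASE_ONLY_CENTRAL = 0.06
_DIFF_CONTROL_CENTRAL = 0.09

_CHAR_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE_LUT[ord(_c)] = _i


@dataclass
class Genome:
    name: str
    sequence: str
    role: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunityTruth:
    """Simulated genomes, group abundance profiles, and truth regions.

    ``regions`` maps category -> list of (genome_name, start, end) with
    0-based half-open coordinates:

    * ``case-specific`` — the case-only genome minus its shared intervals
      (the replaced blocks);
    * ``common`` — the retained (shared) intervals of the case-only genome;
    * ``differential`` — the whole differential genome;
    * ``case-only-genome`` — the whole case-only genome (used for the
      strain-level precision of the logical track).
    """

    genomes: list[Genome]
    shared_fraction: float
    fold_change: float
    profiles: dict[str, np.ndarray]  # group -> central abundances (sum 1)
    regions: dict[str, list[tuple[str, int, int]]]
    seed: int | None = None

    @property
    def genome_names(self) -> list[str]:
        return [g.name for g in self.genomes]

    def genome(self, name: str) -> Genome:
        for g in self.genomes:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class ReadSet:
    """One sample's reads with per-read provenance for testing."""

    sample_id: str
    group: str
    reads: list[str]
    read_len: int
    provenance: dict = field(default_factory=dict)  # genome_idx, pos, strand arrays


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _CHAR_LUT[rng.integers(0, 4, length)].tobytes().decode()


def _default_profiles(
    n_background: int, fold_change: float
) -> tuple[np.ndarray, np.ndarray]:
    """Central abundances ordered [shared, case-only, differential, bg...].

    Controls: 0.18 + 0 + 0.09 + backgrounds(0.73) = 1.  Cases replace the
    differential mass so that after renormalization the control:case ratio
    equals ``fold_change`` exactly: with r = 0.09 / fc, the raw case value is
    d = 0.97 r / (1 - r), and the case profile is divided by 0.97 + d.
    """
    if n_background == len(_BG_CENTRAL):
        bg = np.array(_BG_CENTRAL)
    else:
        bg = np.full(n_background, sum(_BG_CENTRAL) / n_background)
    ctrl = np.concatenate(([_SHARED_CENTRAL, 0.0, _DIFF_CONTROL_CENTRAL], bg))
    ctrl = ctrl / ctrl.sum()
    r = _DIFF_CONTROL_CENTRAL / fold_change
    others = _SHARED_CENTRAL + _CASE_ONLY_CENTRAL + bg.sum()
    d = others * r / (1.0 - r)
    case = np.concatenate(([_SHARED_CENTRAL, _CASE_ONLY_CENTRAL, d], bg))
    case = case / case.sum()
    return ctrl, case


def make_community(
    n_background: int = 8,
    genome_len: int = 50_000,
    shared_fraction: float = 0.87,
    fold_change: float = 3.0,
    profiles: dict[str, Sequence[float]] | None = None,
    n_blocks: int = 10,
    seed: int | None = None,
) -> CommunityTruth:
    """Build the community genomes and record exact truth regions.

    The case-only genome is a copy of the shared-common genome with
    ``n_blocks`` intervals totalling (1 - shared_fraction) of its length
    replaced by novel uniform DNA; the replaced intervals are the
    case-specific truth regions.
    """
    if not (0.0 < shared_fraction <= 1.0):
        raise ValueError(f"shared_fraction must be in (0, 1], got {shared_fraction}")
    if fold_change <= 0:
        raise ValueError(f"fold_change must be positive, got {fold_change}")
    rng = np.random.default_rng(seed)

    shared_seq = _random_dna(rng, genome_len)
    total_repl = int(round((1.0 - shared_fraction) * genome_len))
    intervals: list[tuple[int, int]] = []
    if total_repl > 0:
        blocks = min(n_blocks, total_repl)
        base = total_repl // blocks
        lens = [base + (1 if i < total_repl % blocks else 0) for i in range(blocks)]
        gap_min = min(100, max(1, (genome_len - total_repl) // (2 * (blocks + 1))))
        free = genome_len - total_repl - gap_min * (blocks + 1)
        if free < 0:
            raise ValueError("genome too short for the requested replacement blocks")
        extra = rng.multinomial(free, np.full(blocks + 1, 1.0 / (blocks + 1)))
        pos = 0
        for i, L in enumerate(lens):
            pos += gap_min + int(extra[i])
            intervals.append((pos, pos + L))
            pos += L
    case_chars = np.frombuffer(shared_seq.encode(), dtype=np.uint8).copy()
    for start, end in intervals:
        novel = _random_dna(rng, end - start)
        case_chars[start:end] = np.frombuffer(novel.encode(), dtype=np.uint8)
    case_seq = case_chars.tobytes().decode()

    genomes = [
        Genome("shared_common", shared_seq, ROLE_SHARED),
        Genome("case_only", case_seq, ROLE_CASE_ONLY),
        Genome("differential", _random_dna(rng, genome_len), ROLE_DIFFERENTIAL),
    ]
    for i in range(n_background):
        genomes.append(Genome(f"background_{i + 1}", _random_dna(rng, genome_len), ROLE_BACKGROUND))

    if profiles is None:
        ctrl, case = _default_profiles(n_background, fold_change)
    else:
        ctrl = np.asarray(profiles[CONTROL], dtype=float)
        case = np.asarray(profiles[CASE], dtype=float)
        if ctrl.size != len(genomes) or case.size != len(genomes):
            raise ValueError("profiles must have one abundance per genome")
        ctrl = ctrl / ctrl.sum()
        case = case / case.sum()

    # common intervals = complement of the replaced blocks on the case genome
    common: list[tuple[str, int, int]] = []
    prev = 0
    for start, end in intervals:
        if start > prev:
            common.append(("case_only", prev, start))
        prev = end
    if prev < genome_len:
        common.append(("case_only", prev, genome_len))

    regions = {
        "case-specific": [("case_only", s, e) for s, e in intervals],
        "common": common,
        "differential": [("differential", 0, genome_len)],
        "case-only-genome": [("case_only", 0, genome_len)],
    }
    return CommunityTruth(
        genomes=genomes,
        shared_fraction=shared_fraction,
        fold_change=fold_change,
        profiles={CONTROL: ctrl, CASE: case},
        regions=regions,
        seed=seed,
    )


def sample_abundances(
    truth: CommunityTruth, group: str, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """One sample's relative abundances: central + half-normal noise.

    a_g = c_g + |Normal(0, c_g)| for genomes with c_g > 0, renormalized to
    sum to 1; genomes absent from the group (c_g = 0) stay exactly 0.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    central = truth.profiles[group]
    noise = np.abs(rng.normal(0.0, np.where(central > 0, central, 0.0)))
    a = central + np.where(central > 0, noise, 0.0)
    return a / a.sum()


def simulate_reads(
    truth: CommunityTruth,
    group: str,
    n_reads: int = 200_000,
    read_len: int = 100,
    err_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "sample",
) -> ReadSet:
    """Draw error-free (or substitution-noised) fixed-length reads.

    A genome is chosen per read with probability proportional to abundance
    times genome length, the start is uniform, the strand uniform; with
    ``err_rate`` > 0 each base substitutes independently.
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be positive, got {n_reads}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lengths = np.array([len(g) for g in truth.genomes], dtype=float)
    if read_len > lengths.min():
        raise ValueError("read_len exceeds the shortest genome")
    ab = sample_abundances(truth, group, rng)
    w = ab * lengths
    counts = rng.multinomial(n_reads, w / w.sum())

    reads: list[str] = []
    g_idx_parts, pos_parts, strand_parts = [], [], []
    offsets = np.arange(read_len)
    for gi, c in enumerate(counts):
        if c == 0:
            continue
        g = truth.genomes[gi]
        codes = _CODE_LUT[np.frombuffer(g.sequence.encode(), dtype=np.uint8)]
        pos = rng.integers(0, len(g) - read_len + 1, c)
        strand = rng.integers(0, 2, c)
        win = codes[pos[:, None] + offsets]
        rc_rows = strand == 1
        if rc_rows.any():
            win[rc_rows] = (3 - win[rc_rows])[:, ::-1]
        if err_rate > 0:
            mask = rng.random(win.shape) < err_rate
            if mask.any():
                shift = rng.integers(1, 4, int(mask.sum())).astype(np.uint8)
                win[mask] = (win[mask] + shift) % 4
        chars = _CHAR_LUT[win]
        reads.extend(s.decode() for s in chars.reshape(c, read_len).view(f"S{read_len}").ravel())
        g_idx_parts.append(np.full(c, gi))
        pos_parts.append(pos)
        strand_parts.append(strand)
    provenance = {
        "genome_idx": np.concatenate(g_idx_parts),
        "pos": np.concatenate(pos_parts),
        "strand": np.concatenate(strand_parts),
        "abundances": ab,
    }
    return ReadSet(sample_id=sample_id, group=group, reads=reads, read_len=read_len, provenance=provenance)


@dataclass
class SimConfig:
    """Desk-scale study design: 15+15 samples over 50 kb genomes at ~24x
    depth for the rarest genome, k = 31."""

    n_background: int = 8
    genome_len: int = 50_000
    shared_fraction: float = 0.87
    fold_change: float = 3.0
    n_blocks: int = 10
    n_case: int = 15
    n_control: int = 15
    n_reads: int = 200_000
    read_len: int = 100
    err_rate: float = 0.0
    k: int = 31


TOY = SimConfig()
SMALL = SimConfig(genome_len=3_000, n_reads=10_000, n_case=10, n_control=10)


def simulate_dataset(
    cfg: SimConfig = TOY, seed: int | None = None
) -> tuple[CommunityTruth, list[ReadSet], SampleSheet]:
    """Community + per-sample read sets + sample sheet from one seed."""
    ss = np.random.SeedSequence(0 if seed is None else seed)
    truth = make_community(
        n_background=cfg.n_background,
        genome_len=cfg.genome_len,
        shared_fraction=cfg.shared_fraction,
        fold_change=cfg.fold_change,
        n_blocks=cfg.n_blocks,
        seed=int(ss.generate_state(1)[0] % (2**31)),
    )
    children = ss.spawn(cfg.n_control + cfg.n_case)
    readsets: list[ReadSet] = []
    entries: list[SampleEntry] = []
    for i in range(cfg.n_control):
        sid = f"control_{i + 1:02d}"
        readsets.append(
            simulate_reads(
                truth, CONTROL, cfg.n_reads, cfg.read_len, cfg.err_rate,
                rng=np.random.default_rng(children[i]), sample_id=sid,
            )
        )
        entries.append(SampleEntry(sid, CONTROL))
    for i in range(cfg.n_case):
        sid = f"case_{i + 1:02d}"
        readsets.append(
            simulate_reads(
                truth, CASE, cfg.n_reads, cfg.read_len, cfg.err_rate,
                rng=np.random.default_rng(children[cfg.n_control + i]), sample_id=sid,
            )
        )
        entries.append(SampleEntry(sid, CASE))
    return truth, readsets, SampleSheet(entries)


def write_fixture(
    truth: CommunityTruth,
    readsets: Sequence[ReadSet],
    outdir,
    force: bool = False,
    compress: bool = True,
) -> SampleSheet:
    """Write FASTA per sample, sample sheet, genomes, truth JSON and BED."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    entries = []
    for rs in readsets:
        suffix = ".fa.gz" if compress else ".fa"
        path = outdir / "samples" / f"{rs.sample_id}{suffix}"
        write_fasta(
            ((f"{rs.sample_id}_read_{i}", s) for i, s in enumerate(rs.reads)), path
        )
        entries.append(SampleEntry(rs.sample_id, rs.group, (str(path),)))
    sheet = SampleSheet(entries)
    sheet.to_tsv(outdir / "samples.tsv")
    write_fasta(((g.name, g.sequence) for g in truth.genomes), outdir / "genomes.fa")
    meta = {
        "shared_fraction": truth.shared_fraction,
        "fold_change": truth.fold_change,
        "roles": {g.name: g.role for g in truth.genomes},
        "profiles": {grp: prof.tolist() for grp, prof in truth.profiles.items()},
        "genome_order": truth.genome_names,
        "regions": {cat: [[g, s, e] for g, s, e in regs] for cat, regs in truth.regions.items()},
        "seed": truth.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    with open(outdir / "regions.bed", "w") as fh:
        for cat, regs in sorted(truth.regions.items()):
            for g, s, e in regs:
                fh.write(f"{g}\t{s}\t{e}\t{cat}\n")
    return sheet


def load_truth(outdir) -> CommunityTruth:
    """Reconstruct a CommunityTruth written by :func:`write_fixture`."""
    from Bio import SeqIO

    outdir = Path(outdir)
    with open(outdir / "truth.json") as fh:
        meta = json.load(fh)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(outdir / "genomes.fa"), "fasta")}
    genomes = [
        Genome(name, seqs[name], meta["roles"][name]) for name in meta["genome_order"]
    ]
    return CommunityTruth(
        genomes=genomes,
        shared_fraction=meta["shared_fraction"],
        fold_change=meta["fold_change"],
        profiles={g: np.asarray(p) for g, p in meta["profiles"].items()},
        regions={cat: [tuple(r) for r in regs] for cat, regs in meta["regions"].items()},
        seed=meta.get("seed"),
    )
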