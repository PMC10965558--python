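"""Genome sequence handling: FASTA reading, CpG site extraction, chunk planning.

All coordinates are 0-based, half-open. A CpG site is recorded at the
position of its C on the forward strand; since CpG is its own reverse
complement one record represents both strands.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, InputError, ParseError

__all__ = [
    "ChromosomeSequence",
    "CpGSiteList",
    "ChunkPlan",
    "read_fasta",
    "extract_cpg_sites",
    "plan_chunks",
    "write_cpg_bed",
    "read_cpg_bed",
]


@dataclass
class ChromosomeSequence:
    """One chromosome: name, uppercase sequence, and derived counts."""

    name: str
    seq: str
    length: int = field(init=False)
    n_count: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be nonempty")
        self.seq = self.seq.upper()
        self.length = len(self.seq)
        self.n_count = self.seq.count("N")


@dataclass
class CpGSiteList:
    """Sorted 0-based positions of the C of every CG dinucleotide."""

    chrom: str
    positions: np.ndarray  # int64, strictly increasing, consecutive diffs >= 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size > 1 and np.any(np.diff(self.positions) < 2):
            raise ValueError("CpG positions must be strictly increasing with gaps >= 2")

    def __len__(self) -> int:
        return int(self.positions.size)

    def gaps(self) -> np.ndarray:
        """Inter-CpG distances d_i = x_{i+1} - x_i - 1 (each >= 1)."""
        return np.diff(self.positions) - 1


@dataclass
class ChunkPlan:
    """Tiling of a chromosome into overlapping chunks safe for parallel clustering.

    Adjacent chunks share exactly ``overlap`` bases; overlap = d_max + 2
    guarantees any gap <= d_max adjacency (plus the 2 bp of the CpG itself)
    is fully visible inside at least one chunk.
    """

    chrom: str
    chunk_starts: list[int]
    chunk_size: int
    overlap: int

    def chunk_intervals(self, chrom_length: int) -> list[tuple[int, int]]:
        return [(s, min(s + self.chunk_size, chrom_length)) for s in self.chunk_starts]


def read_fasta(path: str | os.PathLike) -> Iterator[ChromosomeSequence]:
    """Stream records from a (possibly multi-record, wrapped) FASTA file.

    Sequences are uppercased; record order is preserved. An empty file
    yields an empty stream. Sequence data appearing before the first
    header is a parse error reported with its line number.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: sequence data before first FASTA header at line {lineno}"
                )
            break
    for record in SeqIO.parse(path, "fasta"):
        yield ChromosomeSequence(name=record.id, seq=str(record.seq))


def extract_cpg_sites(chrom_seq: ChromosomeSequence) -> CpGSiteList:
    """Positions of every CG dinucleotide (the C, forward strand)."""
    if chrom_seq.length < 2:
        return CpGSiteList(chrom=chrom_seq.name, positions=np.empty(0, dtype=np.int64))
    arr = np.frombuffer(chrom_seq.seq.encode("ascii"), dtype=np.uint8)
    mask = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return CpGSiteList(chrom=chrom_seq.name, positions=np.flatnonzero(mask).astype(np.int64))


def plan_chunks(chrom_seq: ChromosomeSequence, chunk_size: int, d_max: int) -> ChunkPlan:
    """Tile a chromosome into chunks with overlap d_max + 2.

    start_{k+1} = start_k + chunk_size - overlap, until a chunk reaches the
    chromosome end. Requires chunk_size > 2 * (d_max + 2) so the overlap
    never spans more than one chunk boundary.
    """
    overlap = d_max + 2
    if chunk_size <= 2 * overlap:
        raise ConfigurationError(
            f"chunk_size={chunk_size} must exceed 2*(d_max+2)={2 * overlap}"
        )
    starts = [0]
    while starts[-1] + chunk_size < chrom_seq.length:
        starts.append(starts[-1] + chunk_size - overlap)
    return ChunkPlan(chrom=chrom_seq.name, chunk_starts=starts, chunk_size=chunk_size, overlap=overlap)


def write_cpg_bed(sites: CpGSiteList, path: str | os.PathLike) -> None:
    """Export CpG sites as BED6 (name="CpG", score=0, strand="+")."""
    with open(path, "w") as fh:
        for pos in sites.positions:
            fh.write(f"{sites.chrom}\t{pos}\t{pos + 2}\tCpG\t0\t+\n")


def read_cpg_bed(path: str | os.PathLike) -> list[CpGSiteList]:
    """Re-read a BED6 CpG export; inverse of :func:`write_cpg_bed`."""
    per_chrom: dict[str, list[int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields: Sequence[str] = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: expected >=3 BED columns at line {lineno}")
            chrom, start = fields[0], int(fields[1])
            if chrom not in per_chrom:
                per_chrom[chrom] = []
                order.append(chrom)
            per_chrom[chrom].append(start)
    return [
        CpGSiteList(chrom=c, positions=np.asarray(per_chrom[c], dtype=np.int64))
        for c in order
    ]
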