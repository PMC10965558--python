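"""Synthetic genomes, annotations and methylation tracks with known truth.

The genome generator places background CpG sites with i.i.d. geometric
inter-CpG gaps — exactly the null model the islet predictor assumes —
and plants dense CpG runs at requested locations by overwriting the
background (coordinates stay stable). Filler bases are drawn with a
configurable GC fraction and post-processed so no accidental CG
dinucleotide survives outside the recorded site list: every CpG in the
output is a recorded one.

Every artifact is a pure function of its seed; the truth object records
the seed and everything needed to verify recovery.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel
from .errors import ConfigurationError
from .sequence import ChromosomeSequence

__all__ = [
    "ClusterSpec",
    "SyntheticTruth",
    "generate_genome",
    "generate_annotation",
    "generate_methylation",
    "write_preset",
    "PRESETS",
]


@dataclass
class ClusterSpec:
    """A planted CpG run: n sites starting at ``start`` with gaps drawn
    uniformly in [1, gap_max]."""

    start: int
    n: int
    gap_max: int = 3


@dataclass
class SyntheticTruth:
    seed: int
    background_p: float
    length: int
    chrom: str
    planted_clusters: list[dict] = field(default_factory=list)
    background_positions: list[int] = field(default_factory=list)
    level_probs: tuple[float, float, float] | None = None
    gene_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def _fill_background(
    rng: np.random.Generator, length: int, background_p: float
) -> np.ndarray:
    """Background site positions with geometric(background_p) gaps."""
    if not 0 < background_p < 0.5:
        raise ConfigurationError("background_p must be in (0, 0.5)")
    positions = []
    x = int(rng.geometric(background_p)) - 1
    while x + 2 <= length:
        positions.append(x)
        gap = int(rng.geometric(background_p))
        x = x + gap + 1
    return np.asarray(positions, dtype=np.int64)


def generate_genome(
    length: int,
    background_p: float,
    clusters: list[ClusterSpec] | None = None,
    seed: int = 0,
    gc_fraction: float = 0.4,
    chrom: str = "chrS",
) -> tuple[ChromosomeSequence, SyntheticTruth]:
    """Synthetic chromosome with geometric background CpGs and planted runs."""
    rng = np.random.default_rng(seed)
    clusters = list(clusters or [])

    planted: list[dict] = []
    planted_pos: list[np.ndarray] = []
    for spec in sorted(clusters, key=lambda c: c.start):
        if spec.n < 2 or spec.gap_max < 1:
            raise ConfigurationError(f"invalid cluster spec {spec}")
        gaps = rng.integers(1, spec.gap_max + 1, size=spec.n - 1)
        pos = spec.start + np.concatenate(([0], np.cumsum(gaps + 1)))
        end = int(pos[-1]) + 2
        if end > length:
            raise ConfigurationError(f"planted cluster {spec} exceeds chromosome length")
        if planted and spec.start < planted[-1]["end"] + 2:
            raise ConfigurationError(f"planted cluster {spec} overlaps the previous one")
        planted.append(
            {"start": int(pos[0]), "end": end, "n": spec.n, "positions": pos.tolist()}
        )
        planted_pos.append(pos)

    background = _fill_background(rng, length, background_p)
    # overwrite semantics: drop background sites near planted intervals
    for rec in planted:
        background = background[
            (background < rec["start"] - 2) | (background >= rec["end"])
        ]
    all_pos = np.sort(np.concatenate([background] + planted_pos)) if planted_pos else background
    if all_pos.size > 1:  # enforce >= 2 bp separation (background vs background edge case)
        keep = np.concatenate(([True], np.diff(all_pos) >= 2))
        all_pos = all_pos[keep]
        background = np.intersect1d(background, all_pos)

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    arr = rng.choice(bases, size=length, p=probs)
    arr[all_pos] = ord("C")
    arr[all_pos + 1] = ord("G")
    # erase accidental CG dinucleotides between filler bases (flipping the
    # G to A can never create a new CG, so one vectorized pass suffices)
    cg = np.zeros(length, dtype=bool)
    cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cg[all_pos] = False
    arr[np.flatnonzero(cg) + 1] = ord("A")

    seq = ChromosomeSequence(name=chrom, seq=arr.tobytes().decode("ascii"))
    truth = SyntheticTruth(
        seed=seed,
        background_p=background_p,
        length=length,
        chrom=chrom,
        planted_clusters=planted,
        background_positions=background.tolist(),
    )
    return seq, truth


def generate_annotation(
    genes: int,
    chrom_length: int,
    seed: int = 0,
    chrom: str = "chrS",
    coding_fraction: float = 0.8,
) -> tuple[str, list[GeneModel]]:
    """Toy gene models laid out in non-overlapping slots, as GFF3 text.

    Round-trips exactly through ``annotation.parse_annotation``.
    """
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    models: list[GeneModel] = []
    if genes > 0:
        slot = chrom_length // genes
        if slot < 300:
            raise ConfigurationError("chromosome too short for that many genes")
        for i in range(genes):
            gid = f"G{i + 1:06d}"
            slot_start = i * slot
            g_len = int(rng.integers(200, max(201, int(slot * 0.8))))
            g_start = slot_start + int(rng.integers(0, slot - g_len))  # 0-based
            g_end = g_start + g_len
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "protein_coding" if rng.random() < coding_fraction else "lncRNA"
            n_tx = int(rng.integers(1, 3))
            tss_list: list[int] = []
            exons: set[tuple[int, int]] = set()
            attrs = f"ID=gene:{gid};gene_id={gid};gene_name=SYN{i + 1};gene_type={biotype}"
            lines.append(
                f"{chrom}\tsynth\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t{attrs}"
            )
            for t in range(n_tx):
                t_start = g_start if t == 0 else g_start + int(rng.integers(0, g_len // 4))
                t_end = g_end if t == 0 else g_end - int(rng.integers(0, g_len // 4))
                tid = f"{gid}.{t + 1}"
                lines.append(
                    f"{chrom}\tsynth\ttranscript\t{t_start + 1}\t{t_end}\t.\t{strand}\t.\t"
                    f"ID=tx:{tid};Parent=gene:{gid}"
                )
                tss_list.append(t_start if strand == "+" else t_end - 1)
                t_len = t_end - t_start
                n_ex = int(rng.integers(1, 4))
                cuts = np.sort(rng.integers(1, t_len, size=2 * (n_ex - 1))) if n_ex > 1 else np.array([], dtype=int)
                bounds = np.concatenate(([0], cuts, [t_len]))
                for e in range(n_ex):
                    es, ee = t_start + int(bounds[2 * e]), t_start + int(bounds[2 * e + 1])
                    if ee - es < 1:
                        ee = es + 1
                    exons.add((es, ee))
                    lines.append(
                        f"{chrom}\tsynth\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                        f"ID=exon:{tid}.{e + 1};Parent=tx:{tid}"
                    )
            models.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=f"SYN{i + 1}",
                    biotype=biotype,
                    strand=strand,
                    chrom=chrom,
                    tss_list=sorted(set(tss_list)),
                    exons=sorted(exons),
                    gene_interval=(g_start, g_end),
                )
            )
    return "\n".join(lines) + "\n", models


_LEVEL_BANDS = {
    1: (np.nextafter(0.75, 1.0), 1.0),
    2: (0.0, 0.1),
    3: (0.1, np.nextafter(0.75, 1.0)),
}


def generate_methylation(
    positions: np.ndarray,
    level_probs: tuple[float, float, float],
    seed: int = 0,
    chrom: str = "chrS",
    coverage_range: tuple[int, int] = (5, 50),
) -> str:
    """bedMethyl text with one forward-strand record per CpG site.

    Each site draws a methylation level with probabilities
    (q1, q2, q3) = P(highly methylated, unmethylated, moderate), then a
    ratio uniform within that level's band, then a coverage uniform in
    ``coverage_range``.
    """
    q = np.asarray(level_probs, dtype=float)
    if q.size != 3 or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"level_probs must be 3 nonnegative values summing to 1: {level_probs}")
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=np.int64)
    levels = rng.choice([1, 2, 3], size=positions.size, p=q)
    lines = []
    for pos, lv in zip(positions, levels):
        lo, hi = _LEVEL_BANDS[int(lv)]
        ratio = float(rng.uniform(lo, hi))
        cov = int(rng.integers(coverage_range[0], coverage_range[1] + 1))
        percent = ratio * 100.0
        lines.append(
            f"{chrom}\t{pos}\t{pos + 1}\t.\t{min(1000, cov)}\t+\t{pos}\t{pos + 1}\t"
            f"0,0,0\t{cov}\t{percent:.10g}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


PRESETS = {
    "small": {
        "length": 100_000,
        "background_p": 0.01,
        "n_clusters": 5,
        "cluster_n": 10,
        "gap_max": 3,
        "genes": 10,
        "level_probs": (0.5, 0.3, 0.2),
    },
    "genome-like": {
        "length": 2_000_000,
        "background_p": 0.01,
        "n_clusters": 60,
        "cluster_n": 12,
        "gap_max": 3,
        "genes": 100,
        "level_probs": (0.5, 0.3, 0.2),
    },
}


def write_preset(preset: str, outdir, seed: int = 0) -> dict:
    """Write a complete fixture set (FASTA, GFF3, bedMethyl, truth JSON).

    Planted clusters are spread evenly over the chromosome; all files are
    a pure function of (preset, seed).
    """
    from .sequence import extract_cpg_sites

    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    os.makedirs(outdir, exist_ok=True)
    spacing = cfg["length"] // (cfg["n_clusters"] + 1)
    clusters = [
        ClusterSpec(start=(i + 1) * spacing, n=cfg["cluster_n"], gap_max=cfg["gap_max"])
        for i in range(cfg["n_clusters"])
    ]
    seq, truth = generate_genome(
        cfg["length"], cfg["background_p"], clusters, seed=seed
    )
    gff_text, gene_models = generate_annotation(
        cfg["genes"], cfg["length"], seed=seed + 1, chrom=seq.name
    )
    truth.gene_ids = [g.gene_id for g in gene_models]
    truth.level_probs = cfg["level_probs"]
    sites = extract_cpg_sites(seq)
    meth_text = generate_methylation(
        sites.positions, cfg["level_probs"], seed=seed + 2, chrom=seq.name
    )
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "bedmethyl": os.path.join(outdir, "methylation.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{seq.name}\n")
        for i in range(0, seq.length, 80):
            fh.write(seq.seq[i : i + 80] + "\n")
    with open(paths["gff3"], "w") as fh:
        fh.write(gff_text)
    with open(paths["bedmethyl"], "w") as fh:
        fh.write(meth_text)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
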