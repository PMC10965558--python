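"""Gene annotation parsing and CpG site / island annotation.

Assigns positions to structural/functional sequence categories
(core promoter > exon > intron > gene body (other) > intergenic), calls
CGI+ genes (protein-coding genes with at least one TSS inside a
predicted island) and classifies islands or genes into high /
intermediate / low CpG-island density classes (HCGI / ICGI / LCGI).

GFF3/GTF input is 1-based closed and converted to the package's
0-based half-open convention on read. The core promoter window defaults
to TSS-1000 / TSS+500 oriented by strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "GeneModel",
    "RegionAssignment",
    "DensityClass",
    "CATEGORIES",
    "DensityThresholds",
    "parse_annotation",
    "assign_region",
    "assign_regions",
    "call_cgi_plus_genes",
    "classify_density",
    "summarize_annotation",
]

CATEGORIES = ("core_promoter", "exon", "intron", "gene_body_other", "intergenic")

_TRANSCRIPT_TYPES = ("transcript", "mRNA")


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str
    strand: str  # "+" or "-"
    chrom: str
    tss_list: list[int]  # one per transcript, 0-based
    exons: list[tuple[int, int]]  # 0-based half-open
    gene_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class RegionAssignment:
    position: int
    category: str
    gene_id: str | None = None


@dataclass
class DensityClass:
    subject_id: str
    density_class: str | None  # "HCGI" | "ICGI" | "LCGI" | None (unclassifiable)
    oe_ratio: float | None
    gc_content: float | None


@dataclass
class DensityThresholds:
    """Promoter-class style thresholds on normalized O/E and GC."""

    hi_oe: float = 0.75
    hi_gc: float = 0.55
    lo_oe: float = 0.48


def parse_annotation(path) -> list[GeneModel]:
    """Read gene models from a GFF3 or GTF file via gffutils (in-memory db).

    TSS = transcript start on the + strand, transcript end - 1 on the
    - strand (0-based). Genes without any transcript children get their
    gene interval boundary as a single TSS. Orphan exons are skipped with
    a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted errors on bad dialects
        raise ParseError(f"could not parse annotation {path}: {exc}") from exc

    genes: list[GeneModel] = []
    gene_ids = set()
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gf.attributes.get("gene_id", [gf.id])[0]
        gene_ids.add(gf.id)
        name = gf.attributes.get("gene_name", gf.attributes.get("Name", [gene_id]))[0]
        biotype = gf.attributes.get(
            "gene_type", gf.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        strand = gf.strand if gf.strand in ("+", "-") else "+"
        tss_list: list[int] = []
        exons: list[tuple[int, int]] = []
        for tr in db.children(gf, featuretype=_TRANSCRIPT_TYPES):
            tss_list.append(tr.start - 1 if strand == "+" else tr.end - 1)
        for ex in db.children(gf, featuretype="exon"):
            exons.append((ex.start - 1, ex.end))
        if not tss_list:
            tss_list = [gf.start - 1 if strand == "+" else gf.end - 1]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=name,
                biotype=biotype,
                strand=strand,
                chrom=gf.seqid,
                tss_list=sorted(set(tss_list)),
                exons=sorted(set(exons)),
                gene_interval=(gf.start - 1, gf.end),
            )
        )
    n_orphans = sum(
        1
        for ex in db.features_of_type("exon")
        if not any(p.featuretype == "gene" for p in db.parents(ex))
        and not any(
            any(pp.featuretype == "gene" for pp in db.parents(p))
            for p in db.parents(ex)
        )
    )
    if n_orphans:
        warnings.warn(f"{path}: skipped {n_orphans} orphan exon(s) with no gene parent")
    return genes


class _IntervalIndex:
    """Sorted-starts interval lookup with bounded back-scan."""

    def __init__(self, intervals: Sequence[tuple[int, int, object]]):
        arr = sorted(intervals, key=lambda t: (t[0], t[1]))
        self.starts = np.asarray([t[0] for t in arr], dtype=np.int64)
        self.ends = np.asarray([t[1] for t in arr], dtype=np.int64)
        self.payload = [t[2] for t in arr]
        self.max_len = int((self.ends - self.starts).max()) if arr else 0

    def hits(self, pos: int) -> list:
        hi = int(np.searchsorted(self.starts, pos, side="right"))
        lo = int(np.searchsorted(self.starts, pos - self.max_len, side="left"))
        return [self.payload[i] for i in range(lo, hi) if self.ends[i] > pos]


def _promoter_window(tss: int, strand: str, up: int, down: int) -> tuple[int, int]:
    # oriented offset o in [-up, down): + strand o = pos - tss, - strand o = tss - pos
    if strand == "+":
        return (tss - up, tss + down)
    return (tss - down + 1, tss + up + 1)


class _AnnotationIndex:
    def __init__(self, genes: Sequence[GeneModel], promoter_up: int, promoter_down: int):
        promoters, exons, spans, bodies = [], [], [], []
        for g in genes:
            for tss in g.tss_list:
                s, e = _promoter_window(tss, g.strand, promoter_up, promoter_down)
                promoters.append((max(s, 0), e, (tss, g)))
            for s, e in g.exons:
                exons.append((s, e, g))
            if g.exons:
                spans.append((min(s for s, _ in g.exons), max(e for _, e in g.exons), g))
            bodies.append((g.gene_interval[0], g.gene_interval[1], g))
        self.promoters = _IntervalIndex(promoters)
        self.exons = _IntervalIndex(exons)
        self.spans = _IntervalIndex(spans)
        self.bodies = _IntervalIndex(bodies)


def _nearest_tss_key(pos: int, g: GeneModel):
    return (min(abs(pos - t) for t in g.tss_list), g.gene_id)


def assign_regions(
    positions: Iterable[int],
    genes: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 500,
) -> list[RegionAssignment]:
    """Assign each position to exactly one category.

    Precedence: core_promoter > exon > intron > gene_body_other >
    intergenic. Ties between overlapping genes are broken by nearest TSS,
    then lexicographically smallest gene_id.
    """
    idx = _AnnotationIndex(genes, promoter_up, promoter_down)
    out: list[RegionAssignment] = []
    for pos in positions:
        pos = int(pos)
        prom = idx.promoters.hits(pos)
        if prom:
            tss, g = min(prom, key=lambda t: (abs(pos - t[0]), t[1].gene_id))
            out.append(RegionAssignment(pos, "core_promoter", g.gene_id))
            continue
        ex = idx.exons.hits(pos)
        if ex:
            g = min(ex, key=lambda g: _nearest_tss_key(pos, g))
            out.append(RegionAssignment(pos, "exon", g.gene_id))
            continue
        sp = idx.spans.hits(pos)
        if sp:
            g = min(sp, key=lambda g: _nearest_tss_key(pos, g))
            out.append(RegionAssignment(pos, "intron", g.gene_id))
            continue
        body = idx.bodies.hits(pos)
        if body:
            g = min(body, key=lambda g: _nearest_tss_key(pos, g))
            out.append(RegionAssignment(pos, "gene_body_other", g.gene_id))
            continue
        out.append(RegionAssignment(pos, "intergenic", None))
    return out


def assign_region(
    position: int,
    genes: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 500,
) -> RegionAssignment:
    """Single-position convenience wrapper over :func:`assign_regions`."""
    return assign_regions([position], genes, promoter_up, promoter_down)[0]


def call_cgi_plus_genes(islets: Sequence, genes: Sequence[GeneModel]) -> set[str]:
    """CGI+ genes: protein-coding genes with >= 1 TSS inside an island.

    A TSS t is inside island [s, e) iff s <= t < e (half-open: a TSS at
    the island end is outside).
    """
    by_chrom: dict[str, list] = {}
    for isl in islets:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    sorted_idx = {
        chrom: (
            np.asarray([i.start for i in sorted(lst, key=lambda x: x.start)]),
            np.asarray([i.end for i in sorted(lst, key=lambda x: x.start)]),
        )
        for chrom, lst in by_chrom.items()
    }
    plus: set[str] = set()
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        if g.chrom not in sorted_idx:
            continue
        starts, ends = sorted_idx[g.chrom]
        for t in g.tss_list:
            i = int(np.searchsorted(starts, t, side="right")) - 1
            if i >= 0 and t < ends[i]:
                plus.add(g.gene_id)
                break
    return plus


def classify_density(subject, thresholds: DensityThresholds | None = None) -> DensityClass:
    """HCGI if O/E >= hi_oe and GC >= hi_gc; LCGI if O/E < lo_oe; else
    ICGI. Missing O/E -> unclassifiable (class None).

    ``subject`` may be an IsletRecord (features used), a FeatureVector,
    or any object with ``oe_ratio`` and ``gc_content`` attributes.
    """
    th = thresholds or DensityThresholds()
    fv = getattr(subject, "features", None) or subject
    oe = getattr(fv, "oe_ratio", None)
    gc = getattr(fv, "gc_content", None)
    sid = getattr(subject, "gene_id", None) or (
        f"{subject.chrom}:{subject.start}-{subject.end}"
        if hasattr(subject, "chrom")
        else "subject"
    )
    if oe is None or (isinstance(oe, float) and np.isnan(oe)):
        return DensityClass(sid, None, None, gc)
    if oe >= th.hi_oe and gc is not None and gc >= th.hi_gc:
        cls = "HCGI"
    elif oe < th.lo_oe:
        cls = "LCGI"
    else:
        cls = "ICGI"
    return DensityClass(sid, cls, oe, gc)


def summarize_annotation(
    assignments: Sequence[RegionAssignment],
    islets_by_d: Mapping[int, Sequence] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-category site counts and, per interval d, islet-site counts and
    mean island CpG density.

    ``site_counts`` always lists every category (zero-filled) and sums to
    the number of assignments. Islands are attributed to the category of
    their first CpG site.
    """
    cat = pd.Categorical(
        [a.category for a in assignments], categories=list(CATEGORIES)
    )
    site_counts = (
        pd.Series(cat).value_counts().reindex(list(CATEGORIES), fill_value=0)
    )
    tables: dict[str, pd.DataFrame] = {
        "site_counts": site_counts.rename_axis("category").reset_index(name="n_sites")
    }
    if islets_by_d:
        by_pos = {a.position: a.category for a in assignments}
        rows = []
        for d in sorted(islets_by_d):
            for cat_name in CATEGORIES:
                members = [
                    isl
                    for isl in islets_by_d[d]
                    if by_pos.get(int(isl.cpg_positions[0])) == cat_name
                ]
                dens = [
                    isl.features.cpg_density
                    for isl in members
                    if isl.features is not None
                ]
                rows.append(
                    {
                        "d": d,
                        "category": cat_name,
                        "n_islets": len(members),
                        "n_sites": int(sum(isl.n for isl in members)),
                        "mean_cpg_density": float(np.mean(dens)) if dens else np.nan,
                    }
                )
        tables["islet_by_category"] = pd.DataFrame(rows)
    return tables
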