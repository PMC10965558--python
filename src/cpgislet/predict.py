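"""Position-defined CpG island (CpG islet) prediction.

The predictor clusters CpG sites by their inter-CpG distance

    d_i = x_{i+1} - x_i - 1

(the open gap between the C of one CpG and the C of the next, minimum 1):
a candidate cluster is a maximal run of consecutive CpGs whose successive
gaps are all <= d. Under a null model in which gaps are i.i.d. geometric,

    P(d) = (1 - p)^(d-1) * p,

with p the per-base CpG probability of the chromosome, the total gap sum
of an n-CpG cluster is a sum of n-1 shifted geometric variables, i.e. a
shifted negative binomial. The cluster p-value is the left tail of that
sum at the observed total gap; clusters with p-value <= alpha are
reported as islets. The default interval d = 12 bp targets short,
position-sensitive islands.

Chromosomes longer than ``chunk_size`` are cut into chunks overlapping by
d_max + 2 bases, clustered independently (optionally on a worker pool)
and merged deterministically; the merged result is identical to
single-pass clustering for every worker count.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ComputeError, ConfigurationError
from .features import FeatureVector, compute_features
from .sequence import ChromosomeSequence, CpGSiteList, extract_cpg_sites, plan_chunks

__all__ = [
    "GeometricModel",
    "CandidateCluster",
    "IsletRecord",
    "fit_geometric_model",
    "geometric_pmf",
    "cluster_sites",
    "cluster_pvalue",
    "merge_chunk_clusters",
    "predict_islets",
    "write_islet_bed",
    "islets_to_frame",
]


@dataclass
class GeometricModel:
    """Null model: per-base CpG probability p on one chromosome.

    p = n_cpg / effective_length, where the effective length excludes
    N bases (ambiguous runs carry no CpG information).
    """

    chrom: str
    p: float
    effective_length: int
    n_cpg: int


@dataclass
class CandidateCluster:
    chrom: str
    cpg_positions: np.ndarray  # sorted member positions
    start: int = field(init=False)
    end: int = field(init=False)  # last CpG position + 2 (half-open)
    n: int = field(init=False)
    gaps: np.ndarray = field(init=False)  # n-1 entries, each >= 1

    def __post_init__(self) -> None:
        self.cpg_positions = np.asarray(self.cpg_positions, dtype=np.int64)
        self.start = int(self.cpg_positions[0])
        self.end = int(self.cpg_positions[-1]) + 2
        self.n = int(self.cpg_positions.size)
        self.gaps = np.diff(self.cpg_positions) - 1


@dataclass
class IsletRecord:
    chrom: str
    start: int
    end: int
    cpg_positions: np.ndarray
    n: int
    p_value: float
    d: int
    features: FeatureVector | None = None


def fit_geometric_model(sites: CpGSiteList, chrom_seq: ChromosomeSequence) -> GeometricModel:
    """Estimate p = n_cpg / (length - N bases)."""
    n_cpg = len(sites)
    if n_cpg < 2:
        raise ComputeError(
            f"{sites.chrom}: need >= 2 CpG sites to fit a distance model (got {n_cpg})"
        )
    effective_length = chrom_seq.length - chrom_seq.n_count
    if effective_length <= 0:
        raise ComputeError(f"{sites.chrom}: effective length is zero")
    p = n_cpg / effective_length
    if not 0.0 < p < 1.0:
        raise ComputeError(f"{sites.chrom}: degenerate CpG probability p={p}")
    return GeometricModel(chrom=sites.chrom, p=p, effective_length=effective_length, n_cpg=n_cpg)


def geometric_pmf(d: int | np.ndarray, model: GeometricModel | float) -> float | np.ndarray:
    """P(d) = (1-p)^(d-1) * p, the null probability of inter-CpG distance d."""
    p = model.p if isinstance(model, GeometricModel) else float(model)
    d = np.asarray(d)
    if np.any(d < 1):
        raise ValueError("inter-CpG distance d must be >= 1")
    out = (1.0 - p) ** (d - 1) * p
    return float(out) if out.ndim == 0 else out


def _clusters_from_breaks(
    chrom: str, positions: np.ndarray, d: int, min_cpg: int
) -> list[CandidateCluster]:
    if positions.size == 0:
        return []
    gaps = np.diff(positions) - 1
    runs = np.split(positions, np.flatnonzero(gaps > d) + 1)
    return [CandidateCluster(chrom=chrom, cpg_positions=r) for r in runs if r.size >= min_cpg]


def cluster_sites(sites: CpGSiteList, d: int, min_cpg: int = 2) -> list[CandidateCluster]:
    """Maximal runs of CpGs with all successive gaps <= d, keeping runs of
    at least ``min_cpg`` sites. Clusters are disjoint and ordered by start."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return _clusters_from_breaks(sites.chrom, sites.positions, d, min_cpg)


def cluster_pvalue(cluster: CandidateCluster, model: GeometricModel) -> float:
    """Left tail of the null distribution of the cluster's total gap sum.

    The sum S of k = n-1 i.i.d. geometric gaps (support >= 1) satisfies
    S - k ~ NegativeBinomial(k, p), so
    P(S <= g) = nbinom.cdf(g - k, k, p). For n = 2 this is the geometric
    CDF 1 - (1-p)^g. Tighter clusters (smaller g at fixed n) get smaller
    p-values.
    """
    if cluster.n < 2:
        raise ValueError("cluster p-value requires n >= 2 (at least one gap)")
    k = cluster.n - 1
    g = int(cluster.gaps.sum())
    return float(stats.nbinom.cdf(g - k, k, model.p))


def merge_chunk_clusters(
    left: Sequence[CandidateCluster],
    right: Sequence[CandidateCluster],
    overlap_interval: tuple[int, int],
    d: int,
) -> list[CandidateCluster]:
    """Merge cluster lists from two adjacent overlapping chunks.

    Clusters duplicated inside the overlap are deduplicated (their member
    sites coincide) and boundary-spanning runs are re-stitched whenever
    two clusters share sites or their inter-cluster gap is <= d. With
    overlap >= d + 2 the result equals clustering the union site list in
    one pass.
    """
    clusters = sorted(list(left) + list(right), key=lambda c: (c.start, c.end))
    chroms = {c.chrom for c in clusters}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge clusters from different chromosomes: {sorted(chroms)}")
    if not clusters:
        return []
    merged: list[CandidateCluster] = []
    current = clusters[0].cpg_positions
    chrom = clusters[0].chrom
    for nxt in clusters[1:]:
        pos = nxt.cpg_positions
        if pos[0] <= current[-1] or (pos[0] - current[-1] - 1) <= d:
            current = np.union1d(current, pos)
        else:
            merged.append(CandidateCluster(chrom=chrom, cpg_positions=current))
            current = pos
    merged.append(CandidateCluster(chrom=chrom, cpg_positions=current))
    return merged


def _chunk_site_lists(
    sites: CpGSiteList, intervals: Sequence[tuple[int, int]]
) -> list[np.ndarray]:
    """Sites whose CG dinucleotide lies fully inside each chunk interval."""
    pos = sites.positions
    return [pos[(pos >= s) & (pos + 2 <= e)] for s, e in intervals]


def _cluster_chromosome(
    sites: CpGSiteList,
    chrom_seq: ChromosomeSequence,
    d: int,
    min_cpg: int,
    chunk_size: int,
    workers: int,
    d_max: int,
) -> list[CandidateCluster]:
    """Cluster one chromosome, chunked if it exceeds chunk_size."""
    if chrom_seq.length <= chunk_size:
        return cluster_sites(sites, d, min_cpg)
    plan = plan_chunks(chrom_seq, chunk_size, d_max)
    intervals = plan.chunk_intervals(chrom_seq.length)
    chunk_positions = _chunk_site_lists(sites, intervals)

    def _run(pos: np.ndarray) -> list[CandidateCluster]:
        # min_cpg deferred to after the merge so boundary singletons can re-join
        return _clusters_from_breaks(sites.chrom, pos, d, min_cpg=1)

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            chunk_clusters = list(ex.map(_run, chunk_positions))
    else:
        chunk_clusters = [_run(pos) for pos in chunk_positions]

    acc = chunk_clusters[0]
    for i in range(1, len(chunk_clusters)):
        ov = (intervals[i][0], intervals[i - 1][1])
        acc = merge_chunk_clusters(acc, chunk_clusters[i], ov, d)
    return [c for c in acc if c.n >= min_cpg]


def predict_islets(
    genome: Iterable[ChromosomeSequence],
    d_values: Sequence[int],
    alpha: float = 1e-5,
    workers: int = 1,
    min_cpg: int = 2,
    chunk_size: int = 10_000_000,
    bh_correct: bool = False,
    attach_features: bool = True,
) -> dict[int, list[IsletRecord]]:
    """Predict position-defined CGIs for each interval d over a genome.

    Per chromosome: fit the geometric null model, cluster at each d,
    compute cluster p-values, keep p <= alpha (optionally after
    Benjamini-Hochberg adjustment across each chromosome/d pass) and
    attach sequence features. Output is identical for any ``workers``.
    """
    if not d_values:
        raise ConfigurationError("d_values must be nonempty")
    if any(d < 1 for d in d_values):
        raise ConfigurationError("every d must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    d_max = max(d_values)
    if chunk_size <= 2 * (d_max + 2):
        raise ConfigurationError(
            f"chunk_size={chunk_size} incompatible with d_max={d_max}: "
            f"must exceed {2 * (d_max + 2)}"
        )
    results: dict[int, list[IsletRecord]] = {d: [] for d in d_values}
    for chrom_seq in genome:
        sites = extract_cpg_sites(chrom_seq)
        if len(sites) < 2:
            continue
        model = fit_geometric_model(sites, chrom_seq)
        for d in d_values:
            clusters = _cluster_chromosome(
                sites, chrom_seq, d, min_cpg, chunk_size, workers, d_max
            )
            if not clusters:
                continue
            pvals = np.array([cluster_pvalue(c, model) for c in clusters])
            keep = (
                stats.false_discovery_control(pvals) <= alpha
                if bh_correct
                else pvals <= alpha
            )
            for c, pv, k in zip(clusters, pvals, keep):
                if not k:
                    continue
                feats = (
                    compute_features((c.start, c.end), chrom_seq)
                    if attach_features
                    else None
                )
                results[d].append(
                    IsletRecord(
                        chrom=c.chrom,
                        start=c.start,
                        end=c.end,
                        cpg_positions=c.cpg_positions,
                        n=c.n,
                        p_value=float(pv),
                        d=d,
                        features=feats,
                    )
                )
    return results


def _bed_score(p_value: float) -> int:
    if p_value <= 0.0:
        return 1000
    return min(1000, round(-10.0 * math.log10(p_value)))


def write_islet_bed(islets: Sequence[IsletRecord], d: int, path) -> None:
    """BED6+4: chrom start end name score strand n_cpg p_value d."""
    with open(path, "w") as fh:
        for i, isl in enumerate(sorted(islets, key=lambda r: (r.chrom, r.start)), start=1):
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tislet_d{d}_{i:05d}\t"
                f"{_bed_score(isl.p_value)}\t.\t{isl.n}\t{isl.p_value:.6g}\t{d}\n"
            )


def islets_to_frame(islets: Sequence[IsletRecord]):
    """Feature table (one row per islet) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for isl in sorted(islets, key=lambda r: (r.chrom, r.start)):
        row = {
            "chrom": isl.chrom,
            "start": isl.start,
            "end": isl.end,
            "n_cpg": isl.n,
            "p_value": isl.p_value,
            "d": isl.d,
        }
        if isl.features is not None:
            fv = isl.features
            row.update(
                length_bp=fv.length_bp,
                gc_content=fv.gc_content,
                oe_ratio=np.nan if fv.oe_ratio is None else fv.oe_ratio,
                cpg_density=fv.cpg_density,
                cpg_num=fv.cpg_num,
                c_num=fv.c_num,
                g_num=fv.g_num,
            )
        rows.append(row)
    return pd.DataFrame(rows)
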