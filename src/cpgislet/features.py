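"""Per-island sequence features and proportion-distribution summaries.

For an island of length N with CpGNum CpG dinucleotides, CNum C's and
GNum G's:

    O/E ratio   = CpGNum / (CNum * GNum) * N
    CpG density = CpGNum / N
    GC content  = (CNum + GNum) / N

The O/E ratio is reported as missing (None / NaN) when CNum * GNum == 0,
never as infinity. Island intervals are 0-based half-open with
end = last CpG position + 2, so the minimal island "CG" has N = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ComputeError
from .sequence import ChromosomeSequence

__all__ = [
    "FeatureVector",
    "ProportionDistribution",
    "compute_features",
    "summarize_features",
    "islet_fraction_below",
    "DEFAULT_BINS",
]

#: Default bin edges for the proportion-distribution summaries. The source
#: figures print no boundaries, so these are explicit, configurable
#: placeholders (flagged as such in output metadata).
DEFAULT_BINS: dict[str, list[float]] = {
    "length_bp": [0, 50, 100, 150, 200, 300, 500, 1000, math.inf],
    "gc_content": [0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "oe_ratio": [0, 0.6, 0.8, 1.0, 1.2, 1.5, 2.0, math.inf],
}


@dataclass
class FeatureVector:
    length_bp: int
    cpg_num: int
    c_num: int
    g_num: int
    gc_content: float
    oe_ratio: float | None  # None when c_num * g_num == 0
    cpg_density: float


@dataclass
class ProportionDistribution:
    feature: str
    bin_edges: list[float]
    proportions: list[float]  # one per bin, sums to 1 over non-missing values
    n_total: int
    n_missing: int = 0


def compute_features(
    island_interval: tuple[int, int], chrom_seq: ChromosomeSequence
) -> FeatureVector:
    """Counts and derived features from an island's subsequence."""
    start, end = island_interval
    if not (0 <= start < end <= chrom_seq.length):
        raise ValueError(
            f"interval [{start},{end}) outside chromosome {chrom_seq.name} "
            f"of length {chrom_seq.length}"
        )
    if end - start < 2:
        raise ValueError("island must be at least 2 bp")
    sub = chrom_seq.seq[start:end]
    n = len(sub)
    c_num = sub.count("C")
    g_num = sub.count("G")
    cpg_num = sub.count("CG")
    gc = (c_num + g_num) / n
    oe = cpg_num / (c_num * g_num) * n if c_num * g_num > 0 else None
    return FeatureVector(
        length_bp=n,
        cpg_num=cpg_num,
        c_num=c_num,
        g_num=g_num,
        gc_content=gc,
        oe_ratio=oe,
        cpg_density=cpg_num / n,
    )


def _feature_values(islets: Iterable, feature: str) -> list[float]:
    out = []
    for isl in islets:
        fv = getattr(isl, "features", None) or isl
        out.append(getattr(fv, feature))
    return out


def summarize_features(
    islets: Sequence, feature: str, bin_edges: Sequence[float] | None = None
) -> ProportionDistribution:
    """Histogram of one feature over islands, normalized to proportions.

    Values below the first / above the last edge are assigned to the
    first / last bin (open-ended). Missing values (undefined O/E) are
    skipped and counted in ``n_missing``.
    """
    if len(islets) == 0:
        raise ComputeError("cannot summarize an empty islet list")
    edges = list(bin_edges if bin_edges is not None else DEFAULT_BINS[feature])
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    values = _feature_values(islets, feature)
    clean = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    n_missing = len(values) - clean.size
    clipped = np.clip(clean, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=np.asarray(edges, dtype=float))
    total = counts.sum()
    props = (counts / total).tolist() if total else [0.0] * len(counts)
    return ProportionDistribution(
        feature=feature,
        bin_edges=edges,
        proportions=props,
        n_total=len(values),
        n_missing=n_missing,
    )


def islet_fraction_below(islets: Sequence, threshold_bp: float) -> float:
    """Fraction of islands strictly shorter than ``threshold_bp``.

    Lengths below 200 bp mark the short, position-sensitive islands
    ("CpG islets") the predictor targets.
    """
    if len(islets) == 0:
        raise ComputeError("cannot compute a fraction over an empty islet list")
    lengths = _feature_values(islets, "length_bp")
    return sum(1 for v in lengths if v < threshold_bp) / len(lengths)
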