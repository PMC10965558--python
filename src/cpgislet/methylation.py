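"""Per-CpG methylation tracks: bedMethyl reading, level classification,
specificity summaries and genome-track slices.

Methylation levels follow the three-band definition on the per-site
methylation ratio r (fraction of reads reporting methylation):

    level 1 (highly methylated)  r > 0.75
    level 2 (unmethylated)       r < 0.1
    level 3 (moderate)           otherwise

Inequalities are strict: r = 0.75 and r = 0.1 both fall in level 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "MethylationRecord",
    "read_bedmethyl",
    "classify_level",
    "classify_levels",
    "level_specificity_table",
    "region_track",
    "mean_islet_methylation",
    "write_bedgraph",
]

_MIN_COLUMNS = 11  # ENCODE bedMethyl dialect: coverage = col 10, percent = col 11


@dataclass
class MethylationRecord:
    chrom: str
    position: int  # 0-based, C of the CpG (forward strand)
    methylation_ratio: float
    coverage: int
    tissue: str = ""


def read_bedmethyl(
    path,
    min_coverage: int = 4,
    merge_strands: bool = True,
    tissue: str = "",
) -> pd.DataFrame:
    """Read an ENCODE-dialect bedMethyl file into a DataFrame.

    Columns out: chrom, position, methylation_ratio, coverage, tissue.
    Percent methylation is converted to a fraction. Reverse-strand
    records are mapped to position-1 (the forward-strand C) and merged
    with the forward record by coverage-weighted average (disable with
    ``merge_strands=False``). Records with coverage < ``min_coverage``
    or zero coverage are dropped; percent outside [0, 100] is rejected
    with a warning. Short rows raise a parse error with the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < _MIN_COLUMNS:
                raise ParseError(
                    f"{path}: expected >= {_MIN_COLUMNS} bedMethyl columns, "
                    f"got {len(fields)} at line {lineno}"
                )
            chrom, start = fields[0], int(fields[1])
            strand = fields[5]
            coverage = int(fields[9])
            percent = float(fields[10])
            if not 0.0 <= percent <= 100.0:
                warnings.warn(
                    f"{path}: percent methylation {percent} outside [0,100] "
                    f"at line {lineno}; record rejected"
                )
                continue
            pos = start - 1 if (merge_strands and strand == "-") else start
            rows.append((chrom, pos, coverage, percent / 100.0))
    df = pd.DataFrame(rows, columns=["chrom", "position", "coverage", "methylation_ratio"])
    df = df[df["coverage"] > 0]
    if merge_strands and len(df):
        df["_w"] = df["coverage"] * df["methylation_ratio"]
        grouped = df.groupby(["chrom", "position"], as_index=False, sort=True).agg(
            coverage=("coverage", "sum"), _w=("_w", "sum")
        )
        grouped["methylation_ratio"] = grouped["_w"] / grouped["coverage"]
        df = grouped.drop(columns="_w")
    df = df[df["coverage"] >= min_coverage].reset_index(drop=True)
    df["tissue"] = tissue
    return df[["chrom", "position", "methylation_ratio", "coverage", "tissue"]]


def classify_level(ratio: float) -> int:
    """Map one methylation ratio to level 1, 2 or 3 (strict boundaries)."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"methylation ratio must be in [0, 1], got {ratio}")
    if ratio > 0.75:
        return 1
    if ratio < 0.1:
        return 2
    return 3


def classify_levels(ratios: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_level`; NaN ratios get level 0 (no level)."""
    ratios = np.asarray(ratios, dtype=float)
    out = np.full(ratios.shape, 3, dtype=np.int64)
    out[ratios > 0.75] = 1
    out[ratios < 0.1] = 2
    out[np.isnan(ratios)] = 0
    return out


def _positions_in_islets(islets: Sequence) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[np.ndarray]] = {}
    for isl in islets:
        by_chrom.setdefault(isl.chrom, []).append(np.asarray(isl.cpg_positions))
    return {c: np.unique(np.concatenate(v)) for c, v in by_chrom.items()}


def level_specificity_table(
    records: pd.DataFrame,
    assignments: Mapping[int, str] | Sequence,
    islets_by_d: Mapping[int, Sequence] | None = None,
) -> pd.DataFrame:
    """Counts and proportions of methylation levels per annotation
    category (and per CpG interval d when island sets are given).

    ``assignments`` maps site position -> category (a mapping, or a
    sequence of RegionAssignment). Proportions sum to 1 within each
    (d, category) group. Rows for d = 'all' cover every classified site;
    per-d rows cover sites inside that d's islands.
    """
    if not isinstance(assignments, Mapping):
        assignments = {a.position: a.category for a in assignments}
    df = records.copy()
    df["level"] = classify_levels(df["methylation_ratio"].to_numpy())
    df = df[df["level"] > 0]
    df["category"] = df["position"].map(assignments)
    df = df[df["category"].notna()]

    def _tab(sub: pd.DataFrame, d_label) -> list[dict]:
        rows = []
        for cat_name, grp in sub.groupby("category", sort=True):
            counts = grp["level"].value_counts().reindex([1, 2, 3], fill_value=0)
            total = int(counts.sum())
            for level in (1, 2, 3):
                rows.append(
                    {
                        "d": d_label,
                        "category": cat_name,
                        "level": level,
                        "count": int(counts[level]),
                        "proportion": counts[level] / total if total else np.nan,
                    }
                )
        return rows

    rows = _tab(df, "all")
    if islets_by_d:
        for d in sorted(islets_by_d):
            pos_by_chrom = _positions_in_islets(islets_by_d[d])
            mask = df.apply(
                lambda r: r["position"] in set(pos_by_chrom.get(r["chrom"], ())), axis=1
            ) if len(df) else pd.Series(dtype=bool)
            rows.extend(_tab(df[mask] if len(df) else df, d))
    return pd.DataFrame(rows)


def region_track(
    records: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    islets: Sequence = (),
    chrom_length: int | None = None,
) -> dict:
    """Genome-browser-style slice: ordered (position, ratio) pairs in
    [start, end) plus island interval overlays."""
    if start < 0 or (chrom_length is not None and end > chrom_length) or start >= end:
        raise ValueError(f"invalid interval [{start},{end}) on {chrom}")
    sub = records[
        (records["chrom"] == chrom)
        & (records["position"] >= start)
        & (records["position"] < end)
    ].sort_values("position")
    overlays = [
        (max(isl.start, start), min(isl.end, end))
        for isl in islets
        if isl.chrom == chrom and isl.start < end and isl.end > start
    ]
    return {
        "chrom": chrom,
        "interval": (start, end),
        "points": list(zip(sub["position"].tolist(), sub["methylation_ratio"].tolist())),
        "islets": overlays,
    }


def mean_islet_methylation(
    islets_by_d: Mapping[int, Sequence], records: pd.DataFrame
) -> pd.DataFrame:
    """Coverage-weighted mean methylation ratio per island, plus per-d
    distribution stats. Islands with no covered CpG get NaN and are
    excluded from the per-d mean (counted in n_missing)."""
    lookup: dict[tuple[str, int], tuple[float, int]] = {
        (r.chrom, int(r.position)): (float(r.methylation_ratio), int(r.coverage))
        for r in records.itertuples()
    }
    rows = []
    for d in sorted(islets_by_d):
        for isl in islets_by_d[d]:
            num = den = 0.0
            n_cov = 0
            for pos in np.asarray(isl.cpg_positions):
                hit = lookup.get((isl.chrom, int(pos)))
                if hit is not None:
                    num += hit[0] * hit[1]
                    den += hit[1]
                    n_cov += 1
            rows.append(
                {
                    "d": d,
                    "chrom": isl.chrom,
                    "start": isl.start,
                    "end": isl.end,
                    "mean_methylation": num / den if den else np.nan,
                    "covered_cpgs": n_cov,
                }
            )
    return pd.DataFrame(rows)


def write_bedgraph(records: pd.DataFrame, path) -> None:
    """Export per-CpG methylation ratios as a bedGraph track."""
    with open(path, "w") as fh:
        for r in records.sort_values(["chrom", "position"]).itertuples():
            fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.methylation_ratio:.4f}\n")
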