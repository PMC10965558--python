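"""Pipeline orchestration and report assembly.

The pipeline runs the three-stage workflow — islet prediction, genome
annotation, methylation analysis — from a validated RunConfig and writes
deterministic TSV/BED outputs plus the config itself into the output
directory (re-running an identical config reproduces identical bytes).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation, baselines, methylation, predict, sequence
from .errors import ConfigurationError, InputError

__all__ = ["RunConfig", "run_pipeline", "render_comparison_report"]


@dataclass
class RunConfig:
    fasta: str = ""
    gff: str | None = None
    bedmethyl: str | None = None
    outdir: str = "cpgislet_out"
    d_values: list[int] = field(default_factory=lambda: [12])
    alpha: float = 1e-5
    min_cpg: int = 2
    workers: int = 1
    chunk_size: int = 10_000_000
    bh_correct: bool = False
    promoter_up: int = 1000
    promoter_down: int = 500
    min_coverage: int = 4
    merge_strands: bool = True
    hi_oe: float = 0.75
    hi_gc: float = 0.55
    lo_oe: float = 0.48
    run_baselines: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.fasta:
            raise ConfigurationError("fasta input is required")
        if not os.path.exists(self.fasta):
            raise InputError(f"FASTA not found: {self.fasta}")
        for path, label in [(self.gff, "annotation"), (self.bedmethyl, "bedMethyl")]:
            if path is not None and not os.path.exists(path):
                raise InputError(f"{label} file not found: {path}")
        if not self.d_values or any(d < 1 for d in self.d_values):
            raise ConfigurationError(f"invalid d_values: {self.d_values}")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError(f"alpha out of range: {self.alpha}")
        if self.min_cpg < 2:
            raise ConfigurationError("min_cpg must be >= 2")
        if self.workers < 1:
            raise ConfigurationError("workers must be >= 1")
        if self.chunk_size <= 2 * (max(self.d_values) + 2):
            raise ConfigurationError(
                f"chunk_size {self.chunk_size} too small for d_max {max(self.d_values)}"
            )


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> str:
    """Execute prediction -> annotation -> methylation; returns outdir."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "run_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)

    genome = list(sequence.read_fasta(config.fasta))

    # stage 1: prediction + features
    islets_by_d = predict.predict_islets(
        genome,
        d_values=config.d_values,
        alpha=config.alpha,
        workers=config.workers,
        min_cpg=config.min_cpg,
        chunk_size=config.chunk_size,
        bh_correct=config.bh_correct,
    )
    for d, islets in islets_by_d.items():
        predict.write_islet_bed(islets, d, os.path.join(config.outdir, f"islets_d{d}.bed"))
        _write_tsv(
            predict.islets_to_frame(islets),
            os.path.join(config.outdir, f"islets_d{d}.features.tsv"),
        )

    method_results = []
    if config.run_baselines:
        for chrom_seq in genome:
            sites = sequence.extract_cpg_sites(chrom_seq)
            if len(sites) >= 2:
                method_results.append(
                    baselines.predict_cpgcluster_classic(sites, chrom_seq, alpha=config.alpha)
                )
            method_results.append(baselines.predict_density_defined(chrom_seq))

    # stage 2: annotation
    genes = None
    if config.gff:
        genes = annotation.parse_annotation(config.gff)
        all_sites = [
            (chrom_seq.name, sequence.extract_cpg_sites(chrom_seq)) for chrom_seq in genome
        ]
        assignments = []
        for _, sites in all_sites:
            assignments.extend(
                annotation.assign_regions(
                    sites.positions, genes, config.promoter_up, config.promoter_down
                )
            )
        tables = annotation.summarize_annotation(assignments, islets_by_d)
        for name, df in tables.items():
            _write_tsv(df, os.path.join(config.outdir, f"annotation_{name}.tsv"))
        th = annotation.DensityThresholds(config.hi_oe, config.hi_gc, config.lo_oe)
        for d, islets in islets_by_d.items():
            classes = [annotation.classify_density(i, th) for i in islets]
            _write_tsv(
                pd.DataFrame(
                    {
                        "subject": [c.subject_id for c in classes],
                        "density_class": [c.density_class or "unclassifiable" for c in classes],
                    }
                ),
                os.path.join(config.outdir, f"density_classes_d{d}.tsv"),
            )
            plus = sorted(annotation.call_cgi_plus_genes(islets, genes))
            with open(os.path.join(config.outdir, f"cgi_plus_genes_d{d}.txt"), "w") as fh:
                fh.write("\n".join(plus) + ("\n" if plus else ""))

    # stage 3: methylation
    if config.bedmethyl:
        records = methylation.read_bedmethyl(
            config.bedmethyl,
            min_coverage=config.min_coverage,
            merge_strands=config.merge_strands,
        )
        methylation.write_bedgraph(records, os.path.join(config.outdir, "methylation.bedGraph"))
        _write_tsv(
            methylation.mean_islet_methylation(islets_by_d, records),
            os.path.join(config.outdir, "islet_methylation.tsv"),
        )
        if config.gff and genes is not None:
            _write_tsv(
                methylation.level_specificity_table(records, assignments, islets_by_d),
                os.path.join(config.outdir, "level_specificity.tsv"),
            )
    elif config.bedmethyl is None:
        pass

    if method_results:
        table = baselines.compare_methods(method_results)
        _write_tsv(table, os.path.join(config.outdir, "baseline_comparison.tsv"))
    return config.outdir


def render_comparison_report(
    results: list, include_literature: bool = True
) -> pd.DataFrame:
    """Table-style method comparison: island count and mean +/- sd of
    length, GC, O/E and CpG density per method. Literature rows carry
    ``recomputed=False`` and the note "reported, not recomputed"."""
    table = baselines.compare_methods(results)
    table["note"] = ""
    if include_literature:
        lit = pd.DataFrame(baselines.LITERATURE_ROWS)
        lit["note"] = "reported, not recomputed"
        table = pd.concat([table, lit], ignore_index=True)
    return table


def format_report_markdown(table: pd.DataFrame) -> str:
    """Render the comparison table as Markdown (length to 1 decimal,
    GC as percent to 1 decimal, O/E and density to 2/3 decimals)."""
    lines = [
        "| Method | CGI number | Avg length ± sd | Avg GC ± sd | Avg O/E ± sd | Avg CpG density ± sd |",
        "|---|---|---|---|---|---|",
    ]
    for row in table.itertuples():
        def fmt(mean, sd, scale=1.0, nd=1, suffix=""):
            if mean is None or (isinstance(mean, float) and np.isnan(mean)):
                return "-"
            return f"{mean * scale:.{nd}f}{suffix} ± {sd * scale:.{nd}f}{suffix}"

        note = f" ({row.note})" if getattr(row, "note", "") else ""
        lines.append(
            f"| {row.method}{note} | {row.n_islands} | "
            f"{fmt(row.length_mean, row.length_sd)} | "
            f"{fmt(row.gc_mean, row.gc_sd, 100, 1, '%')} | "
            f"{fmt(row.oe_mean, row.oe_sd, 1, 2)} | "
            f"{fmt(row.density_mean, row.density_sd, 1, 3)} |"
        )
    return "\n".join(lines) + "\n"
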