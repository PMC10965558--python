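# Methods

## Model

CpG dinucleotides are recorded at the 0-based position of the C on the
forward strand; a CpG is its own reverse complement, so one record covers
both strands. For a chromosome's sorted sites x₁ < x₂ < … the inter-CpG
distance is dᵢ = xᵢ₊₁ − xᵢ − 1 (the open gap between the two C's; minimum 1
because sites are at least 2 bp apart). Clustering at interval d keeps
maximal runs whose successive distances are all ≤ d (inclusive comparison:
d is a *maximum allowed* interval) with at least `min_cpg` members
(default 2, the smallest unit that has a distance).

The null model treats distances as i.i.d. geometric with success
probability p, the chromosome's per-base CpG probability:
p = n_CpG / (chromosome length − N bases). N runs are excluded from the
denominator because they can never carry a CpG; soft-masked lowercase is
uppercased and treated as ordinary sequence (configurable at read time).
The pmf is P(d) = (1 − p)^(d−1) p, normalized over d ≥ 1.

A cluster of n CpGs has total gap sum S = Σ dᵢ over its n − 1 gaps. Under
the null, S − (n − 1) is negative binomial with n − 1 successes, so the
cluster p-value is the exact left tail

    p_value = nbinom.cdf(S − (n − 1), n − 1, p)

computed by scipy's stable CDF, not simulation. For n = 2 this reduces to
the geometric CDF 1 − (1 − p)^S, and it is strictly monotone in S at fixed
n: tighter clusters score smaller. Clusters with p_value ≤ α are reported;
α defaults to 10⁻⁵ and is deliberately configurable because no single
published cutoff exists for this family of methods. No multiple-testing
correction is applied by default; a Benjamini–Hochberg option
(`bh_correct`) adjusts within each chromosome × d pass. Because the gap
distribution is discrete, the attained level at any α is slightly below α
(the calibration tests compare against the exact attained level).

## Parallel chunking

Chromosomes longer than `chunk_size` (default 10 Mb) are tiled into chunks
overlapping by exactly d_max + 2 bases, where d_max is the largest interval
analyzed. Any pair of CpGs with gap ≤ d spans at most d + 2 bases, so every
adjacency is fully visible inside at least one chunk. Chunks are clustered
independently (thread pool; results collected in chunk order) **without**
the min_cpg filter, so boundary singletons survive to the merge; adjacent
chunk results are merged left-to-right by unioning clusters that share
sites or whose inter-cluster gap is ≤ d, after which min_cpg filtering and
p-values are applied. This makes the chunked result provably equal to
single-pass clustering, which is the testable content of the map/reduce
design: the equivalence is asserted byte-for-byte on BED output across
worker counts, and against a single-pass oracle on randomized site lists.
Distributed (Hadoop-style) execution is out of scope; the in-process pool
honors the same split/merge contract.

## Island features and comparison baselines

Island intervals are half-open with end = last CpG position + 2, so the
minimal island "CG" has length 2 and all counts (CpGNum, CNum, GNum) are
taken from the island's own subsequence. O/E = CpGNum/(CNum·GNum)·N is
reported as missing — never 0 or ∞ — when CNum·GNum = 0; summaries skip
missing values and report how many were skipped. Distribution summaries
(length, GC, O/E) use configurable bin edges; the defaults are explicit
placeholders because no canonical binning exists, and out-of-range values
fall into the open end bins.

Two baselines are re-implemented on the shared core. The classical
distance-clustering baseline sets d per chromosome to the median inter-CpG
distance (even counts take the lower middle value; the result is floored
to an integer) and then runs the identical cluster → p-value pipeline. The
density-defined baseline slides a 200 bp window by 1 bp, keeps windows
with GC ≥ 0.50 and O/E ≥ 0.6, merges overlapping/touching windows, and
retains merged regions that are ≥ 200 bp and still pass both thresholds at
the region level (Gardiner-Garden-style criteria; all five parameters
configurable). Comparison tables report count and mean ± population sd
(ddof = 0) of length, GC, O/E and density per method; rows for methods not
re-implemented are static literature values flagged "reported, not
recomputed".

## Annotation

GFF3/GTF is parsed with gffutils into gene models (1-based closed
converted to 0-based half-open; TSS = transcript start on +, transcript
end − 1 on −). Sites are assigned to exactly one category with precedence
core promoter > exon > intron > gene body (other) > intergenic. The core
promoter window is TSS − 1000 / TSS + 500 oriented by strand — a
conventional choice, configurable and recorded in outputs, since "core
promoter" has no universal coordinates. Ties between overlapping genes go
to the nearest TSS, then the lexicographically smallest gene id —
determinism over biological nuance. CGI+ genes are protein-coding genes
with at least one TSS strictly inside an island under the half-open
convention (a TSS at the island end is outside). Density classes use
promoter-class style thresholds: HCGI if O/E ≥ 0.75 and GC ≥ 0.55, LCGI if
O/E < 0.48, else ICGI; islands with undefined O/E are reported as
unclassifiable rather than forced into a class. These thresholds are a
recognized convention, not a measured property of this package —
reproduction runs should treat them as tunable.

## Methylation

bedMethyl input must carry the 11-column ENCODE dialect (coverage in
column 10, percent methylated in column 11); shorter rows are a parse
error with the line number, and percents outside [0, 100] reject the
record with a warning. Reverse-strand records are mapped to the
forward-strand C (position − 1) and merged by coverage-weighted average
(can be disabled); records below the minimum coverage (default 4 reads,
reported in output metadata) are dropped, and zero-coverage sites never
receive a level. Level classification uses strict inequalities — ratios
exactly 0.75 or 0.1 are moderate (level 3) — with no rounding before
comparison, so the three bands partition [0, 1] exactly. Island
methylation is the coverage-weighted mean over covered member CpGs;
islands with no covered CpG are reported missing and counted, not
silently dropped. Tissues are analyzed independently; nothing averages
across samples by default.

## Synthetic data

The generator *is* the null model plus planted signal: background sites
are placed with i.i.d. geometric(background_p) gaps (default scenarios use
background_p = 0.01, roughly the genome-wide CpG rate), planted clusters
overwrite the background at fixed coordinates with n sites at gaps drawn
uniformly in [1, gap_max], and filler bases are drawn at a configurable GC
fraction (default 0.40, the human genome-wide value) then scrubbed so no
accidental CG survives — the extracted site list equals the recorded truth
exactly. Methylation tracks draw a level per site from stated
probabilities (default (0.5, 0.3, 0.2) for highly/un/moderately
methylated) and a ratio uniform within the level's band; gene models are
laid out in non-overlapping slots and round-trip through the parser.

What a green test therefore establishes: the predictor recovers clusters
generated by its own assumed model, the p-values are calibrated against
that model, and the pipeline is deterministic and parallel-safe. What it
does not establish: behavior on real genomes, where CpG spacing is not
geometric (methylation-driven CpG decay, isochores, repeats), GC varies
regionally, and annotation is far denser — genome-scale counts on a real
assembly require the real FASTA/GFF inputs and a parameter sweep over α
and min_cpg, because the published parameterization of this method family
is under-specified.

## Numerical choices and limitations

- p-values use the exact negative-binomial CDF; no continuity or Monte
  Carlo approximation anywhere in the scoring path.
- Cluster emission order is (chrom, start); BED scores are
  round(−10·log₁₀ p) capped at 1000 with p = 0 mapped to 1000.
- The interval index used for region assignment is a sorted-starts scan
  with bounded back-scan — adequate for gene-scale interval sets; a
  dedicated interval tree would be preferable for extremely dense
  annotations.
- The level-specificity table restricts per-d rows to CpGs inside that d's
  islands; the "all" rows cover every classified site.
- Expression-breadth (tissue-specific gene) labels are consumed from an
  optional user table and are not computed here.
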