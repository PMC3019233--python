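# Methods

This note documents the models, defaults, and design choices behind
`bccluster`, and what the simulator-based validation does and does not
demonstrate.

## Broken-read graph and biconnectivity

Contigs are nodes; an edge joins two contigs whenever at least one base
read name (recovered from split-read identifiers) has placements in
both.  Edge weight is the number of *distinct* base names, and parallel
broken reads between one pair collapse into a single weighted edge for
connectivity purposes.  This collapse matters: if each broken read were
its own edge, any two contigs sharing two reads would count as
"biconnected", defeating the requirement that a bi-connected component
(BCC) comprise three or more contigs linked by independent evidence.

Two biconnectivity semantics are provided.  The default, `mode="edge"`,
is the literal reading of "not split if any one edge is removed":
maximal 2-edge-connected subgraphs, computed by deleting bridges and
taking the surviving components.  `mode="vertex"` gives the classical
articulation-point blocks that most graph libraries (and probably most
historical scripts) compute.  The two differ only on graphs where blocks
share a cut vertex; both are validated in the test suite against a
brute-force oracle that deletes each edge in turn and checks
connectivity.  Only components with ≥ 3 nodes are reported, and reported
connected components require ≥ 2 nodes (an isolated contig carries no
broken-read evidence).

The minimum edge multiplicity is exposed (`min_multiplicity`, default 1)
because observed per-edge counts on real data run far above 1; the
default keeps every edge and lets the user tighten it.

### Split-read naming

Assembler suffix conventions for split reads are not standardized.  The
default pattern strips a trailing `.<int>-<int>` (sub-range style) or
`_part<int>`; it is a guess at the common dialects and is configurable
everywhere (`--name-pattern`).  A non-matching name is treated as
unsplit.

## Pair and BCC classification

Pairs are aligned with exact affine-gap local alignment
(`Bio.Align.PairwiseAligner`; match +1, mismatch −2, gap open 5, gap
extend 2, a length-k gap costing 5 + 2k).  Both strands are tried and
the better kept.  Identity is counted over *all* aligned columns,
including gap columns, so indels dilute identity rather than being
ignored.  Significance uses the ungapped Karlin–Altschul form
`E = K·m·n·exp(−λS)` with K = 0.46, λ = 1.28 over search space m·n —
deliberately simple, since the decision only consumes a single threshold
(E < 10⁻⁵) and the scoring defaults approximate standard nucleotide
BLAST behaviour.  All parameters are configurable.

The allelic criterion ("a ≥ 50 bp block of ≥ 95% identity flanked by at
most 10 nt of lower identity, single-stranded overhangs of any length
permitted") is operationalized on the best local alignment's boundaries:
at each end, either at most one sequence has unaligned residue (an
overhang), or both unaligned tails are ≤ 10 nt.  The optimal local
alignment boundary is exactly where extending at < 95% identity stops
paying, so the unaligned-tail rule realizes the contiguous-low-identity
phrasing in a decidable form.

Within a BCC, allelic pairs are unioned (union–find) into merged groups
first; the component verdict is then taken over inter-group pairs: all
`alt_splice` → `alternative_splicing`; any `duplicated` → `duplicated`;
a single merged group → `allelic`.  Allelic merging picks mismatched
bases from the higher-coverage contig (ties break to the
lexicographically smaller contig id) and appends overhangs — the
merging rule itself is not specified anywhere authoritative, so the
package states its own, auditable rule.

A note on identity bands: descriptions of duplicates as "85–95%
similarity" and splice variants as "< 85%" are summaries, not the
operative criteria; the E-value cascade above is what the code applies,
and the bands are only used by the simulator to place paralog families
in a regime the cascade separates cleanly.

## Variant calling

### Re-alignment

Pyrosequencing's dominant error is an over- or under-call of a
homopolymer run length, which appears as a gap column in the
read-versus-consensus alignment.  Before building the multiple
alignment, each pairwise alignment is scrubbed: a gap column whose
opposite base lies in a run of ≥ 3 identical bases (configurable
`min_run`) is removed.  Insertion columns (consensus-side pads) are
deleted outright; deletion columns are *masked* rather than deleted so
the consensus coordinate walk stays intact — the read simply contributes
no observation there.  The run threshold of 3 is the standard 454-error
heuristic; nothing in the pipeline is sensitive to it except the
definition of "homopolymer context" itself, and the variant filter uses
the same threshold for consistency.

The MSA is keyed by `(consensus position, insertion rank)`.  Reads that
span an insertion locus without carrying the insertion are recorded
there as `-`, so insertion columns see full spanning coverage — without
this, an insertion carried by k reads would appear unanimous.

### The posterior

Historical pipelines obtained their per-site "probability" from an
external Bayesian caller whose model is not documented, so the
package substitutes a fully documented two-hypothesis posterior with the
same interface (a per-site probability thresholded at 0.9).  Per column,
with k₁ copies of the majority allele, k₂ of the runner-up, k₀ others,
error rate ε and site prior π:

* monomorphic: `L0 = (1−ε)^k1 (ε/3)^(k2+k0)`
* biallelic, pooled allele frequency integrated over a uniform Beta
  prior: `L1 = B(k1+1, k2+1) (1−ε)^(k1+k2) (ε/3)^k0`
* `P = π L1 / (π L1 + (1−π) L0)`, computed in log space.

Defaults ε = 0.01 (typical cleaned 454 accuracy) and π = 0.005 (near
the per-bp SNP rate observed in pooled EST data).  At coverage 20 the
0.9 threshold sits between k₂ = 3 (P ≈ 0.85) and k₂ = 4 (P ≈ 0.997),
which is what makes the minor-fraction-0.2 calibration work.

Adjacent single-column deletion calls are merged into one deletion call
(probability = max over the merged columns), since downstream summaries
count indel *sites*, not columns.  Coverage bounds are applied
per-variant-call.

### Filters

Defaults: coverage in [5, 100] (below: too little evidence; above:
likely collapsed repeats), probability ≥ 0.9, and indel calls flagged as
homopolymer-context are dropped while SNPs in the same context are kept.
Each rejected call is attributed to the first failing rule in that
order, and the report carries per-reason counts.

## Residual variation statistics

The per-contig variant count is regressed by OLS on log₁₀ length and
log₁₀ read count, with intercept; the residual is the power-corrected
variation estimate.  The response is the raw count by default (a
`log_response` option fits log1p(count) instead) — the choice follows
the convention of reporting total detected variants per contig, and the
ambiguity is noted rather than hidden.  Per-term F statistics are the
partial F with one numerator degree of freedom (t²).  Rank-deficient
designs raise immediately rather than producing silently unstable
estimates.

Array constructs matching several contigs receive the arithmetic mean
residual; constructs matching none are dropped.  The expression model
regresses unit residuals on overall expression level, number of tissues
(0–4), morph-biased and sex-biased expression.  Since the coefficient
scale depends on the (unavailable) original response units, only the
model *structure*, signs and calibration are validated — parameter
recovery on synthetic data with known slopes, and a type-I error rate in
[0.02, 0.09] over null replicates.

Extreme sets take floor(fraction·n) units from each tail (default 5%),
with boundary ties broken by unit id so results are reproducible.
Enrichment uses the one-sided (enrichment) Fisher exact test by default
— "most variable" and "least variable" sets are directional questions —
with a two-sided option, and Benjamini–Hochberg correction across tested
terms.  No annotation-graph propagation is performed; terms are taken as
given.

## The simulator

The simulator emits post-assembly state directly instead of running an
assembler: contigs, padded consensus, gapped read placements and split
"broken reads" are constructed from ground truth via exact edit-script
(CIGAR-style) coordinate maps, so every placement is consistent by
construction and the ACE output round-trips bit-identically.  All
randomness flows from one integer seed.

Study conditions (defaults): per-base allele divergence 0.0057 SNP/bp
and 0.002 indel/bp — the observed pooled rates in large 454 EST data;
duplicate families at 85–95% identity (the band separating paralogs from
alleles); cassette-exon genes whose two isoforms fragment into the
three-contig triangle; read lengths truncated-normal with mean 440 nt,
sd 60 nt; per-source coverage 20×.  Planted allelic indels avoid
homopolymer context so that genuine indels and pyrosequencing errors
remain separable — a deliberate idealization.

Gene categories map to expected BCC verdicts: `allelic_triple` (two
alleles plus a chimeric contig) → allelic; `paralog_triple` → duplicated;
`cassette` → alternative_splicing; plain `allelic_pair` genes yield
two-contig components.  With `collapse_alleles` both alleles' reads are
placed in one contig, producing a pooled mixed-allele column structure
for variant-calling tests.  Homopolymer error mode duplicates or drops
one base adjacent to runs ≥ 3 at a configurable per-position rate.

What the simulator does *not* model — and hence what passing tests do
not show: flowgram-level 454 noise and quality values, chimeric reads,
normalization-library bias, assembler-specific consensus artifacts, and
paralog divergence by indels (paralogs differ by substitutions only, so
paralog coordinate maps stay trivial).  Classification accuracy on real
data with intermediate identity bands (93–97%) will be worse than the
simulated 98–99.5 / 85–92 / no-overlap regime, which is intentionally
well-separated to validate machinery rather than to estimate real-world
error rates.

## Problem sizes and numerics

The validation suite uses 500 simulated BCCs for verdict recovery,
2,000 planted SNP columns at coverage 20 for caller calibration, 700
random graphs against the biconnectivity oracle, n = 500 contigs /
n = 1,500 units for regression recovery and 200 null replicates for
type-I calibration — sizes chosen so the full suite runs in well under a
minute per component while keeping Monte-Carlo noise far from the
asserted margins.  The posterior is computed with `lgamma` in log space
and saturates to 1.0 in double precision around k₂ ≈ 12 at coverage 40;
monotonicity assertions treat the saturated region as ties.  OLS degenerate
designs are detected by explicit rank checks, not by catching solver
warnings.
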