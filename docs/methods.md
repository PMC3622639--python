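# Methods

## Model and assumptions

The assembler treats transcript reconstruction as three decoupled
problems — local exon inference, splice-graph construction, and global
isoform selection — and deliberately does not estimate transcript
abundance.

**Exon inference.** The driving assumption is that read coverage is
*locally* uniform: within one gene region, each exon contributes a
roughly constant number of reads per base, so interval coverage profiles
are near-additive superpositions of per-exon coverages. The LP's slack
variables absorb departures from additivity (coverage of stacked
subexons vs. the interval mean) and continuity (adjacent subexons of one
exon), and the objective — total slack — measures how badly an exon
combination explains the profile. Conservation is a hard equality: total
subexon coverage mass must equal total observed mass. With the default
lower bound c_{i,j} ≥ 1 this can be infeasible in low-coverage regions;
the solve is retried once with bound 0 before the combination is
discarded. Coverages and the pair penalty live on different scales
(reads-per-base vs. a proportion); they are summed as-is, with an
optional normalisation of the LP objective by mean region coverage
available behind `RunConfig` for users who want scale-free scores.

**Feasibility.** A combination must (1) place every splice site on an
exon boundary, (2) contain every unspliced read inside an exon and every
spliced read's blocks inside exons pinned to its junction boundaries, and
(3) join each pair's inner endpoints by identical or non-overlapping
exons. Region edges are not treated as splice sites for condition (1):
they are coverage limits, not biochemically defined boundaries. Reads
whose junctions fail the support/anchor filters are excluded from the
requirements so that a single artifact read cannot render a whole region
infeasible; if a region still has no feasible combination it is emitted
as one whole-region exon with a warning.

**Enumeration caps.** Subset enumeration is exponential, so regions with
more than `max_candidates` (default 16) candidate exons fall back to a
restricted pool: exons directly pinned by spliced-read blocks, tightest
containing exons for terminal blocks, minimal completions covering each
splice site, and the whole-region exon. The downgrade is logged. Maximal
path enumeration per component is capped at `max_paths` (default 1000),
exploring highest-support edges first so retained paths favour
well-supported splice structures.

**Selection.** Constraints deduplicate reads into (interval set,
junction chain, fragment class) triples; multiplicity is recorded but
does not weight the cover objective, which counts each distinct
constraint once. Satisfaction requires exact junction agreement over
the read footprint — a transcript with an extra intron under a
contiguously covered stretch fails. Pair fragment checks use the
f_l ± 2f_σ window with interval-level position flexibility (the
min/max implied fragment over all placements of the mates inside their
recorded intervals), consistent with class-level deduplication. The
weighted greedy rule is cost-effectiveness (weight per newly covered
constraint), the standard greedy for weighted set cover; with equal
weights it reduces exactly to the unweighted rule, and ties break by
smaller weight, longer intron chain, then lexicographic coordinates, so
selection is fully deterministic. λ defaults to 1 (weights in [1, 2]);
the additive 1 keeps fully annotated transcripts from having zero cost,
which would degenerate the ratio rule. Intronless transcripts get
weight 1: the intron-pair measure is undefined for them and penalising
would bias against short genes.

## Tunable parameters

| Parameter | Default | Units | Role |
| --- | --- | --- | --- |
| `min_mapq` | 0 | — | drop low-quality alignments |
| `max_gap` | 0 | nt | zero-coverage gap bridged inside a region |
| `min_region_len` | 25 | nt | noise-island threshold |
| `min_junction_support` | 1 | reads | junction filter |
| `min_anchor` | 8 | nt | shortest flanking block for a junction |
| `frag_len`, `frag_sd` | estimated | nt | fragment distribution override |
| `lp_lower_bound` | 1 | reads/base | minimum subexon coverage |
| `max_candidates` | 16 | exons | subset-enumeration cap per region |
| `max_paths` | 1000 | paths | per-component path cap |
| `evidence_lambda` | 1 | — | annotation weight strength |

Junction and region thresholds are permissive because the reference
data for this package are clean simulations; on real alignments users
should raise `min_junction_support` and consider `min_mapq ≥ 10`.

## Fragment length estimation

The estimator uses pairs whose mates are both unspliced and fall inside
a single covered region, measuring (right end − left start), with a 5%
two-sided trim against chimeric pairs. The trimmed standard deviation is
rescaled by the standard deviation of a correspondingly truncated normal
so it is consistent on clean Gaussian libraries while staying robust.
Two caveats: only fragments shorter than their harbouring exon are
observable, so on genes with exons shorter than the fragment length the
estimate is biased low; and the bias narrows the ± 2σ feasibility
window, which can prune genuine pair constraints. When the library's
fragment parameters are known (as they are for simulated data) they
should be passed explicitly — the benchmark scripts do so.

## The synthetic data generator

`make_gene_models` places non-overlapping multi-exon genes (default 4–8
exons of 100–300 nt, introns 200–800 nt, 2 kb spacing) on a toy contig
and derives 1–3 isoforms per gene by skipped exons, alternative
donors/acceptors, and alternative first/last exons.
`simulate_alignments` draws fragments uniformly along each isoform in
proportion to its weight, with truncated-Gaussian lengths (default
250 ± 25 nt), projects 75 nt reads through the exon map into gapped
CIGAR alignments, and writes sorted SAM plus a truth GTF; everything is
deterministic given the seed.

Two generator design choices matter for interpreting results. First,
each gene's isoform diversity is concentrated at a single focal
alternative site (one internal exon, or one terminus), and a donor
variant and an acceptor variant are never placed on the same exon: a
gene carrying both admits a chimeric exon (alternative start ×
alternative end) whose coverage decomposition is exactly as good as the
truth's and smaller — the configuration is unidentifiable from coverage,
and no coverage-based method can resolve it. Concentrated variation
mirrors the common biological case of a single alternative splicing
event per gene and keeps every isoform identifiable: each carries at
least one private read constraint at realistic fragment lengths.
Second, the generator has no error model, no multi-mapping and no
intronic background. Passing tests therefore demonstrate the
correctness of the algorithmic chain — region detection, LP scoring,
path enumeration, constraint satisfaction, cover selection — under the
stated coverage model, not robustness to alignment artifacts,
positional bias, or overlapping genes, all of which real libraries
exhibit.

## Numerical choices

LPs are solved with HiGHS through scipy; objective ties between exon
combinations are compared after rounding to 9 decimals to make the
fewest-exons tie-break immune to solver noise. The LP slack granularity
is one ε per additivity constraint and one per continuity constraint —
finer than one shared slack per exon, and reducing to it when the slacks
agree. All coordinates are 0-based half-open internally; GTF conversion
happens only at I/O boundaries. Degenerate inputs are defined: an empty
SAM body yields an empty region list and an empty (valid) GTF; a region
with no feasible combination becomes a single exon; an empty prediction
set evaluates with precision 0 and a warning.

## Benchmark problem sizes

The test suite and acceptance script use 20 genes (~35–45 isoforms,
~16,000 reads) at depth 50 for end-to-end checks, 200 random instances
for each optimisation-core oracle comparison (LP vertex-enumeration
oracle on ≤ 6-variable systems; exhaustive minimum set cover on ≤ 10
transcripts × ≤ 12 constraints; brute-force path counts on ≤ 8-node
DAGs), chosen so the whole suite completes in seconds on one CPU while
exercising every stage.

## Known limitations

- No abundance estimation; downstream quantifiers should be used.
- Coverage-unidentifiable configurations (see generator notes) are
  resolved by parsimony and may merge or fabricate isoforms.
- Greedy set cover under-predicts when an isoform's constraints are a
  subset of the union of other selected isoforms' constraints.
- The fragment estimator's observability bias on short-exon genes.
- Overlapping genes on the same strand are merged into one region and
  one gene cluster.
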