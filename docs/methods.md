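# Methods

This note documents the models, conventions and numerical choices
behind `pksminer`, and what the synthetic benchmarks do and do not
establish about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open on the plus strand.
External dialects are converted once, at the I/O boundary: BLAST
tabular subject coordinates (1-based inclusive, reversed on the minus
strand), domain-table amino-acid coordinates (1-based inclusive), and
GenBank features. Minus-strand similarity hits are retained and mapped
to plus-strand intervals. Dates are ISO-8601; a bare year is read as
July 1 of that year so that year-resolution records fall mid-year in
the discovery time series.

## KS mining

`scan_ks` emulates a translated search: the record is translated in all
six frames and each frame is locally aligned against a consensus KS
protein with affine gaps (BLOSUM62, gap open 11, extend 1 — the
conventional protein-search defaults). Within a frame, successive
non-overlapping hits are extracted by masking each accepted alignment
with stop characters and re-aligning until the score falls below
`min_score`. Defaults (`min_score = 200` raw score,
`min_len_aa = 100`) are conservative for a ~420-residue consensus:
a true KS at ≤ 50 % identity still scores far above 200, while the
best local alignment of the consensus against 10 kbp of random DNA
stays far below it (exercised by simulation in the test suite). Hit
E-values are out of scope; the scanner reports raw scores and percent
identity.

Hits on either strand whose inter-interval gap is ≤ 3000 bp merge
transitively into one discrete KS domain ("greater than 3 kbp apart"
is read as: separate iff gap strictly exceeds 3 kbp). Candidate
assembly lines are chains of consecutive KS domains with neighbour gaps
≤ 20 kbp (boundary inclusive) and ≥ 3 members. Chaining, rather than
all-pairs proximity, is deliberate: an all-pairs rule would cap cluster
span at 20 kbp, which real assembly lines far exceed.

A called span covers first-KS..last-KS only, while cluster genes
(terminal thioesterase, downstream NRPS modules, stand-alone ATs)
extend beyond the last KS. `assemble_cluster` therefore attaches
proteins within 10 kbp of the span and widens the boundary to whole
CDSs — on the order of one module length, and half the 20-kbp chain
gap, so two separately called candidates can never absorb each other's
core.

## Classification

Modules are delimited KS-to-next-KS over the genomically ordered domain
list. A module containing an AT is cis-AT; otherwise trans-AT. Any
C/A/PCP domain anywhere in the cluster marks NRPS-hybrid character.
The label is all-cis / all-trans / mixed, crossed with hybrid status;
clusters with no AT anywhere *and* no ACP cannot be typed as PKS
modules at all and fall to "other hybrid".

## Deduplication

Within a species (exact, case-insensitive binomial match; clusters
without a species never collapse), two clusters are identical when one
nucleotide sequence equals or contains the other (either strand) or
when their architecture signatures match. The signature is the ordered
per-protein domain-kind string (e.g. `KS-AT-ACP|KS-AT-KR-ACP-TE`); it
ignores coordinates and protein lengths because duplicate unassembled
contigs shift both. Equality is closed transitively (union-find), so
nested sub-sequence chains resolve to one representative — the longest
span, then the earliest deposit, then the smallest id.

## Pairwise similarity

The score is annotation-free, amino-acid-level and local: for each
protein *p* of cluster *a*, the best-scoring local alignment of *p*
against any protein of *b* contributes its identity fraction
(identities / alignment columns) weighted by the number of residues of
*p* it covers; the directed score is the covered-identity mass divided
by the total residue count of *a*, and the reported similarity is the
mean of the two directions (the open normalisation choice — shorter,
longer, or mean — is resolved as mean). Each query residue counts at
most once: one best alignment per protein, no HSP tiling. All cluster
proteins participate, including NRPS-only subunits of hybrids.

Properties guaranteed by construction and enforced by tests: symmetry,
self-similarity 100, range [0, 100], invariance to protein input
order, and monotone non-increasing scores along a simulated divergence
series. Simulated homolog families at moderate divergence fall mostly
inside the 46–89 % band reported for closely related macrolide
assembly lines — a sanity band, not a calibration target.

Redundancy pruning sweeps clusters greedily in priority order
(earliest deposit date, then longest protein complement, then smallest
id — the retention priority is this package's choice); a cluster is
kept iff its similarity to every already-kept cluster is ≤ 90 %.
Greedy retention is not transitive — in a chain A~B, B~C, A≁C both A
and C survive — and the removed-map records, for each pruned cluster,
the first retained cluster exceeding the threshold.

## Network and dendrogram

Edges connect pairs scoring strictly above 50 % (a score of exactly 50
is no edge), weighted by the score; nodes carry type, known-product
and phylum attributes and singletons are reported separately as
deorphanization candidates. Exports: GraphML with typed attributes
(Cytoscape-ready), SIF, edge TSV, all with deterministic ordering.
The dendrogram is UPGMA (average linkage) on d = 100 − similarity —
chosen because the published artefact is distance-based and no method
is named — with node heights d/2, so the tree is ultrametric; Newick
serialization carries branch lengths.

## GRINS detection

GC skew is (G−C)/(G+C) and TA skew (T−A)/(T+A) per window; windows
with a zero denominator report skew 0. The profile uses 150 bp windows
at 30 bp steps: the window must be well below the ~1 kbp target region
length to resolve edges, and 5× overlap smooths single-window noise.
A skewed region is a maximal run of consecutive windows with both
|skews| ≥ 0.25 ("GC and TA skews higher than 25 %" read conjunctively)
and consistent sign per skew, spanning ≥ 700 bp (the operationalization
of "approximately 1 kbp"; all thresholds configurable via
`GRINSParams`).

Internal repeats are found by exact 16-mer seeding off the
self-diagonal, greedy chaining by position (≤ 200 bp) and diagonal
(± 20 bp, tolerating small indels), and global-alignment identity
refinement with edlib; pairs need ≥ 700 bp on both copies and ≥ 90 %
identity, and the two copies must not overlap. A brute-force
windowed-identity oracle guards the heuristic at small scale. The
"often exceeding 90 %" identity is applied as a hard (configurable)
filter.

A GRINS is a skewed region with ≥ 50 % reciprocal overlap with one side
of a repeat pair; both duplicated copies are reported, each with its
partner coordinates and repeat identity. Prevalence tables give, per
PKS type or phylum, the fraction of catalogued clusters with ≥ 1 GRINS.

## Catalogue statistics

Discovery series count clusters per deposit year (an optional cutoff
date implements partial final years, e.g. an August census). Doubling
time is ln 2 / slope of an ordinary least-squares fit of
ln(cumulative) on year, restricted to years whose cumulative count is
at least 2.5 % of the final total: with only a handful of early
deposits the log-counts are Poisson-noise-dominated and bias the slope,
so the fit uses the established exponential regime (the 2.5 % floor
keeps the textbook 100→200→400→800 example exact while making
parameter recovery on simulated catalogues accurate to a few percent).
GC content is computed over the full cluster nucleotide span, and
cluster length as summed protein residues. Histogram bins are
half-open, cover the data range exactly, and conserve counts.

## Synthetic data

The generator emulates the statistical structure the pipeline consumes,
not biology: cluster DNA is a fixed one-codon-per-residue
back-translation of per-module domain blocks (KS ≈ 420 aa, AT ≈ 330,
ACP ≈ 80, optional KR/DH/ER/MT, terminal TE ≈ 260, NRPS C-A-PCP
modules), separated by uniform-random intergenic spacers and flanks.
Every KS block derives from a fixed synthetic consensus KS (25 %
family-level divergence, 5 % module-level), so the scanner finds each
module and homolog families share realistic KS relatedness while
unrelated families stay well below the 50 % network threshold. The
default "rich" module grammar includes the reductive domains so that
consecutive KS loci sit > 3 kbp apart, as in real assembly lines; a
compact KS-AT-ACP grammar keeps proteins short for alignment-heavy
family simulations.

Homologs are derived by codon-level mutation: a substitution replaces a
whole codon by the codon of a different residue, so the nominal rate
equals the realised amino-acid divergence exactly; indels insert or
delete whole codons, keeping frames intact; intergenic DNA (including
planted GRINS) is carried over unchanged and proteins and domain
coordinates are re-derived.

GRINS plants duplicate one composition-biased segment (default 1 kbp,
G/C/T/A = 0.42/0.10/0.38/0.10, i.e. GC skew ≈ +0.62 and TA skew
≈ +0.58 — intense skews well clear of the 0.25 threshold, so
single-window sampling noise does not sever a detection run) into two
inter-protein spacers, which always lie inside the called cluster
span. Deposit dates are drawn by inverse-CDF sampling from an
exponential-growth density (default rate ln 2 / 2.5 per year over
1995–2022); a lightweight date-only catalogue generator supports
growth-curve work at n in the thousands.

Every generator is a pure function of (spec, seed) and emits a truth
manifest (KS/domain/GRINS coordinates, family membership, redundancy,
growth rate) sufficient to score each stage without re-deriving ground
truth.

**What passing tests show — and don't.** Planted-signal recovery and
oracle agreement establish algorithmic correctness under the stated
contracts. The synthetic DNA has no codon-usage structure, no
low-complexity or repetitive background beyond what is planted, no
sequencing gaps or ambiguity codes beyond N-handling, and no
phylogenetic correlation between families; real-genome performance
additionally depends on scan stringency against diverse KS families
and on the quality of upstream domain annotation, neither of which the
synthetic corpus probes.

## Problem sizes

The default test suite and the acceptance script run combinatorial
oracle checks at 200–500 instances of ≤ 50 elements, GRINS panels at
100 planted plus 100 control clusters (~15–25 kbp each), similarity
contracts on compact-grammar clusters of ~2.5 kaa, pruning on a
12-cluster two-member-family catalogue, growth recovery at n = 2000
dated clusters × 50 replicates, and the end-to-end pipeline on a
3-genome corpus — sizes chosen so the whole cycle completes in minutes
on one core while every claim stays at the granularity the operations
are specified at.

## Known limitations

- The built-in scanner is a rigorous local-alignment search, not a
  seeded heuristic; on megabase-scale genomes it is the slowest stage.
- The similarity score's absolute values depend on the scoring matrix
  and gap penalties (fixed at BLOSUM62/11/1); published scores for
  named PKS pairs from other tools are not reproduction targets.
- Dedup requires species labels to collapse anything; records with
  unknown species are always retained.
- GRINS detection reports same-strand duplications only; inverted
  repeats and inter-cluster repeats are out of scope.
- The seven-way classification trusts the supplied domain annotations;
  mis-annotated ATs flip cis/trans module calls.
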