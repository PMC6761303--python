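# Methods

This note documents the models and procedures implemented in `endobin`,
the defaults and why they were chosen, the numerical choices, and what
the synthetic data can and cannot demonstrate.

## Problem setting

A mixed host–endosymbiont DNA sample is sequenced and assembled; the
assembly `A` contains contigs from the host, the target symbiont, and
often contaminant bacteria. The task is to assign a taxonomic origin to
every contig and extract the target organism's contigs. Three signals
are combined: partial homology-derived taxonomy (sparse, because
symbionts are underrepresented in databases), sequence composition
(k-mer frequencies carry a strong species signal), and read-pair linkage
(mates mapping to two contigs place them in the same genome with high
probability).

## Coverage

Coverage is fragment-count based, in fragments per nucleotide, not
per-base depth: each sequenced fragment contributes one count to the
contig(s) it maps to, split 0.5/0.5 when its two mates map to different
contigs. Merged (overlapping-pair) reads appear as single-end fragments
and count once; a pair with one unmapped mate counts once for the mapped
contig (our choice — a fragment was demonstrably sequenced from it; the
alternative of half-counting would break the conservation property that
total counts equal the number of placed fragments). Counts are exact
reals, never rounded. No mapping-quality filter is applied by default
(`min_mapq` exposes one).

## Composition

Canonical k-mer frequencies are computed on contigs with length ≥
`min_contig_len` (default 1000 nt, threshold inclusive — "longer than
1 kb" is ambiguous at the boundary and we standardize on ≥). Counting
slides over the forward strand, skips windows containing N, maps each
window to min(w, revcomp(w)) and normalizes by the number of counted
windows. This is exactly proportional to counting on both strands and
summing complementary columns: every forward window has a mirror window
on the reverse strand, so both-strand counts are twice the canonical
counts — including palindromic k-mers (even k only), which occur once
per strand and therefore carry the same weight as collapsed pairs. The
test suite asserts this equivalence against an explicit both-strand
counter, plus exact strand symmetry. For odd k the canonical space is
4^k/2 (32 for k=3); for even k it is (4^k − p)/2 + p with p palindromes
(136 for k=4). GC content is (G+C)/(A+C+G+T) with N excluded from the
denominator; all-N sequences yield NaN and all-zero k-mer rows are kept
but flagged by their zero row sum.

Default k = 3: with the short contigs typical of mixed-sample
assemblies, longer k-mers need contigs roughly 10× the k-mer space size
to give stable counts (5-mers: 1,024 words, ~10 kb contigs), which would
discard most of the assembly.

## Homology taxonomy and taxon density

Hits are filtered on load — nucleotide: HSP ≥ 200 bp and identity ≥ 70%;
protein: ≥ 70 aa and ≥ 80% (all thresholds inclusive; the boundary
convention is exposed in config). Protein query ids follow the
`<contig>_<n>` gene-caller convention (an explicit mapping can override
this). Nucleotide and protein hits are pooled per contig with equal
per-HSP weight. At each queried rank, hits resolve to labels through the
lineage table; hits with unknown taxids or lineages lacking the rank are
dropped from the pool, so label densities always sum to 1 over the
resolvable pool. The top label is kept iff it is a unique maximum and
its density is ≥ `taxon_density_min` (default 0.75, inclusive); ties and
sub-threshold densities leave the contig unlabeled — incongruent
evidence is discarded rather than guessed.

16S genes (from an rRNA caller's GFF3, converted internally to 0-based
half-open coordinates) are labeled by their best-identity hit against an
rRNA database. When several 16S genes match the target taxon, the one on
the highest-coverage contig is used — symbiont genomes are present in
many copies per host cell, so the target's 16S contig is expected to be
the deepest; exact coverage ties break deterministically by contig id.

## Read-pair graph and label transfer

Vertices are contigs with at least one placed mate; edges connect
contigs linked by cross-contig pairs, weighted by supporting-pair count.
Edges below `edges_min` (default 10) are removed first, then vertices
whose remaining degree exceeds `vertices_max_degree` (default 5) are
removed in a single pass (iterating to a fixed point is available but
off by default; the single pass is the documented, order-stable choice).

Transfer operates per connected component (CC) and never overwrites an
existing label of any provenance. Two strategies exist:

* `vertexdist="all"` (default): the majority label among the
  reference-labeled members propagates to every unlabeled member unless
  the discordant fraction f (counting contigs, not nucleotides) exceeds
  `mixedcomp_max` (default 0.2) or the majority is tied — both vetoes
  are conservative.
* integer `vertexdist` d: an alternative per-source strategy — each
  reference-labeled vertex spreads its own label along unweighted
  shortest paths (edge weights only gate edge existence) up to d hops.
  A labeled vertex with a different label at path distance n truncates
  transfer at n−2, implemented as: no proposal lands within one hop of a
  conflicting labeled vertex. With a conflict at distance ≤ 2 nothing
  beyond the source is labeled. Vertices receiving conflicting proposals
  from different sources are left unlabeled. Both labeled endpoints of a
  mixed path act as sources symmetrically.

The two strategies are alternatives by design: the distance mode exists
precisely for mixed components where the CC-level veto would block all
transfer, so the veto applies only in the "all" mode.

Mode determines which sources anchor the transfer and what happens on a
veto: `extend_taxonomy` anchors on homology labels; `correct_predictions`
anchors on homology + previous graph extensions and, in a vetoed CC,
removes machine-learning labels and records those contigs as
'misclassified'; `extend_clusters` anchors on cluster-membership labels.

## Ensemble classification

For each rank, contigs carrying a homology- or graph-derived label form
the training pool (machine-learning labels are never training input).
Classes with fewer than `min_class_size` (default 10) members are
dropped; fewer than two surviving classes is a hard error. For each of
`n_replicates` = 100 replicates the pool is split stratified-by-class
into 66% training / 34% held-out (stratification prevents empty-class
training sets on imbalanced pools); the model is fit on the k-mer
frequency columns (GC/coverage appended only when `feature_type` says
so), held-out accuracy is recorded, and all unlabeled contigs are
predicted with hard class outputs. A contig's vote fraction for a class
is the share of replicates predicting it; the final label is the
top-voted class, and exact ties flag the contig ambiguous/unlabeled.
All replicate models vote equally — held-out accuracy is reported, not
used for weighting.

Hyperparameters (open choices, exposed in config): RF with 500 trees and
default feature subsampling; SVM with RBF kernel, C = 1, gamma = "scale".
Seeds derive from the master seed via CRC-based stage keys
(`classifier:algo:rank`), so any stage is reproducible in isolation and
all derived seeds stay below 2^31.

Nested classification walks `rank_sequence` coarse→fine; after each rank
the universe is restricted to contigs assigned (by any source) to the
target's ancestor at that rank, inferred from the lineage table, and
predictions are corrected against the graph. The target label itself may
live at a finer rank than the last classification rank (e.g. a
class-level 16S target with superkingdom-only classification, as in a
simple host+one-bacterium sample); extraction then uses the target's
ancestor at the last classified rank while the 16S anchor is matched at
the target's own rank.

## Clustering and target selection (flow A)

The predicted-target contigs' k-mer columns are embedded with UMAP
(`ncomp` = 2 components; n_neighbors = 15, min_dist = 0.1, Euclidean
metric — standard defaults, exposed in config; single-threaded with a
fixed random state for determinism). If `feature_type` includes gc
and/or cov, those columns are z-scored and appended to the embedding
coordinates, so clustering operates on [embedding ‖ extras]. DBSCAN uses
minPts = 5 and, unless overridden, an eps from the elbow of the sorted
5-NN distance curve (the point farthest below the chord — a
kneedle-style criterion chosen because assembly sizes vary over orders
of magnitude, so no fixed eps is sensible). The cluster containing the
target 16S contig becomes the target set; a noise-classified or absent
anchor is a hard error with a remedy hint. Finally the read-pair graph
extends cluster membership (target vs non-target as transferable
labels; noise points stay unlabeled and thus reachable) to contigs
excluded from the composition matrix — chiefly sub-threshold short
contigs. Flow B (clustering disabled) extracts the voted target contigs
directly.

## Evaluation

The evaluated universe is the truth map's key set, so contigs dropped by
the length filter and never recovered count as FN/TN rather than
disappearing. All four rates are computed twice, from contig counts and
from summed nucleotide lengths; zero-denominator rates are reported as
undefined, not 0. Truth comes from a label map (the synthetic generator
knows each contig's source genome); this replaces reference-alignment
statistics, so real-data numbers obtained by aligning to a reference
genome are not directly comparable where assemblies are incomplete.

## Synthetic mixtures: what they emulate and what they do not

Genomes are first- (optionally second-) order Markov chains whose
transition rows carry an exact target GC mass with row-specific C/G and
A/T splits — the simplest model giving each genome a distinctive 3-mer
signature while pinning mean GC (generator tests check recovery to
±0.03). Contigs are log-normal fragments (≥ 200 nt) of one sampled
genome string. Fragment placements are Poisson per contig at
`base_coverage` = 0.02 fragments/nt per coverage-multiplier unit; 20% of
same-contig fragments are single-end (merged) reads. Adjacent contigs of
a genome are junction-linked with probability 0.5 and Poisson(25 ×
multiplier) spanning pairs — calibrated so that the default edge-weight
filter (10) is a live constraint at multiplier 1; the 0.5 junction
probability keeps the linkage graph fragmented so that the ensemble
stage retains genuinely unlabeled contigs to predict. A configurable
noise rate adds cross-genome pairs. 30% of contigs receive 3–8
concordant homology hits drawn above the filter thresholds (plus one
below-threshold decoy each, exercising load-time filtering); an error
rate redirects a contig's hits to the wrong genome. The 16S contig
always receives hits, as its rRNA is by construction represented in
databases. The default study mixture is a 280 kb eukaryote-like host
(GC 0.39, 140 contigs, 9× coverage) plus a 200 kb bacterial symbiont
(GC 0.55, 110 contigs, 1× coverage) — host:symbiont coverage 9:1.

Not emulated: read-level errors, repeats and chimeric assembly,
conserved regions shared between genomes (homology hits are never
ambiguous between genomes unless the error rate says so), uneven
within-genome coverage, and realistic database incompleteness structure.
Passing tests therefore demonstrate the correctness of the machinery and
its behavior under controlled signal strengths, not performance on real
assemblies, where composition overlap and taxonomy errors are harsher.

Problem sizes: the study mixture is ~0.5 Mb across 250 contigs, roughly
two orders of magnitude below a real assembly; it was sized as the
smallest mixture in which every stage (including the edge-weight filter,
the degree filter, the mixed-component veto and short-contig recovery)
operates away from degenerate regimes.

## Degenerate inputs and tie-breaks (summary)

* duplicate contig ids, empty FASTA, unparsable hit rows: hard errors
  with location; non-ACGTN bases masked to N with a count.
* taxon-density ties and vote-fraction ties: unlabeled, never guessed.
* CC majority ties: transfer vetoed.
* 16S coverage ties: lexicographically first contig id, logged.
* all-N/short sequences: flagged zero rows; all-zero rows never crash
  the classifier (they are legal feature vectors).
* empty graph, single-member clusters, singleton target clusters:
  allowed, with warnings.

## Known limitations

* TaxonDensity merges nucleotide and protein evidence with equal per-HSP
  weight; no E-value or bitscore weighting.
* The eps elbow heuristic can over- or under-cluster highly unbalanced
  embeddings; `dbscan_eps` overrides it.
* Distance-mode transfer with multiple conflicting sources resolves
  conservatively (no transfer), which can under-propagate in dense mixed
  components.
* Length-dependent training weights for the classifiers are not
  implemented; misclassification cost is per contig during training even
  though evaluation is length-weighted.
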