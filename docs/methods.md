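# Methods

## The analysis in one paragraph

The package models the standard ceRNA-network dissection of diabetic
retinopathy (DR): two disease gene lists (diabetes and DR) are
intersected and mapped onto a protein–protein interaction (PPI)
backbone; the largest connected component of that disease subgraph is
kept and lncRNA–mRNA ceRNA regulations (each annotated with the miRNAs
the pair shares) are integrated on top, giving a typed network whose
nodes are lncRNA / diabetes / DR / common genes and whose edges are
`ppi` or `cerna`.  The network is characterised topologically, dense
modules are detected with MCODE, modules and hubs are tested for gene-set
over-representation, case/control expression supplies differential
expression and ceRNA coexpression, and disease-associated SNPs are
screened for allele-dependent gain/loss of miRNA seed sites and TF
motifs, which is propagated to created/disrupted ceRNA relations.

## Network construction

Gene-symbol matching is exact, case-sensitive string equality (an
upper-casing hook exists, default off); no identifier-mapping service is
consulted.  Largest-component extraction happens *before* ceRNA
integration, so lncRNAs enter only through ceRNA edges to backbone
genes.  A ceRNA edge must join exactly one lncRNA and one coding gene;
if a pair also interacts in the PPI both edges are kept with distinct
kinds, and a node's degree counts both.  All ceRNA lncRNAs are
integrated without a disease-association filter of their own.

## Topology

Betweenness centrality uses exact shortest-path counting (Brandes, via
networkx) normalized by `(n−1)(n−2)/2`; disconnected pairs contribute
zero; graphs with fewer than three nodes get all-zero BC.  The
topological coefficient follows the NetworkAnalyzer convention:
`TC(v) = avg_m J(v,m)/k_v` over all `m ≠ v` sharing at least one
neighbour, with `J` counting shared neighbours plus 1 if `v` and `m` are
adjacent; nodes of degree ≤ 1 get 0.  Degree-distribution fits regress
`log10 N(k)` on `log10 k` over observed degrees `k ≥ 1` (frequencies,
not densities; zero-frequency degrees are absent by construction) and
require at least three distinct degrees; the signed least-squares slope
is reported as-is.  Group comparisons use the two-sided Mann–Whitney U:
exact null when both groups have ≤ 8 observations and no ties (two-sided
p by doubling the smaller tail, capped at 1), otherwise the normal
approximation with mid-rank tie and continuity corrections.  Hubs are
the top-k nodes by degree (k = 50 by convention), ties broken by node id
for determinism.  Hub-lncRNA regulating proportions count ceRNA partners
per disease class, normalized over disease-typed partners only; partners
typed `other` are reported separately.

## MCODE

The canonical three stages, written from scratch.  Vertex weighting:
`w(v) = k_max × density` of the highest k-core of v's closed
neighbourhood, where density = `2E/(V(V−1))` (no self-loops) and core
numbers come from iterative minimum-degree peeling.  Complex prediction:
seeds descend by weight (id-ascending tie-break); breadth-first
expansion up to `max_depth` admits a neighbour iff its weight exceeds
`w(seed)·(1 − node_score_cutoff)` and it is not claimed by an earlier
complex (complexes are disjoint, first claim wins).  Post-processing:
the haircut iteratively strips members with exactly one intra-complex
edge; fluff is available but off by default; complexes whose induced
minimum core is below `k_core` are discarded.  Score = density × size;
ranking is score desc, size desc, smallest member id.  Defaults are the
study parameters: K-core 2, cutoff 0.2, depth 100, top 5.

## Enrichment

Upper-tail hypergeometric per set with BH correction across the
collection, rows sorted by adjusted p then set name.  lncRNAs are
excluded from queries (enrichment concerns coding genes).  The default
universe in the pipeline is the collection's genes intersected with the
network's coding genes — the background is a genuine free choice here,
so it is explicit and overridable.

## Expression

The matrix is treated as already-normalized non-negative abundances;
missing values are a hard error (no imputation).  The t-test is Welch's
(25 vs 5 samples give no reason to assume equal variances; the pooled
test is available by flag) on `log2(x+1)`, while fold change is the
linear-scale ratio of group means — the combination under which an
"FC ≥ 1.5" threshold is meaningful.  Significance is raw `p < 0.05`
plus the two-sided FC gate; BH-adjusted values are emitted for reference
only.  Zero variance in both groups with equal means yields t = 0,
p = 1; a zero control mean yields FC = ∞ and is flagged.  Coexpression
is Pearson `r` over all samples with `p` from the t transform with
`n−2` df; constant vectors are reported as missing.

## Variant overlay

SNPs carry transcript-relative 0-based positions, single-nucleotide
ref/alt alleles, an LD `r²` (absent for lead SNPs) and one of seven
region classes (enhancer, TFBS, lncRNA body, DHS, open chromatin,
footprint, TAD).  The LD filter keeps leads and proxies with strictly
`r² > 0.8` (inclusive mode by flag).  Region classification from
BED-like intervals is half-open `[start, end)` and multi-label, since
regulatory catalogs overlap.  A miRNA binding site is an exact 7mer-m8
seed match — the reverse complement of miRNA positions 2–8 (6mer/8mer
selectable); TF motifs are IUPAC consensus strings.  Site calling
substitutes each allele at the SNP and compares the sets of match starts
overlapping the SNP: alt-only starts are gains, ref-only starts losses.
The transcript FASTA is taken as the lncRNA sense strand; no
thermodynamic or PWM scoring is attempted.  An existing ceRNA edge is
disrupted when loss events cover all of its shared miRNAs; a relation is
created when a lncRNA gains ≥ 1 site for a miRNA in a non-adjacent
gene's annotated set (a strict all-shared mode exists; identifiers are
opaque strings throughout).

## Synthetic data: what it emulates and what it does not

Defaults mirror the real study shapes: a 9,064-node preferential-
attachment (Barabási–Albert) PPI with m = 7 (≈ 63.5k edges),
1,349/371/269 diabetes/DR/common genes, 1,848 lncRNAs with
Poisson(1.5) ceRNA edges each (1–3 shared miRNAs drawn from a pool of
~370), a 25-case/5-control matrix, and 500 SNPs.  Expression is
log-normal: per-gene baseline `log2` abundance ~ U(3, 8), i.i.d.
Gaussian log2 noise (default sd 0.4), and planted DE genes (default 10%)
add a ±`effect_log2fc` (default 1.5) shift to the case group — the
minimal model under which the t-test + FC analysis is exactly calibrated.
SNP region classes are sampled with fixed weights (TFBS 0.25, DHS 0.20,
lncRNA 0.20, enhancer 0.15, open chromatin 0.10, footprint 0.05,
TAD 0.05); `r²` values are sampled attributes (20% leads, the rest
U(0.5, 1)), not computed from genotypes — no LD haplotype structure is
simulated.  Every lncRNA-body SNP gets a planted miRNA-site event and
every TFBS-class SNP a planted motif event, embedded so that exactly one
allele completes the site; rejection sampling then re-randomises the
surrounding window until **no** accidental allele-differential match
exists for any seed or motif, so the planted truth is exhaustive
(verified by direct string search, independent of the caller).  Where
possible, planted losses target the sole shared miRNA of a real ceRNA
edge and planted gains target miRNAs annotated to non-adjacent genes, so
disrupted/created truth exists.  Planted miRNA seeds are unique at the
7mer level, transcripts are 400 nt, and same-transcript SNPs are kept
≥ 40 nt apart so caller windows never interact.

**Planted modules are separated.**  Planted cliques (default 3, sizes
8–12) are drawn on vertex-disjoint *and non-adjacent* subsets.  Two
cliques joined by even one background edge form a single true dense
module, which no density-based detector can (or should) split — with
fully random placement on a BA(300, m=2) background several such edges
appear per graph and module-recovery truth becomes ill-defined.
Separation is the standard identifiability condition of planted-module
benchmarks; MCODE itself is untouched by it.

What passing tests therefore show: the pipeline's operations are correct
against oracles and calibrated under their own model assumptions.  What
they do not show: robustness to the features real data add — correlated
expression noise, identifier mess, LD structure, overlapping modules,
non-exact miRNA pairing — which the generator deliberately does not
simulate.

## Numerical and determinism choices

All randomness derives from a single seed through per-stage independent
streams (SeedSequence with a CRC of the stage name), so stages are
individually reproducible and a fixed-seed run is byte-identical; the
pipeline caches per-stage JSON blocks and can resume from them.  Exact
statistical kernels (hypergeometric, exact Mann–Whitney, BH) come from
scipy/statsmodels; all tie-breaks (components, hubs, seeds, rankings)
are lexicographic on ids.  Default problem sizes in the test and
acceptance experiments (e.g. 20 seeds × 300-node graphs for module
recovery, 200 null matrices of 100 genes for type-I calibration,
20 fixtures of ≥ 50 planted events for variant recovery) were chosen as
the smallest scales at which the targeted rates are stable.

## Known limitations

The Welch test at 25-vs-5 with 100% planted effect sizes is slightly
anticonservative (null type-I ≈ 0.057 at nominal 0.05).  "Created" ceRNA
relations are a catalog of potential edges (any shared gained miRNA), so
their count grows with the annotation density of the miRNA pool.  The
enrichment stage's collections are random stand-ins: they exercise the
statistics, not biological signal.  Power-law fits on small node classes
of the integrated network are noisy — scale-free behaviour is validated
on the full preferential-attachment backbone instead.
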