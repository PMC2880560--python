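# Methods

This note documents the models, numerical choices and limitations behind
`envfam`. It describes what the code computes; every empirical number quoted
here is produced by the test suite or the acceptance script.

## Pairwise alignment and the similarity graph

Pairwise comparison is optimal local alignment (Smith–Waterman) with affine
gaps, computed by Biopython's `PairwiseAligner`. The scoring scheme defaults
to BLOSUM62 with gap open 11 and gap extend 1; a gap run of length L costs
`11 + L`. Masked residues (`X`) are assigned score 0 against every residue,
so masking can neither create nor destroy similarity. Identity is counted as
matches / alignment columns, gap columns included (CD-HIT-style accounting).

The homology criterion for graph edges is **raw** alignment score ≥ 60. The
classic criterion ("a Blast score of 60") does not state raw vs bit score or
the matrix; raw Smith–Waterman under BLOSUM62/11/1 was chosen because it is
deterministic and independent of database size, and it is configurable
(`ScoringScheme`, `min_edge_score`). Correctness of the aligner is pinned in
two independent ways in the tests: a brute-force enumeration over all sets
of aligned residue pairs (tiny lengths), and a separately coded memoized
recursion (lengths ≤ 12, 200 random pairs).

The all-vs-all comparison is O(n²); at the package's intended desk scale
(10²–10³ sequences) this is seconds. An optional shared-k-mer prefilter
(k = 4, ≥ 2 shared k-mers) skips hopeless pairs; it is a heuristic and is
disabled in every oracle-checked test. Between-family chance alignments at
the threshold have per-pair probability of order 1e-4 for typical lengths,
so a handful of borderline (score ≈ 60) spurious edges per ~10⁵ pairs is
expected and harmless: Markov clustering does not merge well-connected
clusters across a single weak bridge.

## Identity reduction (NR85s)

The search database is reduced by greedy incremental clustering,
longest-first with ties broken by id: a sequence joins the first
representative it matches at ≥ 85 % identity over ≥ 80 % of the shorter
sequence, else becomes a representative. This mirrors the standard
non-redundant-database construction; the 80 % coverage floor prevents short
fragments from being absorbed by spurious local matches.

## Markov clustering

The flow matrix is column-stochastic with per-node self-loops equal to the
node's maximum incident edge weight (standard regularisation; 1.0 for
isolated nodes). Iteration alternates expansion (matrix square) and
inflation (elementwise power 2.0, column renormalisation), pruning entries
below 1e-5, until the maximum elementwise change is below 1e-8 or 200
iterations (non-convergence flags the result instead of failing). Clusters
are the connected components of the converged matrix's nonzero support.
Edge weights are raw alignment scores; no E-value transform exists at this
stage. Node order is lexicographic so floating-point iteration is
reproducible. The implementation is checked for exact partition equality
against an independently coded plain-loop oracle on 50 random graphs.

Inflation 2.0 is the common default for protein-family clustering; the
source analyses do not report the value actually used, so it is exposed in
the configuration.

## Profile models and significance

A profile is a position × residue matrix of half-bit log-odds
`2·log2(p_i(a)/q(a))` with uniform background `q = 1/20` and a Dirichlet
pseudocount α = 0.5 per residue; alignment columns with > 50 % gaps are
dropped. Half-bit units keep profile scores on the BLOSUM62 scale so the
same gap penalties (11/1) are meaningful. Scanning is position-specific
local alignment of profile vs sequence with the same DP recurrences as the
pairwise stage (numba-compiled).

Significance is empirical: for each model the maximum local score against
200 i.i.d. uniform-composition decoys of length 350 is fitted with a Gumbel
law (scipy MLE), and `E(S) = Z · P(score ≥ S)` with effective database size
Z = 2,000, matching the classic `-Z` normalization semantics. Reporting
cutoff is E ≤ 1e-4; the inclusion cutoff during iterative enrichment is the
conventionally looser 1e-3. Limitations: E-values are not length-corrected
per target sequence, decoys are composition-uniform rather than shuffled
real sequences, and the model is a PSSM, not a full match/insert/delete HMM
— adequate for the strongly conserved planted families the generator
produces, and calibration sanity (observed ≤ 3× expected decoy counts at
E ∈ {0.1, 1}) is asserted in the tests.

Iterative enrichment (the PSI-style loop) runs up to 5 rounds: scan the
reduced database, add sequences at the inclusion cutoff (membership is
monotone non-decreasing), realign all members by stacking their hit spans in
model coordinates (model-anchored realignment: insertions relative to the
model are dropped — deterministic and sufficient for profile rebuilds, at
the cost of never lengthening the model), rebuild and recalibrate, stopping
early when membership is fixed. A model that shrinks below 10 columns is
discarded as collapsed, with the reason recorded.

Clusters are merged when their profiles share ≥ 2 sequences with hit spans
overlapping by ≥ 50 % of the shorter span; merging is transitive
(union–find). The published procedure says only "overlapping hits"; the two
thresholds are this package's concrete reading and are configurable.

## Filter cascade semantics

Boundary semantics follow the published wording literally and are pinned by
unit tests: known-family overlap removes at **strictly more than** 20 % of
members; genomic coverage keeps at ≥ 75 % of at least one genome protein
(read as coverage of the *protein*, which the phrasing "aligned with at
least 75% of at least one protein" supports); model length keeps ≥ 100
positions (model length = kept columns); metagenome support keeps ≥ 10 hits;
prior-family acceptance requires ≥ 15 seed hits. The final, historically
manual curation step is represented by advisory flags only: `divergent` (no
column with ≥ 50 % conservation, or > 30 % of residues in low-complexity
windows — Shannon entropy < 2 bits over 12-residue windows), `no_core`
(< 50 % of members overlap the best-covered model position),
`few_reference_hits` (< 15 hits in a reference database) and `annotatable`
(≥ 25 % of member descriptions carry function keywords). Flags are reported;
nothing is removed.

## Specificity statistics

With counts `(g, n, G, N)` and totals `(g_T, n_T, G_T, N_T)`:
`Ov = (g/g_T)/((n+1)/n_T)`, `Ex = g/(G+1) − n/(N+1)`, `Es = G/G_T − N/N_T`.
The pseudocount placement (+1 on the unrelated protein count in Ov, +1 on
both genome counts in Ex, none in Es) is exactly what reproduces every row
of the published reference tables; the 58-row regression fixture in
`tests/data/reference_family_stats.tsv` asserts all three statistics per row
at the printed 2-decimal precision, with half-up rounding (3.625 → 3.63
appears in the reference data and discriminates the rounding mode).
Counting is one best hit per protein — a protein with several domain copies
counts once per model; `g`/`n` are therefore protein counts, not domain
counts. This matches the "total number of representatives" reading of the
reference tables; per-domain counting is a documented possible variant, not
implemented.

No significance test is attached to Ov/Ex/Es (none exists in the source
analysis), and genome relatedness is not corrected for: phylogenetically
clustered genome sets inflate all three statistics.

## The synthetic world

The generator emulates the statistical structure of the real study inputs
without reproducing any real sequence:

* **Planted families** — random consensus sequences (length uniform in
  [90, 180], ≥ 60 enforced), members are i.i.d. per-site mutants at rate
  0.15 (uniform replacement to another residue). This keeps within-family
  pairwise identity around 72 %, comfortably above the score-60 edge
  threshold while leaving room for the 85 % reduction step to act.
* **Prevalence** — per family, related-set prevalence uniform in
  [0.6, 0.95]. Environment-specific families (default 25 % of 40 families)
  have unrelated-set prevalence 0; the rest are habitat generalists with
  equal prevalence in both sets, which separates the Es distribution into a
  specific mode (Es ≈ prevalence) and a neutral mode (Es ≈ 0 ± binomial
  noise) without tuning.
* **Copy number** — zero-truncated geometric with mean 1.5, giving the heavy
  right tail of family sizes with a single parameter.
* **Genomes** — 16 related and 48 unrelated genomes (a ~4× scaled-down
  stand-in for the 65/493 reference collections), each with 30 background
  (i.i.d. random) proteins plus its family members.
* **Metagenome** — 800 ORFs sampled from the related genomes' proteins;
  6 % singleton decoys (i.i.d. random sequences); 20 % of non-decoy ORFs
  truncated by a uniform [20 %, 60 %] prefix/suffix cut and flagged
  incomplete, mimicking reads running off contig edges.
* **Known families** — a configurable fraction of planted families is
  flagged "known" and exported as gap-free seed alignments (8 fresh mutants
  each) for the masking stage. The default world uses 0: the recovery
  benchmarks measure clustering of all planted families, and the masking
  path is exercised by dedicated tests with explicit configurations.

What the world does **not** emulate: real amino-acid composition and
low-complexity sequence, domain architecture (families are single-domain,
full-length), indel evolution within families, genome phylogeny (genomes
are independent draws), and fragmentary assembly beyond simple truncation.
Passing recovery tests therefore demonstrates the pipeline's mechanics —
graph construction, clustering, profile search, counting, ranking — not
performance on real metagenomes, where composition bias and shared domains
make both masking and clustering substantially harder.

On the default world (fixed seed), the suite asserts that ≥ 95 % of planted
families with ≥ 2 complete metagenome members are recovered as clusters at
≥ 90 % membership agreement (Jaccard), and that ≥ 90 % of the top Es decile
of discovered families maps to planted environment-specific families.

## Problem sizes and determinism

Default test and benchmark sizes — 800 ORFs, 64 genomes (~4,300 proteins),
40 families — were chosen as the smallest world at which family recovery is
statistically comfortable (each family expects ~13 metagenome members);
smaller worlds are used for stage-level unit tests. All randomness flows
from explicit seeds (world seed; per-model calibration seeds derived from
the pipeline seed), and a rerun with identical config and seed writes
byte-identical output tables, which the pipeline test asserts with file
comparison. The published headline counts of the original study
(665,559 → 303,314 ORFs; 1,761 families; the cascade to 183) depend on the
real metagenome, Pfam releases and NCBI genomes and are deliberately out of
reach; the cascade's shape properties (monotone non-increasing, exact
bookkeeping) are asserted instead.
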