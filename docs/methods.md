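# Methods

`degradomics` implements the comparative-genomics computations used to
contrast cultivable marine flavobacteria (large genomes, rich degradomes)
with streamlined, uncultivated relatives: genome-aggregate identity and
species delineation, reciprocal-best-match orthology and pangenome
partitioning, polysaccharide-utilization-locus (PUL) detection, degradome
scaling statistics, and read-recruitment abundance estimation.  Every
stage can be exercised on seeded synthetic data with known ground truth.

## ANI and AAI

Average nucleotide identity follows the fragment protocol: the query is
cut into consecutive non-overlapping fragments of `fragment_length`
(default 1020 bp, the published constant of the classic protocol; the
terminal remainder is discarded), each fragment is searched against the
whole subject genome, and a fragment's best hit is retained iff it
reaches `min_hit_identity` (default 30%) over at least `min_hit_coverage`
(default 70%) of the fragment.  One-way ANI is the mean identity of
retained hits; reciprocal ANI is the mean of the two one-way values, so
it is symmetric by construction.  A direction that retains no fragment
makes the pair *undefined* — represented as missing, never 0, so
undefined pairs cannot distort dendrograms or clustering.

The fragment search is an aligner contract.  The default backend aligns
each fragment semi-globally (whole fragment against the best-matching
infix of the subject) by bit-parallel edit distance, searching both
strands; the band is bounded at `max_divergence` (default 0.5) so hits
worse than 50% divergence count as no hit, and the bound tightens to the
best distance found so far, which is what makes genome-scale sweeps
fast.  An exact affine-gap local aligner (match +1, mismatch −1, open
−5, extend −2) is available as an alternative backend with identical hit
semantics, and the two agree to within ~0.3 ANI points on desk-scale
pairs (asserted in tests).

AAI averages percent identity over reciprocal best matches; with a core
OG set supplied it averages only core-gene RBMs.  "Identity" is
exact-match identity over aligned columns, not substitution-matrix
positives — the stricter and more reproducible of the two readings; a
positives-based variant would require choosing a scoring matrix and is
deliberately not the default.

Species are single-linkage components over pairs with reciprocal
ANI ≥ 95%, the conventional prokaryotic species boundary; the threshold
is inclusive and overridable.  Heatmap ordering uses average-linkage
hierarchical clustering of `100 − identity` distances.

## Orthology and pangenome

All-vs-all protein comparison uses a local aligner (BLOSUM62, gap open
−11/extend −1) behind a 5-mer candidate prefilter: subject proteins
sharing no 5-mer with the query are skipped.  At the ≤20% family
divergence the generators plant, true homolog pairs share hundreds of
5-mers, while a random protein pair shares none with high probability —
and a chance single shared 5-mer still gets aligned, so the filter only
removes pairs that could not approach the homology rule.

A reciprocal best match requires (i) mutual best-hit status (rank key =
alignment score; ties broken by lexicographically smallest subject id,
documented and deterministic) and (ii) the 50/50 rule — ≥50% identity
over ≥50% of the query length — evaluated on the query side of each
direction independently.  Both thresholds are inclusive (≥); the rule's
source is silent on boundary behaviour, and inclusive is the natural
reading of "50% or more".

OGs are Markov clusters (expansion 2, inflation 1.5, similarity-weighted
adjacency with unit self-loops, column pruning at 1e-8) of the RBM
graph; clusters are read off the converged flow matrix as connected
components of its support, which for clique-disjoint graphs provably
equals plain connected components (asserted against that oracle in
tests).  A `components` mode is available as a fallback.  Genes with no
RBM edge become singleton OGs; every gene belongs to exactly one OG, and
paralogs of one genome may co-cluster.  The partition counts OGs by
genome *presence*: core = present in all included genomes, variable = in
two or more but not all, genome-specific = exactly one.  The identity
core + variable + specific = total is asserted on every run.  Counts are
reported both with and without singleton OGs (`n_singleton_ogs`),
because published totals are ambiguous about singletons.  When
completeness metadata is given, genomes under 95% complete are excluded
before partitioning.

Variable-gene genome clustering is average linkage on Euclidean
distances between 0/1 presence rows.  Core-gene phylogeny concatenates
per-OG alignments in stable OG-id order, computes p-distances over
gap-free column pairs, and runs canonical Neighbor-Joining with negative
branch lengths clamped to zero.  The per-OG alignment step is a
center-star aligner (longest member as center, pairwise-global merge on
center coordinates) — adequate because planted OG members are
substitution-only relatives; a real MUSCLE/MAFFT alignment can be
substituted wherever an aligned block mapping is accepted.

## PUL detection

Seed genes are degradative CAZymes (any CAZyme except
glycosyl-transferase-only genes), TonB-dependent/susC-like transporters,
susD-like genes and sulfatases.  Two seeds on one contig chain when
within `window` genes of each other (default 7, between the strict
5-gene and permissive 10-gene conventions); clusters are the transitive
closure.  "Within seven genes" is read as ordinal index difference ≤ 7
(so a gap of exactly 7 chains and 8 splits); the alternative reading,
at most 7 *intervening* genes, is selectable via
`distance_mode="intervening"`.  This is the single most consequential
interpretation in the module and is therefore a visible switch, not a
constant.

A cluster is emitted as a PUL iff it has ≥2 seed genes including ≥1
degradative CAZyme — so isolated transporter tandems or lone sulfatases
are not PULs; `require_suscd=True` additionally enforces the classic
susC+susD definition.  Strand is recorded but ignored for chaining.
GT-only genes inside the span are members but never seeds and never
bridge clusters; their families are excluded from the composition.

Substrate classification matches PUL compositions against an ordered
signature table (required families, forbidden families, required roles
such as sulfatase; lowest priority number wins).  The default table in
`src/degradomics/data/signatures.yaml` covers laminarin, alpha-glucan,
fucoidan, mannan, alginate, sulfated-rhamnoglucan, GH92-GH20-GH2-CE4 and
GH136+sulfatase.  Family-to-substrate mappings of this kind are curated
knowledge, not algorithm output, so they ship as editable data.

The caller is verified against an independent O(n²) brute-force
transitive closure (all seed pairs, label propagation) on hundreds of
random tables; the generator also uses that oracle to emit its truth, so
generator truth never depends on the production caller.

## Degradome statistics

Counts distinguish *total* CAZymes (including glycosyl transferases)
from *degradative* CAZymes (excluding GT-only genes); both are kept
because published counts alternate between the conventions, and the
CAZyme:peptidase ratio defaults to degradative/peptidases with a flag
for total.  Scaling fits are least squares: linear directly, exponential
as linear regression on log counts (closed form, deterministic; zero
counts offset by +1 before the log, and r² then refers to the log
scale).  Phylogroup genome-size summaries report mean ± sample (n−1)
standard deviation, the convention behind "a ± b Mb" statements,
formatted to two decimals; singleton groups report SD 0.00.

## Read recruitment

A read is recruited to the single best reference iff identity ≥ 95% over
≥ 80% of the read; equal-identity ties are ambiguous and discarded
(optionally split equally).  Abundance is percent of *all* reads in the
sample, not of mapped reads, and values under the detection limit
(0.001%) display as "<0.001".  The thresholds are conventional rather
than canonical — upstream protocols leave them unstated — so all three
are explicit parameters.  Read accounting is exact:
recruited + ambiguous + unrecruited = total, always.

The built-in mapper is seed-and-extend: three sampled 15-mers locate
candidate loci on either strand, and the read is aligned semi-globally
to each candidate window (±16 bp pad) by edit distance.  With the ≥5%
reference divergence the tests use, an error-free 150 bp read has ≥7
expected mismatches to the wrong reference, so competitive assignment is
near-unambiguous; references closer than ~3% would make ties common and
this recruiter is not designed for strain-level deconvolution.
Pre-mapped SAM input is accepted, with identity recomputed from cigar
and NM fields, grouped per read across references.

## Synthetic data: what it does and does not emulate

Generators are seeded (`numpy.random.default_rng`) and byte-deterministic.
Nucleotide divergence is i.i.d. per-site substitution, uniform over the
three alternative bases, so the realised Hamming fraction is exactly
binomial at the nominal rate — which is what makes `100·(1−d)` an exact
ANI oracle.  Indels are off by default (geometric(0.5) lengths when
enabled).  Protein families draw i.i.d. ancestors over 20 residues,
lengths uniform in 100–400; `per_gene_mutation_rate` is calibrated as
the expected *pairwise* divergence between two OG members (each copy
mutated at half the rate from the ancestor), so rate 0.10 means ~90%
member identity.  Inter-family identity stays below ~20% with
overwhelming probability (asserted empirically).  Read mixtures are
multinomial over genomes, uniform positions and strands, substitution
errors only, constant FASTQ quality.

None of this emulates real sequence evolution: no codon structure, no
transition/transversion or amino-acid exchangeability bias, no rate
heterogeneity, no HGT, no repeat content, no coverage bias or quality
decay.  Passing tests therefore demonstrate algorithmic correctness
(thresholds, chaining, reciprocity, accounting, parameter recovery under
the stated models), not performance on real assemblies, where gene
calling, repeats and contamination dominate error budgets.

## Problem sizes

Desk-scale defaults keep the full suite and the acceptance script
comfortably within a single CPU: ANI benchmarks use 200 kb genomes
(~196 fragments/direction), pangenome recovery uses 5 genomes × 80 OGs
across 20 seeds, PUL equivalence uses 200 random tables of 100–500
genes, and recruitment uses 100,000 reads of 150 bp against two 100 kb
references.  All scale linearly if enlarged.
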