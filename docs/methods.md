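# Methods

This note documents the models, conventions and design choices behind
`genediv`, in the order the pipeline applies them.

## Phylotype definition

Phylotypes are clusters of a gene family's protein sequences at a global
amino-acid identity threshold, default 0.90 — a level of similarity
typical of organisms within a genus, so a phylotype approximates "the same
gene as carried by one genus-level lineage".

*Alignment.* Identity is computed from a Needleman–Wunsch global alignment
under BLOSUM62 with affine gap scores (open −11, extend −1, end gaps
penalised like internal ones). Identity = identical aligned pairs ÷ total
alignment columns, **including gap columns**, so `AAA` vs `AAAA` scores
0.75. The denominator convention materially changes cluster counts near
the threshold; a shorter-sequence denominator is available via
`ClusteringParams(identity_denominator="shorter")`.

*Clustering.* Greedy centroid clustering in the CD-HIT style: sequences
are visited longest-first (optionally most-abundant-first), ties broken
lexicographically by id, and each joins the first existing representative
it matches at the threshold, else founds a new cluster. The explicit sort
makes the partition invariant to input order. Because the algorithm is
greedy, absolute cluster counts are conventions of the method, not
estimates with error bars; published counts from other tools should be
compared qualitatively.

*Guide trees.* UPGMA (average linkage on d = 1 − identity) over cluster
representatives, written as newick with ultrametric branch lengths. The
tree exists purely to order heatmap rows; a likelihood tree would be
required for any phylogenetic claim, which is out of scope.

## Read recruitment and abundance

Reads are assigned to reference genes by banded infix alignment (edlib),
both strands, accepting hits at ≥ `min_nucleotide_identity` (default 0.95)
over at least 0.8 × read length. Candidate references are found by exact
13-mer seeds at 8 evenly spaced read positions (pigeonhole: a 100 nt read
with ≤ 6 mismatches always shares a 13-mer with its source), with
fall-backs to all seed positions and finally to exhaustive alignment, so a
missed seed can slow a read down but never silently drop it. Each read
counts toward exactly one reference — the best edit distance, ties to the
lexicographically smallest id — keeping counts integral; fractional
multi-mapping resolution is deliberately not attempted.

Normalisations:

- RPKM = count ÷ (gene length nt / 1000) ÷ (library size / 10⁶). Library
  size is all reads sequenced in the sample, assigned or not.
- Per-capita gene abundance = Σ family RPKM ÷ Σ marker RPKM, where the
  marker is a universal single-copy gene (*rplB* analog; all marker forms
  are pooled in the denominator). Under the one-copy assumption this is
  the fraction of individuals carrying the gene; values can exceed 1 for
  multi-copy genes.
- Phylotype relative abundance: member rows summed per phylotype, each
  sample column divided by its sum. All-zero columns ("gene not observed
  that day") stay all-zero rather than NaN so time series remain
  rectangular.

## Diversity and turnover

Richness = number of phylotypes with nonzero relative abundance; inverse
Simpson D = 1/Σpᵢ² (1 for a monoculture, = richness under perfect
evenness; defined as 0 for an empty profile, flagged by convention).
Cumulative series pool raw RPKM from each timepoint with all previous
timepoints before renormalising — pooling observations rather than
averaging proportions — which makes cumulative richness exactly the union
of observed phylotypes and hence monotone. Both cumulative series are also
reported as differences from the initial timepoint.

Turnover of a family = mean over phylotypes of the temporal variance of
relative abundance. The estimator is the unbiased (n−1) variance with
unobserved timepoints counted as zero abundance (`variance_ddof` is
configurable because published absolute values depend on this unstated
choice). Two caveats are asserted in tests: the statistic is row-order
invariant, and appending an all-zero phylotype row *lowers* the mean, so
rows must be the family's observed phylotypes. With very low richness
(2–3 phylotypes) the statistic is dominated by a single compositional
constraint and should be read as exaggerated; richness is the meaningful
number there.

Beta diversity uses Bray–Curtis dissimilarity Σ|uᵢ−vᵢ|/Σ(uᵢ+vᵢ)
(scipy's implementation) over all sample pairs, against time lag in
sample-index units by default or calendar distance when dates are given;
the distance-decay summary is the OLS slope of dissimilarity on lag.

## Inference

Welch's t (with Welch–Satterthwaite df), Levene's test (mean-centered by
default since that is the classic test; median-centering gives
Brown–Forsythe), Mann–Whitney–Wilcoxon and simple OLS (R², F(1, n−2)
p-value) are implemented from their defining formulas; only distribution
tail functions come from scipy. The Mann–Whitney p-value is exact — full
enumeration of the U distribution by the standard recurrence — whenever
there are no ties and n₁·n₂ ≤ 400 (the 6-early vs 5-late seasonal design
always takes this path), otherwise the tie-corrected normal approximation
with continuity correction. All p-values are two-sided. Each test is
checked against an independent reference implementation to 1e-6 and, for
Welch and Levene, against its nominal 5% type-I rate by simulation.

The environmental screen regresses each family's diversity (inverse
Simpson), richness and per-capita abundance on temperature, dissolved
oxygen, Cl⁻ (a conservative tracer of groundwater content) and NPOC.
Raw p-values are reported with significance flags at p < 0.05 and
p < 0.10; a Benjamini–Hochberg column is emitted alongside for
transparency but not used for flagging, since the screen is exploratory.

*Between-family profile variability.* Which observations enter the Levene
comparison of "profile variability" between families is genuinely open.
This package's interpretation: observations are phylotype-centered
relative abundances (each phylotype's temporal series minus its own
temporal mean), grouped by family, so the test compares the average
magnitude of temporal deviation — a variance-homogeneity contrast on
profiles that is insensitive to differences in phylotype mean abundance.
Comparing per-phylotype variances directly with a location test is a
reasonable alternative and can be assembled from the exposed primitives.

## Synthetic community generator

The generator emulates the sampling design the package targets: 11 samples
across a season, an environmental shift from surface-water influence
(high NPOC ~0.9 mg/L, low Cl⁻) to groundwater influence (NPOC < 0.4 mg/L,
high Cl⁻) after the 6th sample, temperature on a rise-then-fall arc,
roughly constant dissolved oxygen, and gene families with planted
phylotype structure and dynamics.

- *Sequences.* Each phylotype has an independent random base protein
  (global identity between random proteins is far below any clustering
  threshold); variants are point-substituted with a budget of
  ⌊(1 − within_min)·L/2⌋ sites so any two variants stay above the
  within-phylotype floor. Every pairwise bound (within ≥ 0.96, between
  ≤ 0.60 by default) is verified with the production aligner; generation
  raises rather than emit a violating pool. Coding sequences are seeded
  random synonymous reverse-translations, giving between-phylotype
  nucleotide identity low enough that read misassignment across
  phylotypes is negligible.
- *Dynamics.* Initial abundances are Dirichlet(α) (small α ⇒ one dominant
  phylotype, as in an nxrA-like family); log-abundances then take
  independent Gaussian steps of size `walk_sigma` and are softmax-mapped,
  so columns sum to 1 exactly and `walk_sigma = 0` gives frozen profiles
  with zero turnover. `walk_sigma` maps monotonically onto the turnover
  statistic (verified: 100/100 paired runs ordered correctly at 0.05 vs
  1.5), which is the property the regimes need; no claim is made that real
  communities follow this process.
- *Reads.* Single-end, fixed length (default 100 nt), uniform start
  positions, per-base substitution errors (default 0.005), Phred+33
  quality 30. Sampling probability ∝ carriage × phylotype share × gene
  length; the marker is present in every individual at one copy, so
  per-capita recovery is exact in expectation. Defaults: 10⁵ reads per
  sample in the library API; the demo configuration uses 2×10⁴ so a full
  run stays interactive (~half a minute) — read depth only tightens the
  sampling error around the same expectations.

What the generator does **not** emulate: paired-end inserts, quality-score
profiles, chimeras, strain microdiversity below the phylotype threshold,
assembly artifacts, HMM-based read extraction, multi-copy markers, or
seasonally varying carriage (the amoA-like seasonal abundance rise is not
modeled — carriage is constant per family). Passing tests therefore
demonstrate correctness of the statistics and the recovery machinery under
clean planted structure, not robustness to assembly or annotation error in
field data.

## Demo configuration

Six families mirror the qualitative regime spectrum of N-cycling genes:
narG-like (52 phylotypes, σ = 0.05), nosZ-like (51, 0.15), norB-like
(31, 0.5), nirKS-like (23, 0.5), nxrA-like (7, 0.05, dominance α = 0.15)
and amoA-like (2, 0.3), with carriage fractions 0.28/0.25/0.16/0.40/
0.10/0.15 and a 40-phylotype marker. The marker richness and read depth
are scaled to desk size; they affect sampling noise, not the expectations
being checked. All seeds are derived from the single run seed by hashing,
and the manifest's per-file checksums make end-to-end determinism
checkable.

## Known limitations

- Greedy clustering counts depend on visit order near the threshold;
  determinism is guaranteed, agreement with other tools' counts is not.
- Best-hit read assignment undercounts genuinely ambiguous reads shared
  between near-identical references (within-phylotype variants); this
  cancels in phylotype-level sums, which is why phylotypes are the unit of
  reporting.
- The regression screen treats samples as independent; with ~11
  autocorrelated timepoints, p-values are anti-conservative and should be
  read as ranking, not confirmatory inference.
- Levene's mean-centered test on abundance deviations assumes roughly
  symmetric deviations; heavy-tailed profiles would favor the
  median-centered variant (exposed as an option).
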