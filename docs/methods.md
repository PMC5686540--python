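# Methods

This note records the models, numerical choices and limitations behind
`microdiv`. It documents what the code does and why; every empirical claim
here is one the test suite or `scripts/acceptance.py` computes.

## Substitution model

All sequence-level machinery — distance correction, placement likelihoods,
the synthetic evolution process — uses one model: a 20-state Poisson
process with equal exchangeabilities and uniform stationary frequencies.
Branch lengths are expected substitutions per site; the transition
probability is

    P(same) = 1/20 + (19/20)·exp(−20t/19),

and the maximum-likelihood distance from an observed difference fraction
p is d = −(19/20)·ln(1 − 20p/19), capped at 10 substitutions/site for
saturated pairs. Using the same model for reference distances and
placement keeps the two stages consistent and analytically transparent.
Rate heterogeneity across sites and realistic amino-acid exchangeabilities
(WAG/LG) are deliberately out of scope: they matter for deep-phylogeny
inference, not for the placement-and-binning mechanics exercised here.

## Synthetic universe

`simdata.simulate_universe` emulates a curated reference collection:

* **Topology.** Genomes are arranged hierarchically (phyla → genera →
  genomes) with random sequential pairing inside each level. Stem scales
  are 0.30 (phylum), 0.12 (genus) and 0.05 (within genus) expected
  substitutions/site — chosen so that the markers behave like conserved
  single-copy genes: clear homology even across phyla (~30–40% identity),
  near-identity within genera. The focal genus contains `focal_clades`
  monophyletic clades with stems of `between_clade_div/2` (default 0.20/2)
  and within-clade scales of `within_clade_div/2` (default 0.02/2).
* **Markers.** Each of the 29 markers has an i.i.d. uniform root sequence
  (default 120 residues) evolved down the tree with per-branch
  Poisson(branch × length) substitution events and a uniform replacement
  kernel. There are no indels, so reference alignments are trivially
  correct; the aligner is exercised separately on gapped cases.
* **16S.** A separate slow nucleotide locus (1,300 nt) whose rate is
  scaled to the focal-genus tree depth so all focal genomes stay ≥ 97%
  identical — one OTU hiding the clade structure. The constraint is
  checked after simulation and violation raises an error naming it.
* **Decoys.** Non-marker genes are i.i.d. background sequences; only
  their non-homology matters. Decoy reads are windows of these genes, so
  they hit the stage-1 database (which contains the decoy genes) but die
  at the stage-2 profile filter.
* **Design.** The sampling design is 8 time points × 3 treatments
  (control, drought, nitrogen) × 2 replicates. Focal-genus weight =
  baseline (7.8%) × exp(seasonal sinusoid) × treatment multiplier
  (drought 1.202, nitrogen 0.828) × lognormal noise; background genomes
  share the remainder with lognormal weights (σ = 1), a stand-in choice —
  nothing is claimed about real rank-abundance shapes.
* **Traits.** GH/CBM totals evolve by Brownian motion on the isolate tree
  (rounded, clipped to 58–98) and are spread over an example family map by
  clade-specific propensities; one clade lacks xylan-targeting families.
  Degradation areas are normal around clade × temperature means; the
  default pattern has one clade gaining activity at 37 °C and one losing
  it entirely.

All randomness flows from one root seed through named CRC32-tagged
substreams (`util.rng_for`), making every artifact byte-reproducible.

## Reference curation

Screening demands exactly one gene per marker above the profile threshold
(minimum training-sequence score minus 2 bits; the source gives no
threshold for this annotation screen, and duplicated markers discard the
genome under the strictest single-copy reading). Genus subsampling keeps
two genomes per genus with preference complete+soil > complete > soil >
neither, ties lexicographic; the focal genus is exempt since its isolate
collection is the object of study. Branch-length curation iterates
"remove every genome with a terminal branch > 5 in any marker tree,
rebuild all trees" to a fixed point, logging removals per iteration — the
fixed-point iteration is a choice; a single pass is the other defensible
reading.

Tree inference is neighbor joining (Saitou–Nei) on Poisson-corrected
distances with pairwise deletion of gapped sites. Ties in the Q criterion
break to the smallest row-major (i, j) pair; negative branch estimates
are clamped to zero with the deficit moved to the sister so the joined
pair keeps its observed distance. On additive matrices NJ is exact
(topology and lengths), which the tests verify to 1e-9. Every marker
package shares the topology of the concatenated-supermatrix tree so node
structure is comparable across markers.

## Filtering and placement

* **Stage 1** (BLASTP-like): 3-mer exact seeds, two hits on a common
  (protein, diagonal) required, ungapped extension scored with BLOSUM62,
  E = K·m·n·exp(−λS) with λ and K from a Gumbel moment fit to the best
  diagonal scores of 10,000 seeded random pairs, cached in the package.
  Default cutoff E ≤ 1e−5; the best marker-labelled hit defines the
  read's candidate marker (one marker per read).
* **Stage 2** (profile-HMM-like): Viterbi best path of the read against
  the marker's per-column log-odds profile (match columns = columns with
  < 50% gaps; affine insert/delete transitions of −3 open / −1 extend
  bits; read-global, profile-local). E-values come from a Gumbel fit to
  1,000 seeded i.i.d. decoy scores per marker, cached after first use;
  cutoff E ≤ 1e−10. Stage-2 survivors are a subset of stage-1 candidates
  by construction.
* **Placement**: the aligned read attaches at each edge's midpoint by a
  pendant branch optimized by golden-section search on [0, 5] (30
  iterations, interval ~2e−6); distal length is reported as half the edge
  length. Conditional likelihood vectors for the distal and proximal
  sides of every edge are precomputed at the midpoints, so a read costs
  O(edges × covered sites) per pendant evaluation. Likelihood-weight
  ratios are normalized over all edges, then truncated to the top 20
  records; they serve as the equal-prior surrogate for a placement
  posterior probability.

## Profiling

Each read's kept mass is renormalized to 1. At a given rank an edge maps
to the taxon shared by every leaf of its distal subtree (none if mixed);
the read is assigned to the taxon holding a strict majority (> 0.5) of
its mass, otherwise "unclassified". Coarser ranks can only gain
consensus, so the unclassified fraction is non-increasing from genus to
phylum. Sample profiles average per-marker relative abundances with equal
marker weight (interpreting normalization "by the total number of marker
genes present" as a correction for unequal marker detection); a pooled
mode is available behind a flag. Clade binning applies the same rule to
the focal-genus clade subtrees; genus-consensus reads without clade
consensus are the "failed to classify" fraction.

## Genome comparisons

16S OTU clustering is greedy centroid clustering in decreasing-length
(then id) order; identity is matches / alignment columns excluding
terminal gaps, which makes the 97% boundary well defined. ANI follows the
fragment scheme (1-kb windows, both strands, best hit per fragment,
identity ≥ 0.3 to count) with alignment by edlib in infix mode, so
fragment coverage is complete by construction; ANI is the mean identity
of kept fragments × 100, flagged undefined (not 0) when nothing
qualifies. AAI is the mean percent identity over reciprocal best hits
under global BLOSUM62 alignment — exact, feasible at desk-scale proteome
sizes, and symmetric by construction. Ortholog groups come from Markov
clustering (expansion/inflation 2.0, convergence 1e−6 or 100 sweeps with
a warning flag); clusters are read from the support of the limit matrix.
The GH/CBM family → substrate map is an input; the shipped
`DEFAULT_FAMILY_MAP` is an illustrative example, not a curated Pfam list.

## Statistics

PERMANOVA uses the McArdle–Anderson trace formulation on the
Gower-centered matrix, type III partial SS (each term adjusted for all
others, sum-to-zero factor coding), and permutes reduced-model residuals
(Freedman–Lane), matching "permutations of residuals under a reduced
model"; raw permutation is available behind a flag. Percent variation is
term SS / total SS × 100 — the total-SS denominator is a documented
choice where the source is ambiguous. Permutation p-values use
(b+1)/(P+1) except in exhaustive mode, which enumerates all n! sample
permutations and returns the exact proportion (identity included); for a
balanced one-factor design this equals enumeration over distinct
relabelings. Confounded (rank-deficient) designs raise an error rather
than silently aliasing.

Mantel/RELATE permutes rows+columns of the second matrix jointly and is
one-sided (greater). Tukey HSD uses the studentized-range distribution
via `scipy.stats.studentized_range` with the Tukey–Kramer standard error
for unequal group sizes. PIC requires a strictly bifurcating tree with
positive branch lengths (polytomies raise an error advising zero-length
resolution) and regresses contrasts through the origin with F on (1,
n−1) df for n contrasts. Backward ANCOVA starts from the full factorial,
uses type II tables from statsmodels, never drops a term contained in a
retained higher-order interaction, drops the worst non-significant
interaction per sweep, and drops the highest-order interaction a priori
(with a warning) if the model is saturated.

## Problem sizes and verification scope

The test suite and acceptance script run the study conditions at desk
scale: a ~54-genome universe (three phyla, six focal clades of three
genomes), 29 markers of 120 residues, 12 samples × 5,000 reads of 60
residues with 5% decoys for the end-to-end checks, and a 30-leaf
reference for self-placement. Under these conditions the pipeline
recovers ≥ 90% of focal reads to their true clade, leaks ≤ 1% of decoys,
and recovers a simulated 7.8% focal abundance within ±1.5 points; the
permutation tests are calibrated against exhaustive enumeration and
nominal type-I error.

What passing these tests does **not** show: performance on real reads
(sequencing error, gene-calling fragments, indels, compositional bias),
markers with paralogy or horizontal transfer, rate heterogeneity across
sites or lineages, or reference databases thousands of genomes deep.
The generator's uniform replacement kernel and indel-free markers make
the homology search easier than real data would; the two-stage E-value
thresholds were kept at their standard values rather than retuned to the
simulation.
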