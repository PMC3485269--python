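# Methods

## Data model and coordinate conventions

All genomic intervals are 0-based half-open in memory; conversion to GFF3's
1-based inclusive convention happens only at file boundaries, so the
round-trip GFF(start, end) ↔ (start − 1, end) is an exact bijection.  A
mapped small RNA is one distinct sequence at one genomic locus with its
per-library abundance and its genome-wide locus count N; a sequence mapping
to N loci appears as N rows sharing seq_id, abundance and N.  Reads outside
16–31 nt are rejected at input.  rRNA/tRNA removal is modelled as a seq_id
blocklist applied at read time rather than by re-alignment: the filter
semantics, not the alignment, are what the pipeline depends on.

## Proximity clustering

Reads from all libraries (including technical replicates) are pooled and
swept per chromosome in start order: a cluster extends while the next start
position is less than `gap` (default 500 bp) beyond the previous start;
a distance of exactly `gap` splits.  The cluster interval runs from the
first member start to the last member end, which affects reported sizes but
not counts.  Distances are measured start-to-start: that is the only
reading that keeps a single linear sweep well defined for variable-length
reads, and it makes the sweep provably equal to the transitive closure of
the "pairs less than gap apart" relation (tested against an O(n²)
union-find oracle).  Clusters are strand-agnostic; 24-nt siRNA loci produce
reads from both strands, and strand is retained per read only for the
hairpin screen.

## Quantification

Each locus of a sequence contributes `abundance / N` to its cluster, where
N is the genome-wide locus count (not loci within expressed clusters), so
total abundance is conserved across clusters to floating-point precision
(asserted at 1e-9 relative).  Counts are scaled to reads per million by the
library's total mapped reads, technical replicates are combined by
arithmetic mean, and clusters with all samples below `min_rpm` (default 5)
are removed; a cluster reaching exactly 5 RPM in one sample is kept
("lower than 5 RPM in all libraries" removes).

## Differential gate

Per cluster a classical one-way fixed-effects ANOVA compares CC, LL and a
hybrid group — both reciprocals pooled (set I, up to 8 biological
replicates) or a single reciprocal (sets II/III).  The F-test runs on RPM
values without a variance-stabilising transform (a log2(x+1) transform can
be applied upstream but is not the default), and Benjamini–Hochberg
adjusted q-values gate DE calls at 5% FDR.  Degenerate clusters with zero
within-group variance get p = 1 when the group means are also equal and
p = 0 otherwise.  The vectorised implementation is cross-checked against
`scipy.stats.f_oneway` row by row, and the BH step against a hand-written
step-up oracle.

## Inheritance classification

For a DE cluster with group means, the high/low parent (HP/LP) identity is
fixed by the observed means; `a = (HP − LP)/2`, `d = hybrid − midparent`,
and d/a is reported (NaN-flagged when a = 0).  The categorical call comes
from a decision tree of t-tests at α = 0.05:

* hybrid vs midparent not significant → **additive (MP)**;
* otherwise, on the side given by the sign of d, a Welch t-test of the
  hybrid against the nearer parent: not significant → **HP** / **LP**;
  significant with the hybrid mean beyond the parent → **AHP** / **BLP**;
  significant with the hybrid mean inside the parental range →
  **between MP and HP** / **between MP and LP**.

No multiplicity correction is applied inside the tree (FDR control applies
only at the ANOVA gate).  Two-sample tests default to Welch's unequal
variance form because group sizes (3 vs 4–8) and variances differ; a
pooled-variance option exists.

**Midparent test.** The midparent has no replicate sample, so the
hybrid-vs-midparent comparison is genuinely open to operationalisation.
The default propagates the uncertainty of the observed midparent:

    Var[d] = s²_H/n_H + (s²_CC/n_CC + s²_LL/n_LL) / 4,

with a Welch–Satterthwaite df.  A plain one-sample t-test of the hybrid
replicates against the observed midparent scalar is available
(`midparent="one_sample"`), but it ignores the sampling noise of the parent
means: in simulation at 5–10% count CV it miscalls roughly one in five
truly additive clusters as non-additive (additive recovery 0.79 vs 0.95),
which is why the propagated form is the default.

Parent-of-origin effects are summarised by `a′ = (paternal − maternal)/2`
and `d/a′` for sets II and III, where the maternal parent is the first
letter of the hybrid's genotype code (LC = L maternal × C paternal).

## Annotation

Category assignment weights each member read by the same 1/N multimapping
weight as quantification and takes the abundance-weighted fraction
overlapping transposable elements and genes ("majority" = strictly more
than half; a read overlapping both counts for the TE).  Clusters with no
majority take the closest TE or gene within 500 bp of the cluster boundary
(gap distance between interval boundaries, 0 for touching intervals; exact
ties go to the TE) and otherwise are intergenic.  The TE-within-1-kb flag
for genic clusters is measured from the associated gene's interval, not the
cluster interval.  Size classes sum weighted abundance over 20–22 nt vs
23–24 nt reads; ties are "other".  Feature-kind RPKM resolves overlaps by
the precedence TE > CDS > UTR > intron > intergenic and divides weighted
abundance by library depth and the merged (deduplicated) length of the
kind, making it invariant to splitting a feature into adjacent parts.
Pattern-by-category association always reports the hypergeometric upper
tail and the Pearson χ² (no continuity correction) side by side.

## miRNA screen

The highest-expressed read of a cluster (ties: leftmost locus) anchors a
strand-specific 170-nt window centred on the read midpoint (clipped windows
are flagged); minus-strand reads use the reverse complement with the read
offset transformed.  The window is folded by a pluggable backend returning
a dot-bracket structure and an energy; the built-in backend is a
Nussinov-style maximum base-pairing fold (Watson–Crick plus GU wobble,
minimum loop 3) with an energy proxy of −2.0 per pair.  Criteria: energy
≤ −40 (with the proxy backend this applies to the proxy value, which the
criterion reaches at ≥ 20 pairs); ≥ 75% of read bases paired; the star span
(positions paired to read bases) ≤ 1.5 × read length; ≥ 20 nt between read
and star spans; and no pairing inside the read ± 10 nt neighbourhood.  An
external thermodynamic fold (e.g. an RNAfold wrapper) can be supplied
either as a backend callable or as a precomputed structure + energy, in
which case the −40 kcal/mol threshold has its conventional meaning.
Known-miRNA matching scores full Smith–Waterman local alignments
(match +5, mismatch −4, gap open −10, extend −4) against every database
entry; significance is the fraction of 1,000 shuffled-query best scores at
least as large as the observed best (cutoff 0.001).  The shuffle null is
powerless for homopolymer queries (every shuffle is the query itself);
the synthetic hairpins below are such sequences by design, so database
matching is validated on random-sequence fixtures instead.

## GO enrichment

For a study set of n genes in a background of N (default: all genes in the
map), a term with K background and k study carriers scores
P[X ≥ k] under Hypergeometric(N, K, n), including the observed count.
Raw p-values are reported (the downstream semantic-similarity viewers
consume them); BH adjustment is optional.  The annotation map is tested as
given, without propagation up the GO hierarchy.

## Synthetic data

The generator plants clusters at a fixed pitch (span 300 bp, gap 1,400 bp —
wide enough that a planted near-gene TE cannot contaminate the neighbouring
cluster's annotation) across a random-sequence genome.  Each cluster has a
low-parent level `base_expression_rpm` (default 100 RPM) and a high-parent
level `parental_fold_change` × higher (default 4); which inbred is high is
random.  Hybrid means per pattern: additive = midparent, HP/LP = the parent
levels, AHP = 1.5 × HP, BLP = 0.5 × LP, and the between patterns at the
75%/25% quantiles of [LP, HP].  Counts per biological replicate are
negative-binomial with `Var = m + dispersion·m²` (default dispersion 0.1,
typical of small-RNA-seq overdispersion; 0 gives Poisson), and technical
replicates are a binomial split of the biological total, mimicking
resequencing of one library.  Counts are realised as 4 read species per
cluster with Dirichlet-weighted multinomial splits; multimapping species
repeat at their n_loci placements *within the same cluster* under a shared
seq_id, which exercises 1/N weighting while keeping planted genotype means
exact (cross-cluster weight splitting is exercised by handcrafted fixtures
in the test suite).  rRNA decoy reads are emitted and blocklisted.

Planted pre-miRNA loci splice an idealised 170-nt block into the genome:
inert A flanks, a 21-nt G-homopolymer mature arm, a 30-nt A loop and a
C-homopolymer star arm.  Only mature-to-star pairs are chemically possible
in the block, so the designed stem is the unique maximum-pairing structure
and the hairpin ground truth is exact by construction; realistic precursor
sequence diversity is out of scope.

**Pattern benchmark.** `SimulationConfig.pattern_benchmark` fixes the
7 × 200-cluster recovery design: 3/3/4+4 biological replicates, fold
change 4, base 100 RPM at 8 × 10⁶ reads depth, dispersion 0.0025.  The
noise level follows from an a priori power analysis of the decision tree:
the hardest call is separating between-MP-and-HP (at 81% of HP) from HP
itself with a Welch t-test at n = 3 vs 8, which needs a per-sample count
coefficient of variation near 5%; at the generator's general-purpose
dispersion of 0.1 the count CV is bounded below by √0.1 ≈ 32% regardless
of sequencing depth, and the between patterns are then statistically
inseparable from their parent-like neighbours at any fold change (the
noise is multiplicative, so effect size cannot compensate).  At the
benchmark conditions the pipeline recovers ≈ 95% of planted patterns, with
confusions only between adjacent patterns.

What passing the benchmark does and does not show: the generator emulates
replicated, overdispersed, multimapping-aware cluster counts with planted
effects, but not sequencing error, realistic TE/repeat sequence content,
mapping ambiguity between homologous loci, or genome-scale cluster-size
heterogeneity — recovery rates on real libraries will be lower and
depth-dependent.

## Calibration of the differential gate

Under a complete null (three groups from one NB distribution, mean 50,
dispersion 0.1, n = 3/3/4, 1,000 clusters), every discovery is false, so
the per-repeat false-discovery proportion is the indicator of any BH
rejection and its expectation is the gate's realised FDR.  Measured over
many repeats this sits near 5.5–6%: the classical F-test is mildly
anti-conservative in its extreme tail on skewed counts at these group
sizes, which is inherent to running ANOVA on untransformed counts.
Because the per-repeat FDP is Bernoulli, the Monte-Carlo standard error is
≈ √(0.05/repeats); the calibration helper defaults to 2,000 repeats
(SE ≈ 0.5 points) and the acceptance script uses 20,000 (SE < 0.2 points).

## Numerical choices and degenerate inputs

Filter boundary: max ≥ min_rpm keeps.  Cluster boundary: distance < gap
joins, = gap splits.  a = 0 (equal parents) flags d/a as NaN; the pattern
call then rests on the tests alone.  Zero-variance groups short-circuit
t-tests to p ∈ {0, 1} by mean equality.  Hypergeometric bounds are
validated; empty association margins return p = 1 with a warning.  Ties in
top-read selection resolve to the leftmost locus; size-class ties to
"other"; nearest-feature ties to the TE, then leftmost.  All randomness in
the generator, the shuffle null and the calibration flows from explicit
integer seeds.

## Known limitations

The BED dialect is the only alignment input (no SAM/BAM); alignment, read
preprocessing and rRNA reference construction are upstream of the package.
The default fold backend maximises pairing rather than free energy, so its
−40 threshold is a proxy calibrated only for the screen's pass/fail logic
on constructs; thermodynamic folding should be supplied externally when
available.  The hairpin verdict is a conjunction of five criteria and is
not globally monotone in the pairing set: removing pairs can only worsen
the paired-fraction and energy criteria, but can repair the self-pairing
criterion, so monotonicity holds (and is tested) for the monotone
components.  GO enrichment does not propagate annotations along the
ontology graph.
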