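# Methods

`binmap` builds a recombination bin-based genetic map from low-depth
whole-genome-resequencing genotypes of an F2 intercross and maps QTLs on it
from F2:3 line means. This note describes the models, the defaults and why
they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions.

## The genotyping problem

An F2 individual is heterozygous at half its loci in expectation, but at
sequencing depth *k* a heterozygote is called homozygous whenever all *k*
reads happen to show the same allele: with reads drawn independently and
uniformly from the two alleles the miscall probability is

    p_m = 2 · (1/2)^k = 1 / 2^(k−1),

so at the ~2× depth typical of population resequencing half of all
heterozygous calls are wrong, and the observed per-individual heterozygote
proportion drops from the Mendelian 0.5 to 0.5·(1 − p_m) ≈ 0.25. Because
the errors are symmetric between the two parental alleles, averaging over
many markers recovers the regional genotype; the whole pipeline is built on
that observation.

## Marker selection and QC (`markers`)

Variants become markers when they are diallelic, homozygous in parent A,
homozygous in parent B for the opposite allele, and have F2 minor allele
frequency ≥ 0.3 (allele-count convention, (2·n0 + n1)/(2·n_nonmissing)).
Requiring parent B homozygous as well — slightly stronger than parent A
alone — makes the 0/2 coding unambiguous. Genotypes are coded 0 (parent-A
homozygote), 1 (het), 2 (parent-B homozygote), −1 missing, and missing
genotypes are excluded from every proportion, never imputed at this stage.

Per-individual QC reports the proportion of heterozygous genotypes (PHG)
against its depth-model prediction, and a relatedness score: the
centered-dosage (VanRaden) genomic relationship matrix with off-diagonal
coefficients standardized to mean 0, sd 1. In a well-behaved F2 the scores
are approximately Gaussian; the test suite checks this with Shapiro–Wilk on
populations of 60 individuals (1,770 pairs) — at much larger pair counts
the test detects the mild systematic structure of GRM off-diagonals rather
than the qualitative claim.

## Window genotype index (`windows`)

For each individual, a fixed window (default 300 kb) slides along each
chromosome in steps (default 10 kb). Windows are centered on the step-grid
anchors and half-open, `[anchor − w/2, anchor + w/2)`, truncated at
chromosome ends. The genotype index is the mean genotype code over the
window's non-missing markers,

    GI = 0·p0 + 1·p1 + 2·p2 ∈ [0, 2],

and is discretized with deliberately asymmetric thresholds: call 0 when
GI ≤ 0.2, call 1 when 0.2 < GI ≤ 1.8, call 2 when GI > 1.8. Homozygous
regions give GI almost exactly 0 or 2 (homozygotes are read correctly),
while heterozygous regions scatter around 1 with sd ≈ sqrt(0.5/m) for *m*
markers at depth 2, so the wide central band absorbs that noise. A window
needs at least 10 informative (non-missing) markers to be called; anchors
failing that are NA and never interpolated — missing regions are resolved
later at the bin level. The anchor count per chromosome is
`floor(length/step)`.

## Bin partition and distortion filter (`bins`)

A recombination bin is a maximal run of consecutive anchors whose genotype
vectors across the whole population co-segregate. Co-segregation is
NA-tolerant: an anchor joins the current run when every individual called
at both places agrees, and the run's consensus absorbs newly observed
calls. Strict equality would shatter bins at every isolated NA; the cost is
that a bin's consensus stays NA for an individual only when no member
anchor was called there. Bins inherit the physical extent
`[first_anchor − step/2, last_anchor + step/2)`, so bin lengths are
multiples of the step with a 10-kb minimum.

Bins deviating drastically from the 1:2:1 F2 ratio are dropped before
linkage: Pearson chi-square against (¼, ½, ¼) on 2 df, threshold 25
(p ≈ 3.7×10⁻⁶). Per-individual breakpoint detection skips NA runs and
flags direct 0↔2 transitions as double events; correction of such errors
belongs to the linkage stage.

## Linkage and map construction (`linkage`)

**Recombination fraction.** For two bins, the 9-class joint genotype counts
follow the F2 two-locus multinomial. All classes carry a known recombinant
gamete count except the double heterozygote, which mixes the 0-recombinant
and 2-recombinant phase configurations; EM iterates the posterior weight
2r²/(r² + (1−r)²) on that class. The estimate is clamped to [0, 0.5]
(values below 10⁻⁹ are reported as exactly 0) and verified in the tests
against a 10⁻⁴-grid likelihood search. LOD is log10 L(r̂)/L(0.5).

**Map functions.** Kosambi (default; `d = 25·ln((1+2r)/(1−2r))`) or Haldane
(`d = −50·ln(1−2r)`), with exact inverses. Kosambi is the common default of
interval-mapping software; the choice matters little at bin-scale distances.

**Fixed-order chaining and splitting.** Bins are ordered by their reference
coordinates; adjacent distances accumulate into cM positions. The chain is
cut where adjacent bins are effectively unlinked (LOD < 3) or the gap
exceeds 50 cM. Resulting segments become linkage groups — a chromosome may
legitimately yield several.

**Discordant bins and rippling.** Three situations mark bins as unmappable
at their physical rank: (a) a segment smaller than max(4, 5% of the
chromosome's bins) bounded by broken junctions; (b) a similarly small run
bounded on both sides by adjacent gaps > 15 cM, even if weak linkage
remains across the junctions (windows straddling a mis-assembled segment's
boundary blend markers of two chromosomes and can fake weak linkage);
(c) an interior bin whose insertion inflates the local two-interval length
by > 10 cM over the direct flank distance. Each such inquiry bin is
compared against every mapped bin; if the most tightly linked target
reaches LOD ≥ 6 the inquiry is inserted beside it on the side adding the
least map length (flagged *relocated* when its physical chromosome differs
from the group's), otherwise it is left unplaced and logged. This is how
mis-assembled segments find their genetic home.

**Correction and merging.** Iterated to a fixpoint: (1) a bin genotype
differing from two agreeing flanks within 5 cM implies an immediate double
recombination — vanishingly rare without interference — and is replaced by
the flanking genotype; missing bin genotypes are imputed the same way;
(2) physically consecutive bins at identical cM positions (r = 0) merge,
extents uniting and genotypes taken as the non-missing consensus;
(3) distances are re-estimated. The 5-cM window (`dd_max`) will also erase
genuine very tight double crossovers; that loss is accepted. The loop
terminates because every pass either corrects genotypes or removes bins.

**Summaries.** Per linkage group: genetic length, bin count, effective bin
count (bins minus *redundant* bins — those sharing a cM position with their
predecessor, within 10⁻⁹), nominal and effective mean adjacent spacing
(length over adjacent gaps; totals aggregate as total length over total
gaps), physical span from first to last bin, and span coverage of the
chromosome. The regional genetic/physical profile fits a continuous
piecewise-linear genetic-vs-physical curve with 2 or 3 segments by least
squares over breakpoints on the bin grid, selected by BIC; slopes are the
region-wise cM/Mb. Totals are per-group sums; no between-group gap lengths
are added.

## QTL analysis (`qtl`)

**Interval mapping** is Haley–Knott regression. At each scan position
(1 cM grid plus every bin position) the QTL genotype distribution given the
flanking bin genotypes is computed by enumerating the two gametes as
3-locus haplotypes with no-interference transition probabilities (missing
flanks are marginalized). Line means are regressed on the expected additive
dosage x ∈ [−1, 1] (+1 = wild/parent-B homozygote) and the F2:3 dominance
coding z = ½·P(het): an F3 family from a heterozygous F2 parent segregates
1:2:1, halving the family-mean dominance deviation. LOD =
(n/2)·log10(SS0/SS1); PVE = 100·(1 − SS1/SS0); a and d are the regression
coefficients, so a negative additive effect means the wild allele decreases
the trait. A cofactor-free scan is deliberate: the acceptance surface is a
single major QTL, and stepwise cofactor selection adds variance without
benefit there.

**Thresholds and peaks.** The genome-wise LOD threshold is the (1−α)
quantile of the maximum LOD over phenotype permutations (default 1000,
α = 0.05, seeded). Because scan positions at bins carry full genotype
information while between-bin positions are attenuated, the LOD curve has a
fine sawtooth; peaks are therefore the argmax of each contiguous
above-threshold run, thinned to a minimum 20 cM separation. The reported
support interval is the flanking bin pair (genetic range between their
positions; physical range from the left bin's start to the right bin's
end). Estimates from multiple seasons of the same interval are combined by
averaging a, d and PVE. Ordinal scores are analyzed as numeric line means.

**Cross-checks and candidates.** A naive per-marker linear-model scan
(additive + dominance, F-test) serves only to confirm that association
peaks co-locate with interval-mapping peaks — it deliberately omits any
kinship correction. Candidate variants inside a QTL interval must be
homozygous in both parents for different alleles with read depth ≥ 6 in
each, change the encoded amino acid (codon contexts are supplied as
annotation; unannotated sites are indeterminate and never pass), and show
parent A carrying the reference allele (allele-wise, also for InDels).

## Synthetic data generator (`simulate`)

The generator is first-class, tested code; it defines the study conditions
under which everything else is validated.

* **Genome**: default 3 chromosomes × 80 Mb × 150 cM. Each chromosome has a
  piecewise recombination landscape (weights 5 / 0.3 / 6 relative cM/Mb
  over the distal 20 Mb / central 40 Mb / distal 20 Mb, rescaled to the
  chromosome's genetic length) and a matching marker-density profile
  (3 / 0.5 / 3), emulating recombining gene-dense chromosome arms around a
  recombination-suppressed pericentromeric region.
* **Meiosis**: crossover counts per gamete are Poisson(L/100) with uniform
  positions — no interference, the model under which Haldane distances are
  exact and Kosambi nearly so at bin scale.
* **Markers**: 20,000 by default, multinomially apportioned by the density
  profile; population size n = 200.
* **Sequencing**: per marker per individual, depth is fixed k (default 2)
  or Poisson(λ); depth 0 is missing; heterozygote reads are iid uniform
  over the two alleles, reproducing p_m = 1/2^(k−1) exactly; homozygotes
  are read correctly unless a per-read `base_error` is set. The fixed-k and
  Poisson modes are both exposed because real per-marker depth around a ~2×
  average is somewhere between them.
* **Phenotypes**: F2:3 line mean = μ + x·a + z·d + ε with x ∈ {−1,0,+1}
  from the F2 parent, z = ½ for het parents, ε ~ N(0, σ²); optional
  rounding/clipping to an ordinal scale (0–2 or 0–7). The model-implied
  PVE is (a²/2 + d²/16)/(a²/2 + d²/16 + σ²), from Var(x) = ½ and
  Var(z·d) = d²/16; `additive_effect_for_pve` inverts it.
* **Segregation distortion**: single-locus viability selection — an
  individual survives with relative fitness (w0, w1, w2) by its genotype at
  the distortion locus, via rejection resampling.
* **Mis-assembly**: markers physically inside a chosen segment keep their
  (wrong) coordinates but co-segregate with a target chromosome position;
  the truth record keeps the correct home.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: read-level artefacts (mapping bias,
allele-specific capture, duplicated regions), genotype-calling errors that
are asymmetric between alleles, crossover interference, gene conversion,
residual heterozygosity of the parents, shared environment or
block-structured field effects in phenotypes, and multi-QTL or epistatic
architectures. Performance claims (map-length recovery within 15%, ≥95%
bin-genotype accuracy, QTL localization within 5 cM) are claims about this
generative model at the stated sizes.

## Problem sizes used in the test and acceptance runs

Map recovery runs the full pipeline once at the default conditions
(3 × 80 Mb / 150 cM, 20k markers, n = 200, fixed depth 2). The QTL recovery
experiment uses 50 replicates of a bin-level simulation (150 bins per
chromosome, n = 172 lines, PVE 65%, 200 permutations for each threshold);
the null false-positive experiment uses 200 replicates at 200 permutations;
mis-assembly relocation uses 10 seeded full-pipeline runs of a 400-kb
segment. The mis-assembly truth check counts segment-core bins only — bins
whose windows lie fully inside the segment — because bins formed from
boundary windows mix markers of both chromosomes and have no single
correct home.

## Numerical conventions and degenerate inputs

EM runs at most 300 iterations to tolerance 10⁻¹²; distances are capped at
r = 0.4999 to stay finite; log-likelihoods clamp probabilities at 10⁻³²⁰.
Design matrices in the scan are reduced by SVD with a 10⁻¹⁰ relative
singular-value cutoff, so collinear positions (e.g. no heterozygotes) lose
the dominance column instead of overfitting. A constant phenotype yields an
all-zero LOD curve; an all-missing individual is flagged, not dropped
silently; zero-length chromosomes, empty mis-assembly segments and
single-bin linkage groups are all defined no-ops with NA summaries where a
statistic is undefined.
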