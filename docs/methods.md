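# Methods

## Problem and scope

`dnsnvkit` evaluates and refines call sets of *de novo* single-nucleotide
variants (DNSNVs) from father–mother–child trio sequencing. A DNSNV is a
single-base substitution carried by the child but absent from both parental
germlines; at a germline rate of roughly 1–3 × 10⁻⁸ per site per
generation, true events are vastly outnumbered by sequencing, mapping and
genotyping artefacts, so candidate sets produced by trio callers need
characterisation and refinement before interpretation.

The package deliberately models only biallelic SNVs on the 22 autosomes.
Indels, multi-allelic sites and the sex chromosomes are excluded at
ingestion (and counted in a skip log) because the downstream metrics —
substitution class, the fixed-window context metrics and the allele-depth
score — are defined for biallelic autosomal substitutions. Multi-allelic
sites are skipped rather than split: splitting would require dividing the
child's AD field between alternate alleles, an ambiguity the coverage score
does not address.

## Candidate extraction

Candidates are re-derived uniformly from any trio VCF by the standard
Mendelian-violation pattern: both parents genotyped homozygous reference
(0/0) and the child carrying at least one alternate allele (0/1 or 1/1).
Child 1/1 candidates are admitted but flagged (`HOMALT_CHILD` on VCF
output) since a genuine de novo event is expected to be heterozygous;
users who consider hom-alt children implausible can drop them. Records
missing a genotype in any role cannot be classified and are excluded with
a reason count.

## Context metrics

**Window geometry.** All windowed metrics use an even window of length
*w* = 100 centred on the variant, realised as the 1-based inclusive
interval [pos − w/2, pos + w/2 − 1]. An even window cannot be symmetric
about a single base; this fixed convention contains the variant base and is
used everywhere. Windows that overrun a contig end yield a *missing* metric
rather than a rescaled one, because the denominator is fixed at *w* —
silently shrinking it would bias the distribution of the metric near contig
ends. A window containing N likewise yields missing GC content (unknown
bases are neither counted as G/C nor as A/T).

**GC content** is the G+C count of the reference window × 100/*w*, a
percentage in [0, 100] that is integer-valued at *w* = 100. Call sets are
stratified at a 50% threshold (boundary value goes to the high stratum, i.e.
"high" ⇔ GC ≥ 50%), reflecting the empirical pattern that high-GC regions
amplify poorly and accumulate calling errors.

**SNV density** is the count of called SNV positions inside the window
× 100/*w*. The source set is, by default, every SNV carried by the child in
the same pipeline's VCF — de novo plus inherited — with the focal variant
counting itself; this is the most inclusive reading and any position set
can be supplied instead. Densities are summarised as a cumulative
distribution: the fraction of candidates with density strictly below each
bin edge.

**Substitution class.** A substitution is a transition when it stays within
a base family (A↔G among purines, C↔T among pyrimidines) and a transversion
otherwise; of the 12 ordered base pairs, 4 are transitions and 8
transversions, so random errors drive a call set's Ti/Tv ratio toward 0.5
while genuine variation sits well above it. Ratios are reported at 2
decimals (full precision internally) and are undefined ("NA") when the
transversion count is zero.

## The read-coverage score

For a candidate with allele depths father (F_ref, F_alt), mother
(M_ref, M_alt) and child (S_ref, S_alt), define the per-sample separations
f = |F_ref − F_alt|, m = |M_ref − M_alt|, s = |S_alt − S_ref|. Two
groupings are provided:

* **product** (default): score = log₁₀( ((f + m)/2) · s )
* **ratio**: score = log₁₀( (f + m) / (2 s) )

The default is the product form: it increases with *both* the parental
separation (clean homozygous-reference support in the parents) and the
child separation, matching the intuition that coverage signal at the site
should be strong in every sample, and it places typical exome depths (tens
of reads) inside a −3…3 cutoff range on the log₁₀ scale. The ratio form
rewards clean parents *relative* to the child separation, which penalises
candidates whose child depths look nearly homozygous — the signature of a
miscalled genotype rather than a true heterozygous de novo event. Both
groupings are exposed because they detect different failure modes; see
"Filter behaviour under the generative model" below.

A score is undefined exactly when any depth is missing, when s = 0, or when
(f + m)/2 = 0; undefined scores carry machine-readable reason codes
(`missing-depth`, `zero-child-separation`, `zero-parental-separation`) and
are rejected at every finite cutoff. Filtering uses a strict inequality
(score > cutoff) with the non-stringent default cutoff 0 — the point where
the scored quantity equals 1. Ranking is by descending score, undefined
last, ties broken by genomic position for determinism.

## Call-set comparison

Call sets are matched on the exact key (chromosome, position, ref, alt);
allele-aware matching is stricter than positional matching and prevents
counting discordant calls as agreement. For 2–3 sets the report contains
every Venn-region count (they sum to the union size), all pairwise
overlaps, and the common count. The overlap rate against a known-variant
catalog (any VCF; keys extracted the same way) is
100 × |records in catalog| / |records|, reported at full precision and
rounded to integer percent for display; no frequency-based "common variant"
notion is implemented because that depends on catalog-specific annotations.
Genotype-quality (GQ) summaries report per-role order statistics (min, q25,
median, q75, max) and mean over non-missing values, with missing values
counted; GQ is an evaluation metric here, never a filter input.

The package ships a 22-variant consensus fixture (`data/table1_fixture.vcf`)
— the candidates nominated by all three reference pipelines on the GIAB
Ashkenazi trio exomes — encoding chromosome, position and substitution in
their published order (including one out-of-order chromosome-5 row, kept
verbatim), with canonical de novo genotypes, no depths, and gene/phenotype
strings carried as opaque INFO metadata. Re-tallying it yields 22 records,
five on chromosome 14, and an 11/11 transition/transversion split; these
are used as regression values.

## Synthetic trio generator

Real trio data (GIAB BAMs processed by external pipelines) are out of
scope, so evaluation uses a generator whose defaults are the study
conditions and whose every draw is recorded in a truth table.

**Reference.** 22 autosomes of 200 kb each (4.4 Mb total — large enough
that ~2300 planted variants leave windows mostly disjoint, small enough to
regenerate in seconds), each built from a 100 kb segment at 40% GC and a
100 kb segment at 60% GC, the two regimes in which calling behaviour is
compared. Bases are i.i.d. within a segment: G/C with the target
probability (split evenly), A/T otherwise, so a 100-base window's G+C count
is Binomial(100, target) and segment GC is recoverable from variant windows
within binomial bounds.

**Variants.** Default 2000 inherited SNVs, 300 de novo, and spurious
candidates at 10% of the candidate pool (33 sites). Positions are drawn
without replacement, ≥ 50 bp from contig ends so every planted variant has
a defined context window. Substitutions are transitions with probability
2/3 (planted Ti/Tv = 2, the conventional expectation for genuine
variation), otherwise uniform over the two transversions of the reference
base. Inherited sites pick a random carrier parent (het with probability
2/3, hom-alt otherwise) and transmit Mendelianly; de novo sites are parents
0/0, child 0/1; spurious sites are truly 0/0 in all three samples but the
*called* child genotype is 0/1 — a pure genotyping error.

**Depths and GQ.** Per-site per-sample depth ~ Poisson(30); alt reads ~
Binomial(depth, vaf) with vaf = 0.01 (the read error rate) for genotype
0/0, 0.5 for 0/1, 0.99 for 1/1. GQ is synthesised, not derived from
likelihoods: uniform on 60–99 for true variants and shifted down by a
30-point margin for spurious sites, encoding the assumption that a
genotyping error is accompanied by lower genotype confidence. The margin is
a config knob.

**What the generator does not model:** read-level artefacts (no
FASTQ/BAM), mapping and reference bias, GC-dependent coverage, indels,
clustered errors, linkage between neighbouring sites, and genotype
likelihoods. Passing tests therefore demonstrate correctness of the
package's computations and the filter's behaviour *under this model*, not
calling accuracy on real exomes.

## Filter behaviour under the generative model

Under this generator the two score groupings separate different things, and
the package's directional tests are assigned accordingly:

* A true heterozygous de novo site at depth ~30 has a small child
  separation (s ≈ |Binomial(d, ½) − d/2| · 2) and large parental
  separations (f, m ≈ d). The **product** score is then comfortably
  positive whenever s ≠ 0, so filtering at cutoff 0 retains ≥ 90% of true
  planted DNSNVs (the ~7% loss is P(s = 0), ties of the child's binomial
  split); this retention property is asserted at the default settings.
* A spurious site (child truly 0/0, miscalled 0/1) has a *large* child
  separation (s ≈ d), so the product score is high and does not remove it —
  under this generator the product grouping has no power against
  genotyping-error candidates, and no test claims otherwise. The **ratio**
  score compares (f + m)/2 against s, which are equal in distribution at a
  spurious site; with the strict cutoff at 0 the majority of spurious sites
  fall at or below log₁₀(1) and are removed, while true sites
  (s ≪ (f+m)/2) are retained at the same ≥ 90% level. The
  spurious-discrimination and GQ-improvement properties are therefore
  asserted under the ratio grouping, with the product grouping remaining
  the default for its monotone both-samples-strong semantics.
* The filter never inspects ref/alt bases, so the kept set's transition
  fraction stays within binomial sampling error of the input's; Ti/Tv is
  preserved by filtering up to sampling noise.

## Numerical and reporting conventions

Positions are 1-based at every public interface (VCF convention);
chromosome labels accept `chr1`/`1` dialects and normalise to unprefixed
with numeric sort order. Ratios display at 2 decimals, percentages at
integers; JSON bundles serialise full precision with sorted keys and fixed
indentation so reruns are byte-identical. Scores annotate VCFs as `DNSCORE`
(3 dp) with rejected records marked `DNSNV_FAIL` in FILTER. Quantiles use
NumPy's default linear interpolation. All randomness in the generator flows
from one integer seed through `numpy.random.default_rng`; repeated runs are
byte-identical, and every stochastic test fixes its seed and tolerance
(binomial 99% or 99.9% bounds as stated in the test).

## Problem sizes

The default simulated study (4.4 Mb reference, ~2.3k variants) generates in
a few seconds; the test suite uses 4-autosome, 20 kb-chromosome
configurations (80 or 300 planted de novo sites) chosen so binomial
assertions have adequate counts while the whole suite runs in seconds.

## Known limitations

Depths come from VCF AD fields — there is no pileup re-examination, no
realignment, and no genotype-likelihood modelling. The score has no
statistical calibration (no p-value or confidence index); the cutoff is a
unitless log₁₀ threshold whose natural scale depends on sequencing depth.
Overlap analysis treats call sets as exact key sets: near-misses (±1 bp,
allele swaps) are counted as disagreement. The consensus fixture carries no
depth information, so it can be tallied and compared but not scored.
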