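# Methods

This note documents the models and procedures implemented in `gbscall`,
the defaults chosen where the design was open, and what the synthetic data
do and do not establish about real GBS experiments.

## The simulation model

The simulator emulates a demultiplexed single-end GBS experiment on a
population of diploids.

**Fragment space.** Fragments are i.i.d. uniform-random DNA with lengths
uniform on [240, 400] bp. Uniform ≥240-mers are pairwise dissimilar with
overwhelming probability, which models the "unique fragment" assumption of
de novo GBS; real fragment spaces additionally contain repeats and
paralogous families, which this generator deliberately omits (the homolog
filter is instead exercised with constructed paralog-collapse fixtures).

**Variants.** At most one variant per fragment: SNPs (uniform alternate
base) and bi-allelic indels with lengths uniform on [1, 10] bp, stored
left-anchored in VCF convention. Variant anchors are restricted to
[10, 140] on the fragment so that a 150 bp read covers every variant with
flank on both sides; without this margin, undetected variants would
conflate caller misses with simple non-coverage.

**Genotypes.** Each variant draws a minor-allele frequency p uniform on
[0.1, 0.5]; individuals then draw genotypes at Hardy–Weinberg proportions
((1−p)², 2p(1−p), p²). A variant left with no alternate-allele carrier is
resampled so every truth record is in principle discoverable. The defaults
(25 individuals, depth uniform on [20, 30] reads per fragment per
individual, 1.1% per-base substitution error, 150 bp single-end reads) are
the benchmark study conditions; the full-scale published experiment
(100,000 fragments, 35,000 variants, ~60M reads) is reproduced only for
variant induction, while read-level stages run at a 4,000-fragment /
1,400-variant scale that preserves every per-locus quantity (depth, error,
population size) and divides only the number of loci.

**Reads.** Per (individual, fragment): depth d ~ uniform integers; each
read picks one of the individual's two haplotypes (fair coin for hets) and
takes the first 150 bases (paired mode adds the reverse complement of the
last 150). Substitution errors hit each base independently and uniformly
over the three other bases. Quality strings are constant (Q40): the
pipeline's rules are depth-based, not quality-aware. No PCR duplicates,
barcode/adapter remnants, or indel sequencing errors are simulated.

**Randomness.** One integer seed fans out through `numpy.random.SeedSequence`
into independent streams: fragments, variants, genotypes, then one stream
per individual's reads — so per-individual read generation is independently
re-runnable and the whole run is byte-reproducible.

## Mock-reference construction

Reads of the selected individuals (default: the single most read-abundant
individual, the practice that maximises accuracy in the benchmark design)
are exactly dereplicated, then clustered greedily in descending (length,
abundance, lexicographic) order: a sequence joins the first-founded
centroid whose identity, 1 − edit_distance/max(lengths) (unit costs,
edlib), is at least the threshold (default 0.93), else founds a cluster.
Unique sequences supported by fewer than 2 reads may join but not found
clusters; this abundance floor suppresses error-only centroids at the cost
of dropping fragments that happen to yield no duplicated read (the main
Type II contributor at 20–30×, ~3–6% of loci). A q-gram-lemma prefilter
(k = Lmin/(E+1), exhaustive fallback when k < 5) accelerates candidate
search without changing results. Consensus is the count-weighted majority
base per centroid column (ties to the centroid base; all-member-gap
columns dropped); a single base is emitted per column rather than IUPAC
ambiguity codes.

Because identity is global, the two 150 bp haplotype prefixes of a
heterozygous indel individual differ by twice the indel length (the indel
plus the induced end shift); indels > 5 bp in a heterozygous MR individual
therefore split into two centroids and their variant is usually lost
(counted in Type II). This is an accepted property of the global-identity
design, shared with fixed-window de novo pipelines.

## Alignment and pileups

Candidates come from exact k-mer seeds (k = 20, probed at three read
offsets, both strands); each candidate is scored by a banded
(band = 12 > max indel) affine dynamic program with match +1, mismatch −1,
gap open −2, gap extend −1 (a length-g gap costs 2+(g−1)); the read is
aligned end to end, centroid overhangs are free, and read bases running
off the centroid's 3′ end are soft-clipped. A candidate whose gap-free
alignment has ≤ 2 mismatches is accepted without the DP — with this
scoring a gapped alignment can never outscore a ≤2-mismatch ungapped one
over the same span — which keeps the 2.5M-read desk-scale run in minutes.
Reads are reported only when edit distance ≤ 0.1 × read length, and reads
with equally good best hits on more than one centroid are unmapped
(unique-mapping policy, protecting the homolog filter's interpretation).
Indels in accepted alignments are left-normalised against the centroid
before being counted, so every read, the caller and the truth matcher
share one indel normal form. Pileups record per-individual base counts per
column, deletion-spanning depth, and left-anchored indel allele counts.

## Variant calling

Per column the population-wide top alternate allele (a non-reference base
or an anchored indel) is chosen by pooled depth. A site is dropped if any
further allele exceeds a noise floor of max(2 reads, 5% of pooled depth),
or if deletion-spanning reads anchored elsewhere exceed that floor (such
reads support neither site allele and indicate an overlapping event).
Individuals are genotyped from the two site alleles: depth < 6 → missing;
minor-allele depth ≥ 3 and minor fraction ≥ 0.20 → heterozygous; minor
fraction ≤ 0.10 → homozygous for the major allele; anything between is
ambiguous and set missing rather than forced. The two site alleles must
themselves carry the depth floor — depth contributed by reads supporting
neither allele licenses no genotype. Sites are retained when ≥ 75% of
individuals are genotyped, at least one genotyped individual carries the
alternate allele, and both alleles are observed. All thresholds are
configurable; they are conservative choices for 20–30× data, not canonical
values of any published tool.

For an indel allele, reads carrying the event still place the shared
anchor base, so anchor-column base counts include them; reference support
is anchor-base depth minus indel-allele depth.

## Homolog Z-score

Collapsed paralogs produce apparent heterozygotes whose allele depths are
systematically unbalanced (e.g. 3:1 when a variant segregates on one of
two collapsed copies). Pooling reference depth x and total depth n over
all heterozygous individuals, z = (x − n/2)/√(n/4), i.e. the normal
standardisation of binomial(n, ½); |z| > 5 (strict) culls the variant.
Variants without heterozygotes are never culled (no evidence either way).
Pooling across heterozygotes is the default; a per-heterozygote mean-ratio
variant of the statistic (variance Σ 1/(4dᵢ) / H²) is available behind
`method="mean"` since the phrase "mean allele depth ratio" admits both
readings — the two agree exactly when depths are equal. At pooled n in the
hundreds the normal approximation and the exact binomial two-sided tail
classify identically away from the threshold boundary; an exact-binomial
classifier is provided for verification. A fixed difference between two
collapsed paralogs shows 1:1 depths in every individual and is *not*
culled by the Z-score — only heterozygosity-wide imbalance is.

## Ploidy inference

For each individual the alternate-allele fractions at its heterozygous
calls (depth ≥ 10) are scored under three fixed-mean Gaussian mixtures —
means {½} (diploid), {⅓, ⅔} (triploid), {¼, ½, ¾} (tetraploid) — with
free weights and a shared variance fit by EM. Because the tetraploid mean
set contains ½, its maximum likelihood can never fall below the diploid
model's; raw likelihood therefore cannot select the simpler model, and the
reported best model is chosen by BIC (k free parameters = k−1 weights + 1
variance), with the full log-likelihood table retained. Fewer than 30
ratios yields an "insufficient data" report. One caveat discovered during
development: at the mock-reference individual's own het sites the
consensus picks its majority haplotype, so that individual's ratios are
selection-biased low (~0.42 rather than 0.50 at 25×); the bias does not
move the mixture-model choice but is visible in raw ratio summaries.

## Evaluation

Each centroid is anchored to a source fragment by shared-k-mer vote
verified at ≥ 0.9 identity (infix alignment); the alignment path provides
a coordinate projection and the net insertion/deletion shift of the
centroid relative to the fragment. Calls are projected into fragment
coordinates; when the centroid was assembled from an alternate-allele
carrier the call's REF/ALT are swapped relative to the fragment, so
alleles are re-anchored to the fragment frame first — for indels the
swap decision uses the net projection shift around the call (string
matching is ambiguous when an insertion duplicates adjacent reference
sequence). A call validates if it hits a truth record at the exact offset
(SNPs) or within ±2 bp after left-normalisation (indels) with matching
allele pair; each truth record validates at most one call (greedy,
position-ordered). A call whose alleles are genuinely swapped relative to
truth after re-anchoring does not validate. Metrics:

    Type I   = 100 (called − validated) / called
    Type II  = 100 (simulated − validated) / simulated
    accuracy = 100 validated / (simulated + (called − validated))

displayed at one decimal; full precision is kept internally. Genotype
concordance at validated sites (hom classes flipped for swapped calls,
missing excluded) is reported as a separate diagnostic.

## Numerical and engineering choices

- Coordinates are 0-based half-open internally; 1-based only in SAM/VCF.
- Identity-threshold comparisons add a 1e−9 epsilon before flooring edit
  budgets so pairs at exactly the threshold are kept.
- The banded DP is numba-compiled; a pure-Python unbanded affine DP serves
  as its oracle in the test suite, and banded and unbanded scores agree
  whenever the true edit distance is below the band.
- EM for the ploidy mixtures runs at most 200 iterations to a 1e−8
  log-likelihood tolerance with the shared variance clamped to
  [1e−6, 0.25].
- Degenerate inputs: empty call sets produce header-only VCF/TSV; variants
  with no heterozygotes carry NaN Z-scores and are retained; clustering an
  empty read set yields an empty mock reference.

## What passing tests show — and what they do not

The synthetic data exercise the full pipeline under controlled truth, so
the suite demonstrates internal correctness (depth conservation, format
validity, determinism, oracle equivalence) and recovery performance under
the stated study conditions. They do not demonstrate robustness to real
GBS phenomena absent from the generator: repeat families and true
paralogs (beyond the constructed fixtures), PCR duplicates, variable
fragment recovery across individuals, quality-correlated errors, indel
sequencing errors, or barcode bleed. Reported accuracies are therefore
upper bounds with respect to those artifacts.

## Problem sizes used in the shipped analyses

Variant induction is checked at the full published scale (100,000
fragments, 25,000 SNPs + 10,000 indels). The end-to-end accuracy
experiment runs at 4,000 fragments / 1,000 SNPs + 400 indels / 25
individuals / 20–30× / 1.1% error — the per-locus regime of the published
benchmark with fewer loci — chosen so the whole experiment, and the test
suite around it, completes in minutes on a single CPU.
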