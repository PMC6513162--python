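# gbscall

A self-contained toolkit for *de novo* variant calling from
genotyping-by-sequencing (GBS) data, together with a GBS read simulator and
a truth-based evaluation harness.

GBS sequences a reduced representation of the genome: restriction fragments
shared across a population, each covered by a stack of short reads. When no
reference genome exists, reads can be clustered into a **mock reference**
(MR) of consensus fragments, and variants called against it. This package
implements that whole loop:

1. **simulate** — generate a synthetic fragment space, induce SNPs and
   bi-allelic indels (at most one per fragment), assign Hardy–Weinberg
   genotypes to a population and emit per-individual FASTQ reads with a
   configurable per-base error, recording complete truth tables;
2. **mockref** — dereplicate reads, greedily cluster them at a sequence
   identity threshold (identity = 1 − edit distance / max length) and emit
   one count-weighted majority consensus per cluster;
3. **align** — map reads back to the MR with a k-mer seeded, banded,
   affine-gap aligner (match +1, mismatch −1, gap open −2, extend −1;
   unique-mapping policy) and accumulate per-individual pileups;
4. **call** — call bi-allelic SNPs and indels from within-individual depth
   rules and across-population filters; emit a genotype matrix, a variant
   description table and VCF 4.2;
5. **filter-homologs** — flag likely paralog-collapse ("homolog") variants:
   pooling allele depths over heterozygous individuals, the deviation of
   the ref:alt ratio from 1:1 is standardised against binomial(n, ½),

   &nbsp;&nbsp;&nbsp;&nbsp;*Z* = (*x* − *n*/2) / √(*n*/4),

   and variants with |*Z*| > 5 are culled;
6. **ploidy** — score each individual's distribution of het allele-depth
   ratios under fixed-mean Gaussian mixtures at {½}, {⅓, ⅔} and
   {¼, ½, ¾} (EM with free weights, shared variance; selection by BIC);
7. **evaluate** — anchor MR centroids back to their source fragments,
   match calls one-to-one against truth and report
   Type I = 100·(called − validated)/called,
   Type II = 100·(simulated − validated)/simulated, and
   accuracy = 100·validated/(simulated + non-validated).

## Worked example

A small end-to-end run from the shell:

```bash
gbscall run-all --seed 11 --out-dir demo
```

prints (numbers from this exact command):

```
centroids=3845 calls=1286 retained=1286 culled=0
TypeI=0.6% TypeII=8.7% accuracy=90.8% concordance=0.9979
```

meaning: from 4,000 simulated fragments the MR recovered 3,845 consensus
centroids; 1,286 variants passed the caller's filters and none was flagged
as a homolog artifact (the simulation contains no paralogs); 0.6% of calls
could not be validated against truth (false positives), 8.7% of the 1,400
simulated variants were missed (mostly fragments whose reads left no
duplicate-supported cluster founder, plus heterozygous large-indel
fragments whose two haplotypes split into separate clusters), for an
overall accuracy of 90.8%; per-individual genotypes agreed with truth at
99.8% of validated sites.

Each stage is also available separately (`gbscall simulate`, `mockref`,
`align`, `call`, `filter-homologs`, `ploidy`, `evaluate`, `vcf`) so
per-individual work can be re-run independently; see `gbscall --help`.

From Python:

```python
from gbscall import RunConfig, run_pipeline
from gbscall.sim import SimConfig

res = run_pipeline(RunConfig(sim=SimConfig(seed=11)), "demo")
print(res.report)          # counts, Type I/II, accuracy
print(res.ploidy_best)     # per-individual ploidy model choice
```

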