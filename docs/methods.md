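# Methods

## Model

At a heterozygous SNV covered by ChIP-seq reads, let `n` be the number of
informative reads (those showing the reference or the alternative allele
with sufficient base quality) and `k` the number supporting the reference
(G1) allele. Absent allele-specific binding, each read is equally likely to
come from either haplotype, so `k ~ Binomial(n, 1/2)`. Allele-specific
binding shifts the per-read success probability away from 1/2; the pipeline
scores every site with an exact two-sided binomial test and controls the
false discovery rate across sites with the Benjamini–Hochberg step-up.

The two-sided p-value uses the minimum-likelihood convention: the sum of
`P(X = i)` over all outcomes whose probability does not exceed `P(X = k)`,
with a `1e-7` relative slack on the density comparison to absorb
floating-point ties between symmetric outcomes. When the observed outcome is
the mode the test returns exactly 1. For the symmetric null this convention
coincides with doubling the smaller tail (capped at 1) and with
`scipy.stats.binomtest`, which the test suite uses as an independent
cross-check; the implementation itself enumerates the pmf directly.

Selection is on BH-adjusted values, `q < alpha` with `alpha = 0.05`:
correction precedes selection. `alpha = 1.0` is treated as the vacuous
threshold and selects every tested site even though q-values are capped at
1. Raw-p selection is available (`method="raw"`) for sensitivity analysis.

## Pipeline order and design choices

Stages run as: count → discard uncovered → binomial test → FDR selection →
allele-frequency intersection → region exclusion → LD proxy linking. The
exclusion filters prune the *selected* AS-SNP list rather than the testing
universe; filtering first would change the multiple-testing universe, so the
alternative order is only available behind an explicit flag
(`filter_before_test`). The FDR correction applies within one counts table;
combining experiments means concatenating their counts before testing.

**Alternative genome.** G2 is G1 with each SNV's alternative allele
substituted in place. Indels are rejected: they would break the shared
coordinate system that per-position counting assumes. A ref-allele mismatch
between the SNP set and the reference aborts the build — it signals
miscoordinated inputs that would silently corrupt every downstream count.

**Counting.** A read votes for the allele its base shows at the SNP,
provided base quality ≥ 20 and mapping quality ≥ 20 (both conventional
defaults, both configurable). Duplicate-marked and secondary/supplementary
alignments are skipped so each fragment votes once. Under the dual-genome
policy the G1 and G2 alignments are pooled and a read is counted at most
once per SNP (the observed base is identical in both alignments because G2
differs only at substituted positions). Counting streams the alignment files
sequentially with a sorted-position lookup, so no index is required and
plain-text SAM works. "No coverage" means zero *informative* reads in total
(`min_total = 1`): requiring reads on *each* allele would discard exactly
the monoallelic sites that are the strongest AS candidates.

**Region exclusion.** Intervals are 0-based half-open (BED convention); VCF
positions convert once at the readers. Assembly-gap intervals are padded
±1 Mb (covering pericentromeric and peritelomeric sequence), blacklist
intervals ±100 bp, CNV intervals not at all — CNV calls already delimit the
copy-number-variable segment, and an allelic-ratio shift inside one is the
artefact itself, not a neighbourhood effect. Gap types are not subset; the
whole gap track is used. A SNP exactly at a padded interval's end coordinate
is outside it.

**LD.** r² is computed from phased haplotypes in count form,
`(n·n_AB − n_A·n_B)² / (n_A(n−n_A)·n_B(n−n_B))`, which is exact integer
arithmetic up to the final division — perfect LD yields exactly 1.0. There
is no EM phasing of unphased genotypes: the panel is an input, phased by
construction. The proxy threshold is inclusive (`r² ≥ 0.8`) with a strict
mode behind a flag; an AS-SNP identical to a catalog SNP links with r² = 1
without consulting the panel. Monomorphic panel columns raise an error
rather than returning a value, since LD is undefined there.

## Synthetic data generator

The generator emulates the statistical structure of allele-specific
ChIP-seq over one diploid sample:

- **Reference** — uniform random A/C/G/T contig.
- **Het SNVs** — positions drawn without replacement, ≥ `read_length` from
  the contig ends and ≥ `read_length` apart. The spacing constraint makes
  every read overlap at most one site, so the truth table's conservation
  property (true G1 + G2 counts = reads overlapping the site) holds exactly
  without modelling multi-SNP haplotypes.
- **Reads** — per-site depth is Poisson(`mean_depth`) (standard shotgun
  coverage assumption; keeps zero-coverage sites possible so the discard
  rule is exercised). Each read starts uniformly among positions covering
  its site, carries the G1 allele with probability `imbalance_map[site]`
  (0.5 when absent; values must be strictly inside (0, 1)), then each base
  errs with probability `error_rate`, substituting uniformly among the three
  other bases. Reads are single-end, fixed-length, indel-free; strand is
  simulated but SEQ is stored reference-strand per the SAM convention, so
  orientation never affects counting. The truth table records each read's
  pre-error allele of origin.
- **Exclusion tracks** — a chosen fraction of sites is covered by small
  intervals assigned to gap/blacklist/cnv. Synthetic paddings default to
  1000/100/0 bp — contig-scale stand-ins for the genome-scale 1 Mb/100 bp/0
  rules, which would swallow a whole test contig. Membership of *every* site
  in every padded track is recomputed and recorded, so spillover onto
  neighbours of masked sites is part of the truth.
- **Haplotype panel** — the index column has allele frequency exactly 0.5
  (hence the even, ≥ 20 panel size); a partner targeting r² = t copies the
  index allele with probability `(1 + √t)/2`, giving correlation √t in
  expectation, and t = 1 degenerates to an exact copy. Realized r² is
  computed with the same estimator the LD stage uses and stored in the truth
  table, so generator and pipeline cannot drift apart.

What the generator does **not** model: PCR duplicates, GC bias,
fragment-length effects, paired ends, indels, mapping errors or true
reference bias (alignment is simulated as exact placement). Passing tests
therefore demonstrate the correctness of counting, testing, filtering and
linking logic under the binomial read-sampling model — not robustness to
alignment artefacts in real libraries.

## Standard scenario and problem sizes

The end-to-end scenario plants 500 het sites (20 allele-specific with
imbalance drawn in [0.75, 0.9] toward either allele, 480 balanced nulls) on
a 2 Mb contig, 36 bp reads at mean depth 60, error rate 0.002 (typical
short-read substitution error). A quarter of sites are directly covered by
exclusion intervals; padding spillover brings total masking to roughly 30 %.
Each planted AS site gets one GWAS catalog partner with a 1000-haplotype
panel targeting r² = 0.9. These sizes keep a 20-seed recovery run and the
full test suite in the tens of seconds while leaving ample power (exact
power at depth 60, imbalance 0.75 is ≈ 0.97 by enumeration).

Calibration checks (type-I at imbalance 0.5, Poisson depth 30; power at
imbalance 0.8, fixed depth 50) use 2000 sites drawn at the count level by
the same two-stage model as the read simulator, without materialising reads.

## Numerical notes

- All randomness derives from one integer seed through named substreams
  (`numpy.random.default_rng([seed, stream, ...])`); identical config + seed
  reproduces byte-identical outputs, including FASTQ/SAM files.
- BH adjustment is the vectorised step-up (sorted quotients, suffix running
  minimum, cap at 1), order-preserving, with ties handled by the standard
  convention (tied values share the post-minimum value).
- The vectorised binomial test groups sites by depth and reuses one pmf per
  depth; its masked summation order matches the scalar implementation
  bitwise.
- Selection sorts by q, then by |allelic ratio − 0.5| descending — the
  G1-based ratio fixes which allele a factor prefers (ratio > 0.5 means the
  reference allele is favoured).

## Known limitations

- No beta-binomial overdispersion: replicate or peak-level variability
  beyond binomial sampling will inflate significance on real data.
- The dual-genome handling assumes coordinate-identical alignments (true
  for SNV-substituted genomes); it is a mask against reads unmapped in both,
  not a WASP-style remap filter.
- No phasing: G2 carries every alternative allele regardless of haplotype.
- LD requires a phased panel input; there is no population-specific default
  and no live proxy-service lookup.
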