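# Methods

This note documents the models, conventions and design choices behind
`rohetscan`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Run detection: the consecutive scan

Runs are detected per animal and chromosome by a left-to-right scan of
zygosity states (HOM / HET / MISS), without a sliding window. A candidate
window is **valid** when all of the following hold:

* its first and last SNP are in the target state (homozygous for ROHom,
  heterozygous for ROHet) — opposite or missing calls never sit at the ends;
* it contains at least `min_snp` target-state SNPs;
* it contains at most `max_opposite` opposite-state and `max_missing`
  missing calls (strictly inside);
* no two map-adjacent SNPs inside it are more than `max_gap_bp` apart
  (default 1 Mb) — a larger gap always terminates a candidate, regardless
  of remaining budgets;
* its physical span, `end_bp − start_bp`, is at least `min_length_bp`
  (default 1 Mb). Run length is defined as `end − start`, not `end − start
  + 1`; this only affects class-boundary cases.

The emitted run set is the **greedy leftmost-longest** selection: the first
run starts at the earliest target-state SNP admitting any valid window and
extends as far right as validity permits; scanning resumes after it. For a
fixed start every constraint is monotone in the right endpoint, so "the
longest valid window at this start" is well defined; the implementation
uses prefix counts and binary searches instead of rescanning, and the
test-suite holds it to exact agreement with a brute-force enumerator
(all O(n²) windows, declarative validity, greedy selection) on randomized
instances of both parameter families. Chromosomes are processed
independently; runs never span chromosomes or overlap within an animal.

Ties and restart behaviour are convention, not biology: published
consecutive-scan implementations do not document them. Fixing
leftmost-longest with restart after the emitted run makes outputs
deterministic and, for zero-budget parameters (classic ROHom), coincides
with "maximal homozygous stretches that satisfy the count/length/gap
constraints".

## Parameter derivation

The minimum number of target-state SNPs is set so that the expected number
of *chance* runs across the whole panel is controlled at a false-positive
rate α (default 0.05):

    n_snp = ceil( ln(α / (n_s · n_i)) / ln(1 − q) )

where `n_s` is the number of SNPs per individual, `n_i` the number of
individuals, and `q` the per-SNP probability of an interrupting state —
the panel mean heterozygosity for ROHom, the mean homozygosity for ROHet.
The ceiling guarantees the rate stays ≤ α (the printed reference values for
cattle chips, 50 and 18, are consistent with either ceiling or nearest
rounding; ceiling is the conservative choice). Mean heterozygosity is
computed after quality control, over all non-missing calls.

Because heterozygous genotypes are the rarer state, ROHet additionally
tolerate homozygous calls inside the run, budgeted by the ratio of the two
thresholds rounded to the nearest integer (half away from zero):
`max_opp = round(n_snp_ROHom / n_snp_ROHet)`; 50/18 → 3. Missing calls are
not tolerated inside either run kind (`max_missing = 0` by default).

## Quality control

Filter chain, in order: (1) non-autosomal SNPs dropped (default autosome
set "1".."29", cattle); (2) samples with call rate ≤ 95% dropped; (3) SNPs
with call rate ≤ 95%; (4) SNPs with MAF ≤ 0.01; (5) SNPs with exact HWE
p < 1e-6. Samples-before-SNPs mirrors PLINK's mind → geno → maf → hwe
convention; inequalities are strict in the directions stated. The HWE test
is the two-sided exact test (Wigginton, Cutler & Abecasis 2005): the
recurrence-built conditional distribution of heterozygote counts given
allele counts, p = mass of outcomes no more likely than the observed table
(plain probability ordering, no mid-p), computed on all retained samples.
A relative tie-guard of 1e-9 absorbs float rounding when two heterozygote
counts are analytically equiprobable. The test-suite checks the recurrence
against direct log-factorial enumeration, exhaustively for all tables with
up to 200 individuals.

## Coefficients and summaries

`F_ROHom` (inbreeding) and `D_ROHet` (diversity) are each animal's total
run length divided by the genome length covered by SNPs — the sum over
autosomes of (last − first SNP position); chromosomes with fewer than two
SNPs contribute zero. Run-length classes are left-closed, right-open bins
[1,2), [2,4), [4,8), [8,16) and [16,∞) Mb. Dataset tables report mean ±
sample SD (ddof = 1); the per-animal run count is summarised over animals
with at least one run, matching the convention of reporting an "Animals"
column smaller than the genotyped count. "Average size" is the mean over
runs (not over per-animal means).

Cross-density comparisons use classical one-way fixed-effects ANOVA
(scipy) with pairwise Welch t-tests under Bonferroni correction at
α = 0.001 rendered as a compact letter display — Welch + Bonferroni is a
deliberate, simple substitute for Tukey-type post-hocs. LD is measured as
the squared Pearson correlation of genotype dosages (0/1/2,
pairwise-complete over non-missing animals) for all intra-chromosomal
pairs up to 1 Mb apart, averaged in distance bins. Dosage r² replaces
EM-haplotype r² because phase is unavailable from chip genotypes alone;
conclusions drawn from it should be directional, not quantitative.

## Sharing statistics

* **Repeated regions**: runs with *exactly* identical (chromosome, start,
  end) in ≥ 2 animals; the "most shared" subset keeps regions whose sharing
  count reaches the nearest-rank 99.9th percentile of the sharing
  distribution (ties included).
* **Incidence**: per SNP, the number of animals with a run covering it
  (counts, with percentages exported alongside).
* **Islands**: SNPs *strictly exceeding* the nearest-rank 99th percentile
  of the within-dataset incidence distribution (zeros included), merged
  along a chromosome while consecutive members are ≤ 1 Mb apart (the run
  max-gap scale). Nearest-rank semantics keep thresholds reproducible
  integers; raising the percentile can only shrink islands.
* **Annotation/enrichment**: features (genes, QTL) are reported when their
  interval intersects a region extended by ±250 kb; category
  over-representation uses the hypergeometric upper tail with Bonferroni
  correction at 0.05. This is a declared, transparent substitute for
  black-box enrichment tools.

Intervals are 1-based inclusive internally; BED exports convert to 0-based
half-open.

## Synthetic data

The generator emulates a multi-density cattle genotyping study at desk
scale. Defaults (the study conditions of the test-suite and the numbers
quoted in the README):

| parameter | default | rationale |
| --- | --- | --- |
| animals | 200 | a few hundred, typical of single-breed panels |
| genome | 5 × 40 Mb autosomes | desk-scale stand-in for 29 autosomes / 2.5 Gb |
| HD density | 100 SNP/Mb (20k SNPs) | keeps 800k-class inter-SNP spacing (~10 kb) |
| tier fractions | HD 1.0 / MD 0.19 / LD 0.075 | mirrors 583,637 / 113,042 / 43,431 retained SNPs |
| allele frequencies | Beta(2,2) | mean heterozygosity 0.4, array-like common variants |
| planted ROHom | 11 segments, 1.2–10 Mb, carriers ≤ 25% | expected per-animal fraction exactly 0.05 |
| planted ROHet | 3 segments, 1.8–2.5 Mb, `het_prob` 0.9 | heterozygosity-rich, not perfectly heterozygous |
| missing rate | 0.0 | see below |

Background genotypes are Hardy–Weinberg draws per SNP; positions are sorted
uniform draws. Autozygosity is planted by **haplotype self-copying** (both
alleles copied from one sampled haplotype), which creates true IBD-like
homozygous tracts without coalescent machinery. Segments flagged
`identical` share one haplotype across carriers and receive sharp
breakpoints (the flanking SNP is forced heterozygous), so detected runs
have identical coordinates across carriers — the raw material of
repeated-region statistics. Carrier fractions are capped at 0.25 both for
realism (observed sharing of top repeated regions is ~10%) and because a
homozygous segment shared by much more of the sample depresses local
heterozygosity enough to fail the exact HWE filter, which would remove the
very markers the experiment needs.

Missingness is configurable but defaults to zero in the study conditions:
the adopted run definitions allow **no missing call inside a run**, so any
missing genotype inside a true segment splits it by definition. Keeping
the default experiment missingness-free isolates the density effect being
studied; QC and scanner behaviour under missingness are exercised
separately in the unit tests.

Ground truth records, per planted segment and carrier, both the planted
interval and its *realized* anchors — the first and last target-state SNP
inside the plant on a given panel — recomputable on any QC'd or thinned
panel (`realize_on`). Recovery is scored against realized anchors because
they are what the genotypes actually contain.

What the generator does **not** emulate: background LD structure (markers
are independent given allele frequencies), ascertainment bias beyond the
Beta law, pedigree structure, genotyping error, and chromosome-scale
heterogeneity. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative density behaviour, not calibrated estimates
for any real breed.

## Recovery semantics and known limitations

A planted instance is *detectable* on a panel when its realized window is
itself a valid run window there (enough surviving informative markers,
span, budgets, gaps). For zero-budget ROHom, every detectable instance is
covered by a detected run to within one local inter-SNP spacing at each
end — a run cannot stop inside an all-homozygous tract. Detected runs
routinely *over-extend* into flanking chance-homozygous background (each
flanking SNP continues the run with probability ≈ the background
homozygosity, ~0.6), which is expected consecutive-scan behaviour, slightly
inflates mean lengths at sparse densities, and is why recovery is scored as
coverage shortfall rather than two-sided boundary error.

For budgeted ROHet one shortfall mechanism exists: a run may anchor in
heterozygous-leaning background *upstream* of the plant, spend its opposite
budget there, and legitimately end mid-plant; the remainder can be too
short to stand alone. The acceptance tests assert that every detectable
ROHet instance is detected, that shortfalls beyond one spacing occur only
via this mechanism, and that they stay rare (< 20%). This is a property of
the consecutive method itself, not of the implementation — mirroring the
field's caveat that heterozygosity-rich regions "are not true runs".

Other limitations: the scanner's tie-breaking is validated against the
package's own declarative oracle, not against external tools; dosage r²
understates haplotype r²; the enrichment background must be supplied by the
user (no bundled annotation databases); and the density-direction
experiment uses a majority-of-seeds criterion because individual seeds can
produce ties at adjacent tiers.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (simulation, thinning,
pipeline), and pipeline outputs are a pure function of (inputs, config,
seed) — reruns are byte-identical. The default test-suite and acceptance
experiments use the desk-scale conditions above (200 animals × 20k SNPs,
10 seeds for the density experiment; smaller panels for unit fixtures),
chosen as the package's own reference configuration so the full suite runs
in about a minute.
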