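# Methods

## The problem

Before replicated RNA-seq designs became standard, differential expression
between two conditions was commonly assessed from exactly two sequencing
libraries — one per condition — by treating each gene's read counts as
Poisson draws and asking whether the pair of counts is consistent with equal
underlying expression. `twolib` implements that workflow for a two-library
elicitation experiment (a mock-treated and a treated transcriptome of
cultured plant cells): expression quantification, the exact two-library
test, FDR-thresholded gene calling, and the assembly/read QC statistics
such studies report, together with seeded simulators that make every stage
testable without raw sequencing data.

## The exact two-library test

Let N1, N2 be the total read counts of libraries A and B, and x, y one
gene's counts in each. Under the null hypothesis of equal expression, the
count in B conditional on the count in A has mass

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

This is a negative-binomial distribution in y with x+1 successes and
success probability s = N1/(N1+N2), which is how the package evaluates
cumulative sums: `scipy.stats.nbinom.cdf/sf` (regularized incomplete beta),
numerically stable in both tails with no term-by-term cancellation. The
point mass itself (`ac_probability`) is evaluated in log space via the
log-gamma function, so counts of 10^6 and beyond neither overflow nor
underflow prematurely.

The two-sided p-value doubles the smaller tail. With F = Σ_{i≤y} p(i|x):

* p = 2F when F ≤ 0.5 (the boundary F = 0.5 takes this branch and yields
  exactly 1);
* p = 2(1−F) otherwise, where 1−F is the *strict* upper tail P[i > y] — the
  point mass at y stays in the lower tail. This is the literal doubled-tail
  rule; it differs from point-inclusive or mid-p variants, which would add
  back all or half of p(y|x) and give smaller complements. p-values are
  clamped into (tiny, 1] (tiny = smallest positive normal double) so
  downstream log transforms stay finite.

Counts must be integers; fractional "counts" are rejected rather than
rounded, because the mass function is defined on integers only.

### FDR control

The false discovery rate — the expected fraction of false positives among
genes declared significant — is controlled with Benjamini–Hochberg step-up
q-values (q_(i) = min_{j≥i} m·p_(j)/j), delegated to
`statsmodels.stats.multitest.multipletests` behind `bh_fdr`. BH is the
standard realization of the "keep V/R below a cutoff" requirement when no
specific step-up/step-down recipe is prescribed. q-values are invariant to
p-value tie order, so output is reproducible without explicit tie-breaking.

## Expression quantification and the decision rule

RPKM = 10^9 · C / (N · L) for count C, library depth N and transcript
length L (bases); a zero count maps to exactly 0. Fold change is
log2(RPKM_b / RPKM_a); length cancels within a gene, so this equals the
count ratio rescaled by N2/N1 — whether a study applied its fold-change cut
to RPKM or to rescaled count ratios is therefore immaterial per gene.

Zero handling: the default floor substituted for a zero RPKM is the RPKM a
*single read* would earn on that gene in the shallower library
(10^9 / (min(N1,N2) · L)). This keeps ratios finite and depth-aware — a
zero in a deep library is stronger evidence of absence than a zero in a
shallow one. The floor is overridable per run.

A gene is a DEG when q ≤ 0.001 **and** |log2 ratio| ≥ 1, boundaries
inclusive. Both cutoffs are `RunConfig` parameters.

qRT-PCR validation data is summarized with the comparative threshold-cycle
method: fold change = 2^−ΔΔCt, with ΔΔCt = (Ct_target − Ct_reference)
difference between treated and control samples, on replicate-averaged Ct
values (replicate-level error propagation is out of scope). Ct values
outside 5–40 cycles warn but are accepted.

## Assembly and read QC statistics

* **N50**: sort lengths descending, accumulate, return the first length at
  which the running sum reaches half the total bases (≥, not >) — so
  sequences of length ≥ N50 always contain at least 50% of assembled bases,
  and the N50 is always an observed length.
* **Gap ratio**: fraction of N characters in a scaffolded sequence
  (scaffolding writes N runs across unsequenced gaps between joined
  contigs); `gap_ok_fraction` counts sequences *strictly below* a threshold
  (default 5%).
* **Q20**: percentage of bases with Phred quality ≥ 20. The standard Q20
  convention is ≥; a `strict_greater` flag gives the literal "> 20"
  reading. Default Phred offset is 33, with 64 selectable for
  early-Illumina data.
* **GC / N percentages**: N bases are excluded from the GC numerator but
  included in every denominator. Lowercase input is normalized; IUPAC
  ambiguity codes other than N count as non-GC, non-N by default, and a
  strict mode rejects them.
* **Length bins** are half-open [e_i, e_{i+1}); percentage summaries
  (`rate_summary`, `proportion_at_least`) round half-up at two decimals
  (one-decimal mode available), computed in exact rational arithmetic so no
  binary-float artifact can flip a boundary case.

One data remark: among published annotation-rate percentages used as worked
examples, two printed values (90.7% and 96.71%) do not recompute from their
own printed count pairs (4113/4546 = 90.47%, 2785/2880 = 96.70%); the
worked-example suite covers only the pairs that recompute exactly.

## Synthetic data

`simulate_counts` draws transcript lengths and baseline abundances from
log-normals, assigns a DE fraction across effect classes, and samples
counts as independent Poissons with expectation
λ = lib_size · (abundance · length) / Σ(abundance · length), matching the
test's own null model. Defaults (the stated world of the emulated design):

| parameter | default | why |
|---|---|---|
| n_genes | 2000 | desk-scale version of a ~4·10^4-unigene assembly |
| lib_size_a/b | 29 460 / 29 896 | the emulated study's read totals scaled by 10^3 |
| baseline log-sd | 1.5 | typical bulk RNA-seq dynamic range (several orders of magnitude) |
| de_fraction | 0.10 | the simulation examples' stated DE share |
| effect classes | 2.5 and 1.25 log2, equal weight | mirrors the strong vs slight induction split of the worked-example pathway genes |
| length log-mean/sd | log 744 / 0.45 | mean unigene length of the emulated assembly |

Two deliberate design choices:

* **Symmetric effect application.** Read counts are compositional: adding
  DE mass to one condition and renormalizing shifts the relative abundance
  of *every* gene by the total-mass change, biasing estimated ratios by
  log2 E[2^lfc] > 0 for any sign-symmetric effect distribution. The
  generator therefore applies each effect as ×2^(+lfc/2) in condition B
  and ×2^(−lfc/2) in condition A (the B:A abundance ratio is still
  2^lfc) with exactly balanced signs, keeping the two library compositions
  exchangeable. Without this, per-gene ratio recovery and
  column-sums-match-library-size cannot hold simultaneously.
* **Poisson by default.** The exact test's null is Poisson; the default
  generator matches it so type-I calibration tests the test, not the
  generator. A gamma-Poisson `dispersion` option exists to demonstrate the
  anti-conservativeness of no-replicate testing on overdispersed data; it
  is an extension, clearly not the null world.

`simulate_fasta` draws per-record gap ratios from a two-component uniform
mixture (85% below the 5% threshold by default) and writes each gap as one
interior N run; the truth table records the realized integer-rounded ratio.
`simulate_fastq` draws per-base qualities with P(Q ≥ 20) equal to the Q20
target (high scores uniform 20–40, low 2–19) and base identity with
P(G or C) and P(N) at their targets.

Reproducibility: every generator takes one root seed and spawns independent
substreams with `numpy.random.SeedSequence` in a fixed documented order
(lengths, abundance, effect assignment, counts), so identical arguments
give byte-identical outputs. TSV outputs carry the seed in a `# seed=`
comment header; FASTA/FASTQ have no portable comment syntax, so the CLI
records the seed in the run log written next to them.

### What a green test does and does not establish

The generators emulate library-size asymmetry, abundance and length
heterogeneity, known effect sizes and Poisson counting noise. They do not
emulate biological replicate variability (overdispersion is opt-in, not
calibrated to data), mapping ambiguity, positional/GC bias within reads,
or assembly artifacts. Green calibration tests therefore establish that
the implementation controls type-I error and attains power *under the
test's own sampling model* — not that the no-replicate design is adequate
for overdispersed biological data (it is known to be anti-conservative
there, which the `dispersion` option lets you reproduce).

## Calibration harness

`calibrate` re-simulates a scenario `n_reps` times at seeds spawned from a
root seed, runs the full pipeline core, and scores calls against the truth
table: type-I error is the fraction of truly-null genes called DE; power is
reported per |log2 effect| class, counting only calls in the true
direction, optionally restricted to genes above an expected-count floor
(power is depth-dependent). Rates are replicate means with Monte-Carlo
standard errors (sd/√n_reps); at n_reps = 1 the SE is reported as NaN and
the run still completes.

## Numerical and boundary conventions

* Branch boundary F = 0.5: the 2F branch (the complement branch applies
  only for F strictly above 0.5), giving p = 1 exactly for perfectly
  null-compatible counts.
* Equal libraries imply ac_pvalue(x, y) = ac_pvalue(y, x); verified to
  ~1e−11 relative (two incomplete-beta evaluations, not one).
* Library totals may be supplied explicitly or taken as count-column sums
  (flag-controlled); whether a study's totals mean "total clean reads" or
  "total uniquely aligned reads" is a configuration choice, not hard-coded.
* Percentages print half-up at two decimals, matching how such reports are
  conventionally typeset.

## Known limitations

* No replicated-design models (dispersion estimation, NB GLMs) and no
  multi-condition contrasts — by design; use edgeR/DESeq2-class tools when
  replicates exist.
* No TPM/FPKM variants, bias correction, or isoform quantification.
* No enrichment analysis, annotation, or assembly itself; QC statistics
  assume the assembly is given.
* ΔΔCt assumes ~100% amplification efficiency and replicate-averaged Ct.
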