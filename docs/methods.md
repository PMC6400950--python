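# Methods

## Problem and model

Somatic single-nucleotide variants at very low allele frequency (VAF ≤ 1%)
are masked by two error classes with different physics:

* **sequencing errors** — base-call mistakes whose probability is encoded by
  the Phred quality, P(error) = 10^(−q/10);
* **background errors** — mismatches introduced *before* sequencing (PCR
  nucleotide misincorporation, oxidative damage during sonication, other
  library-preparation artifacts). These carry high base qualities and are
  invisible to quality-aware filters; empirically they cluster in specific
  substitution classes (amplicon/PCR libraries: A>G and C>T transitions;
  hybrid capture: C>A from oxidation).

`replicall` detects low-VAF SNVs by analyzing k ≥ 1 *library-level*
replicates jointly. Library replicates are independent library preparations
of the same DNA, so true variants recur with concordant VAFs while
background errors strike independent positions. Re-sequencing the same
library (a *sequencing* or pseudo-replicate) shares the library's background
errors and cannot expose them — the simulator reproduces exactly this
distinction, and the test suite and acceptance script verify that the caller
reports far more error calls on pseudo-replicates than on proper library
replicates.

### Background-error estimation (reference model M0)

For a site with depth n, alt-read count b and alt base qualities q_l, the
expected sequencing-error read count is b_SE = Σ_l 10^(−q_l/10). The
**mismatch over-representation score**

    MOS = b_BE = b − b_SE

estimates the background-error read count, and x_BE = b_BE / n is the
adjusted VAF. Profile samples are collected from every unmasked target
position with at least one alt read and b_BE > 0 (modal alt allele per
site); one exponential density Exp(x; λ_BE) is fitted per strand-collapsed
substitution class {A>C, A>G, A>T, C>A, C>G, C>T} by closed-form maximum
likelihood (λ̂ = 1/mean, identical to iterative ML for this family). The
fraction of target positions with b_BE > 0, f_BE, is computed per replicate
over the full target length (zero-coverage positions count in the
denominator — conservative) and averaged.

Masking of genuine variants before fitting uses two mechanisms instead of
external callers:

1. a matched-control mask — positions whose control VAF ≥ 0.2 at depth
   ≥ 20 (germline signal), optionally unioned with a user VCF;
2. a one-pass self-mask — positions whose x_BE exceeds the type profile's
   99.9th percentile in *every* replicate are removed and the fit repeated
   once. Evidence reproducibly that strong across independent libraries is
   more plausibly a shared variant than a background error.

### Variant model (M_v) and the joint score

With μ̂ the mean adjusted VAF over replicates, the variant model treats
b_BE as binomial successes at rate μ̂ and uses the normal approximation on
the VAF scale: x_BE ~ N(μ̂, μ̂(1−μ̂)/n_j). Priors come from the ratio of
the user-supplied somatic mutation frequency f_v (default 3×10⁻⁶) to the
fitted f_BE: φ_v = f_v/(f_v+f_BE), φ_BE = 1−φ_v, so φ_v + φ_BE = 1 exactly.
Because all replicates share the same true variants, the prior enters once
regardless of k:

    S = log φ_v + Σ_j log N(x_BE_j; μ̂, σ̂_j²)
      − log φ_BE − Σ_j log Exp(x_BE_j; λ_BE)

Sites with S > 0 (strictly) are variant candidates. The Gaussian product is
maximized when the replicate VAFs agree (verified analytically and by grid
test), which is what lets concordant sub-error-level variants outscore
heavier but discordant errors.

## Numerical choices

* Natural logarithm throughout; the sign of S is base-invariant.
* All products are sums of log densities; each density is floored at
  10⁻³⁰⁰ before logging so one extreme replicate cannot produce −∞.
* x_BE ≤ 0 (base qualities over-explain the mismatches): clamped to 0; the
  exponential density is evaluated at 0 (value λ), keeping the likelihood
  finite and monotone.
* μ̂ is clamped to [10⁻⁶, 1−10⁻⁶]; sites where every replicate has
  x_BE ≤ 0 are skipped, as are sites with no replicate at b_BE > 0.
* Zero-coverage replicates are dropped per site (k shrinks): no evidence
  either way.
* Ties in output ordering break by (chrom, pos, alt lexicographic); modal
  alt alleles tie-break lexicographically.
* Per-type fits fall back to the pooled (all-types) fit below 50 samples
  and the type is flagged.

## Post-filters

The probabilistic model does not capture systematic artifacts, so calls are
*flagged* (never deleted; flags land in the VCF FILTER column) by:
strand-bias Fisher exact test (p < 0.005 in all replicates; skipped
entirely in amplicon mode, where strand is determined by the amplicon
design, and skipped per-site when strand counts are unavailable — only the
BAM reader produces them); minimum alt reads per replicate (default 2);
minimum depth (default 100); triallelic consistency (a competing alt at
≥ half the candidate's VAF in all replicates); and proximity to
user-supplied blacklist regions. This filter set is a configurable,
documented stand-in: it covers the artifact classes a practitioner would
filter, but it is not a reconstruction of any specific published pipeline's
proprietary filter cascade.

## Synthetic replicates

The simulator generates the statistical structure the model assumes, on a
single synthetic contig with uniformly random reference bases and uniform
per-replicate depth (coverage variation and mapping artifacts are out of
scope — read-level effects such as mapping ambiguity, indels and clipping
do not exist in these data, so passing tests say nothing about them):

* true variants at configurable spike-in VAFs (default 0.5/1/5/10%,
  the classic dilution-series design), shared across replicates, counts
  Binomial(n, VAF) per replicate;
* background errors: each site independently per library replicate with
  probability f_BE; error VAF x_err ~ Exp(λ_type) truncated to (0, 1]
  (renormalizing truncation; negligible mass for realistic rates), reads
  Binomial(n, x_err), qualities drawn from the ordinary base-quality
  mixture — high quality is the defining feature of these errors;
* sequencing errors: per-site error-read counts Binomial(n, Σ w_q 10^(−q/10));
  error reads flip to one of the three alts uniformly and draw their quality
  from the error-posterior weights w_q·10^(−q/10).

Defaults: target 100 kb, depth 1000×, k = 2, 100 true sites. The
base-quality mixture {41: 0.46, 37: 0.36, 32: 0.10, 27: 0.05, 22: 0.03} is
an Illumina-like binned quality profile *after* the default min-BQ-20
pileup filter (the sub-threshold bins are removed upstream, exactly as the
BAM reader would remove them); its mean error rate is ≈ 4.6×10⁻⁴ per base.
Spectrum presets encode only the published *ordering* of per-class error
intensities — amplicon_pcr: λ(A>G) = λ(C>T) = 150 heaviest, f_BE = 0.01;
capture: λ(C>A) = 200 heaviest, f_BE = 0.003 — absolute magnitudes are
artifact choices.

Determinism: the seed fans out via `SeedSequence.spawn` into one stream per
replicate plus one for the genome/truth layer; identical configs produce
byte-identical pileup tables.

## Benchmark protocol and problem sizes

The end-to-end benchmark (test suite and `scripts/acceptance.py`) runs
duplicates at 1% VAF, 1000×, amplicon spectrum, 100 kb, 100 true sites and
compares three strategies on exact (chrom, pos, ref, alt) keys:

* the joint caller, supplied with the *realized* mutation rate of the
  spiked target (100/10⁵ = 10⁻³) as f_v — the appropriate prior for a
  benchmark whose target is deliberately mutation-dense, mirroring how such
  spike-in evaluations are normally run; the default 3×10⁻⁶ remains the
  shipping default for real samples;
* the intersection of per-replicate naive threshold calls at the naive
  caller's default operating point (min VAF 1%, ≥ 2 alt reads — the common
  reportable-VAF floor for deep targeted panels);
* a single-replicate naive caller whose threshold is tuned to the smallest
  value whose sensitivity is ≥ the joint caller's ("matched sensitivity"),
  for the FPR-at-equal-sensitivity comparison.

Typical results at these conditions (seed-dependent): joint F ≈ 0.99 at
FPR ≈ 0–20/Mb versus intersection F ≈ 0.46 (sensitivity collapses to
≈ 0.30 because both replicates must independently clear the threshold) and
matched-sensitivity naive FPR in the thousands per Mb. On pseudo-replicates
(shared background layer) the joint caller's error-call rate rises by two
to three orders of magnitude, confirming that the gain comes specifically
from background-error independence across libraries.

Replicate concordance is summarized by the scale-free discordance
|x₁−x₂|/(x₁+x₂) when comparing true and error sites: absolute VAF
differences are dominated by evidence mass (a single stray read is
"concordant" in absolute terms), while the normalized measure separates
shared variants (balanced) from independent errors (one-sided).

## Parameter recovery and its depth limit

Fitting recovers generating λ within 10% at 10,000× depth (2,000 sites per
class). This does **not** hold at 1000×: profile sites are conditioned on
b_BE > 0, and at depth n the smallest observable x_BE is ≈ 1/n, so the
zero-truncated mean E[x̂ | b ≥ 1] exceeds 1/λ by a factor that grows with
λ/n (analytically ≈ 27% at λ = 600, n = 1000). This is a property of the
estimator, not of the implementation; at high depth the bias vanishes. The
caller is unaffected in practice because it uses the λ fitted from the
same data it scores.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| f_v | 3×10⁻⁶ | fraction | prior somatic mutation frequency; the only user-facing model parameter |
| min_bq / min_mq | 20 / 30 | Phred | pileup inclusion thresholds (bases below min_bq leave both n and b) |
| keep_duplicates | off | — | retain duplicate-flagged reads; appropriate for amplicon libraries |
| germline mask VAF / depth | 0.2 / 20 | fraction / reads | control-based masking of germline sites before profiling |
| min profile samples per type | 50 | sites | below this, pooled fallback |
| min_alt_reads_per_rep / min_depth | 2 / 100 | reads | post-filter flags |
| strand-bias p | 0.005 | — | Fisher exact threshold, all replicates |
| triallelic ratio | 0.5 | — | competing-alt VAF fraction that flags a site |

## Known limitations

* SNVs only; indels are ignored at pileup time and no clustered-position
  filter is implemented.
* The error model is per-substitution-type, not per-locus; recurrent
  position-specific artifacts must be caught by post-filters or blacklists.
* Exponential error VAFs are an empirical choice; heavy-tailed artifact
  distributions would be under-penalized in the tail.
* The pileup TSV dialect and the simulator carry no strand information, so
  the strand-bias filter is exercised only on BAM input.
* λ estimates from ~1000× data are biased upward by zero-truncation (see
  above); profiles fitted at one depth should not be reused at a much
  different depth.
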