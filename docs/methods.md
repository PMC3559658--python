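# Methods

## Model and procedure

`ipac` identifies genes whose recurrent copy-number alteration plausibly
perturbs a transcriptional program. It assumes:

- **Segmental copy number.** Log2 copy-number profiles are piecewise
  constant along each chromosome plus probe-level Gaussian noise. The
  segmentation objective is the within-segment sum of squared deviations
  plus a penalty γ per breakpoint, minimised exactly per (sample,
  chromosome) by an O(n²) dynamic program subject to a minimum of `kmin`
  probes per segment. Each probe inherits its segment mean (the *PCF
  value*). Ties are broken deterministically: fewest segments, then the
  lexicographically earliest breakpoint sequence.
- **Log-linear cis coupling.** For gene *g* and sample *i*,
  `e_gi = a_g + b_g·c_gi + ε_gi` with `e` log2 expression, `c` log2 copy
  number (PCF-derived, gene-level) and iid Gaussian ε. On the raw scale
  this is `E ∝ C^b`, so both linear (b = 1) and non-linear dose–response
  relations are covered. The model is fitted by ordinary least squares per
  gene; residuals are exactly mean-zero and orthogonal to `c` in sample.
- **In-trans effects are expression-mediated.** The influence of a pivot
  gene on another gene is quantified as the Pearson correlation between the
  pivot's *observed* expression and the other gene's *residual* expression.
  Using residuals on the target side removes variance driven by the
  target's own copy number, which otherwise inflates correlations between
  genes sharing an amplicon (co-occurring aberration confounding).

The pipeline applies three filters in order (each step restricted to the
survivors of the previous one):

1. **Commonly aberrant:** aberration frequency strictly above `freq_min`
   AND gain/loss skew |G − L| ≥ c from an exact binomial sign test
   (X ~ Bin(m, ½), m = G + L): c is the least integer with
   P(|2X − m| ≥ c) ≤ α for *every* m up to the largest aberration count
   observed in the data set. Both sub-filters are deliberately mild and
   applied without multiple-testing correction; each can be disabled in the
   config.
2. **In-cis:** Pearson(c, e) strictly above `cis_cutoff`, one-sided
   positive (deletion-driven underexpression also yields positive r). The
   empirical FDR of the cutoff is the mean number of exceedances after
   permuting the gene order of the copy-number matrix (expression fixed),
   divided by the observed count; the permutation is genome-wide.
3. **In-trans process association:** per pivot and gene set, the minimum
   hypergeometric (mHG) score
   `s = min_{1 ≤ n < N} HGT(b(n); N, B, n)` evaluated separately for the
   top and the bottom (reversed list) of the ranking, with the exact
   p-value `P(score ≤ s)` under uniform label permutation computed by a
   lattice dynamic program in O(N·B). Records are screened by Bonferroni
   (family = pivots × sets × 2 directions, strict inequality) and called
   significant only if the observed score is strictly smaller than every
   score obtained for that set under the empirical null. The null shuffles
   the sample order of the residual matrix only — one permutation per
   simulation, shared by all pivots — preserving gene–gene dependencies, so
   sets of mutually correlated genes (which reach extreme scores by chance
   more easily) are held to a correspondingly harder bar.

## Numerical choices

- Hypergeometric tails are computed in log space (`gammaln` +
  log-sum-exp); the full (n, b) tail table per (N, B) costs O(N·B) memory
  and is shared between scoring, the p-value DP and the empirical null, so
  ties compare exactly.
- The mHG prefix minimum is evaluated only at prefixes ending in a set
  member: HGT(b; N, B, n) is strictly increasing in n at fixed b, so other
  prefixes cannot attain the minimum (verified against a full scan in
  tests). `n_star` is the smallest prefix attaining the minimum.
- The p-value DP accumulates the probability mass *entering* the rejection
  region instead of computing 1 − (surviving mass), so p-values far below
  machine epsilon relative to 1 (e.g. 1e-40) remain accurate. Region
  membership uses a relative tolerance of 1e-12 so mathematically equal
  tails compare as equal; results are clipped into the analytic bounds
  s ≤ p ≤ min(1, N·s). Because p is strictly increasing in s at fixed
  (N, B), the empirical-null store keeps per-set minimum *scores* and
  converts only the minima to p-values.
- Sign-test thresholds use exact binomial tail sums; no normal
  approximation anywhere.
- Segmentation cost ties are resolved within an absolute tolerance of 1e-9
  so summation order cannot flip a genuine tie.
- Missing values: correlations and fits use pairwise-complete samples with
  a minimum of `min_pairs` (default 10; fits additionally require ≥ 3),
  otherwise the statistic is marked missing. Zero-variance vectors give
  missing cis correlations, slope-0 fits with centered-expression
  residuals, and in-trans correlation 0 (mid-list) — each with a warning.
  Probes missing a copy-number value inherit the PCF value of the segment
  covering their position.
- Nearest-probe matching is restricted to the same chromosome; equidistant
  ties resolve to the lower coordinate. Gene-level values are averages over
  the symbol's probes on the log2 scale; the gene position is the mean of
  its expression-probe positions.

## Parameters

| key | default | meaning |
|-----|---------|---------|
| `gamma` | 40 | PCF penalty per breakpoint (log2² units). Conservative for dense arrays where recurrent events span hundreds of probes; scale it to probe density (see below). |
| `kmin` | 5 | minimum probes per segment |
| `tau` | 0.1 | gain/loss threshold on PCF values (log2) |
| `alpha_sign` | 0.05 | sign-test level; threshold c is recomputed from the observed maximum aberration count, not hard-coded |
| `freq_min` | 0.10 | aberration-frequency filter (strict >) |
| `cis_cutoff` | 0.6 | in-cis Pearson cutoff (strict >, positive side); 0.6² = 36% variance explained |
| `n_shuffles` | 2000 | gene-order shuffles for the cis FDR estimate |
| `bonferroni_alpha` | 0.05 | screening level for enrichment records |
| `n_sims` | 100 | sample shuffles for the empirical null |
| `set_min_size`/`set_max_size` | 3 / 2000 | gene-set size bounds after intersection with the universe |
| `min_pairs` | 10 | minimum pairwise-complete samples for any correlation/fit |

## The synthetic generator

`ipac.synthdata` emulates exactly the structure the method assumes: probes
on a regular grid over `n_chromosomes`, segmental events added to a chosen
fraction of samples (membership drawn without replacement, exactly
`round(fraction·n)` samples), Gaussian probe noise on copy number, the
log-linear cis model for expression, and planted modules whose members add
`coupling × (driver expression deviation)` to their own expression. Decoy
gene sets are size-matched to the planted module and drawn from non-module
genes, so specificity claims are meaningful.

Default benchmark condition: 3000 genes on 10 chromosomes, 100 samples,
one amplicon of 11 consecutive genes (driver in the middle) with a
single-copy gain of log2(3/2) ≈ 0.58 in 30% of samples, cis slope 1
everywhere, one 50-gene trans module with coupling 0.7, 500 decoy sets of
50 genes. Noise: copy-number probe sd 0.15, expression sd 0.25 — values
typical of normalised array data, chosen so the driver's expected in-cis
correlation (b·sd(c)/√(b²var(c)+σ²) ≈ 0.73) sits clearly but not trivially
above the 0.6 cutoff. `benchmark_config` sets γ = 1 for this cohort: the
planted amplicon spans only 11 probes, and the penalty must lie between
the spurious-breakpoint gain from noise (≈ 2σ²ln n ≈ 0.26) and the event's
SSE reduction (≈ 3.6); the γ = 40 default presumes the much denser probe
coverage of real arrays. Shuffle and simulation counts are reduced to
benchmark scale (200 gene-order shuffles, 20 null simulations).

What the generator does *not* emulate: tumour subtype structure, allele-
specific events, GC waves and other spatial noise trends, probe-specific
variances, dosage compensation, and non-linear cis responses. Passing the
recovery tests therefore shows the statistical machinery is correct under
the model's own assumptions, not that the thresholds are optimal for any
particular platform.

A note on what recovery looks like: passenger genes on the planted
amplicon legitimately pass the aberration and cis filters and also
associate with the driver's module — they share the driver's copy-number
event, and the residual adjustment removes confounding from the *ranked*
genes' side, not from the pivot side. The specificity claim the benchmark
tests is that no pivot ever associates with a decoy set.

## Known limitations

- The p-value DP's tail tables take O(N·B) memory per distinct set size;
  with very large universes and set sizes near the 2000 cap this reaches
  hundreds of MB. Size-capping the collection (default) keeps it modest.
- The cis FDR estimator is a mean-exceedance ratio; it is reported, not
  used to choose the cutoff.
- Gene symbols spanning several chromosomes keep their majority chromosome
  (ties to the lexicographically first) with a warning; no alias
  resolution or liftover is attempted.
- Cross-cohort consistency compares signed log scores against a shared
  panel of random pivot genes per set; a zero-variance background yields an
  undefined z (flagged).
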