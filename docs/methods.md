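# Methods

## The model

A molecular-QTL study reports, per trait (protein, transcript, metabolite),
a lead variant and a cognate gene.  Restricting to pairs on one chromosome,
the variant-to-TSS distance `d` is modelled as a two-component mixture on
`lx = log10(d)`:

    p(lx) = w · f_W(lx; κ, λ) + (1 − w) · f_T(lx)

**Cis component** — a two-parameter Weibull on the log10 axis,

    f_W(lx) = (κ/λ) (lx/λ)^(κ−1) exp(−(lx/λ)^κ),

with shape `κ` (dimensionless) and scale `λ` (log10-bp).  Its support is
`lx ≥ 0` (distances of at least 1 bp); for `κ > 1` the density vanishes at
`lx = 0`, which is harmless because the likelihood is only ever evaluated
through binned counts and CDFs, never pointwise at single records.  All
logarithms are base 10 throughout.

**Trans component** — the distance distribution of two uniform random
positions conditioned on sharing a chromosome.  On a chromosome of length
`N` there are `2(N − d)` ordered pairs at distance `0 < d < N` out of `N²`,
and a random intrachromosomal pair lands on chromosome `i` with probability
`N_i²/ΣN_j²`.  The genome-wide density is the weighted sum of these
triangles; it has **no free parameters** beyond the chromosome-length
table.  The default table is GRCh38 chr1–22 + chrX (23 chromosomes), chosen
because molecular-QTL panels map traits to autosomes and X; it can be
overridden with any two-column TSV or `.fai` file, and the build used is
recorded in output metadata.  Zero distances are excluded from the model
(a discontinuity with no support in real data), and the density is
renormalised by `ΣN_i(N_i−1)/ΣN_i²` so the discrete mass over
`d = 1..max(N_i)` is exactly 1; the correction is O(1/N) and only visible
on the base-pair-scale toy genomes used by the test oracles.  Tail
probabilities use the exact discrete form
`P(d > x) = Σ(N_i−m)(N_i−m+1)/ΣN_i(N_i−1)` with `m = floor(x)+1`, which is
what exhaustive pair enumeration gives on toy genomes.

On the default human table, `P(d > 1 Mb) ≈ 0.987`: random same-chromosome
pairs are almost always more than a megabase apart, which is what makes the
two regimes separable at all.

## Binning

Distances are binned on the log10 axis at width 0.25 (four bins per decade).
A bin is labelled by its **left edge**; edges sit on multiples of the bin
width, so a distance of exactly 10^4 starts its own bin, and intervals are
half-open `[l, r)` so boundary values are counted once.  Model-expected
counts per bin are exact CDF differences, `total·[w·ΔF_W + (1−w)·ΔF_T]`,
not midpoint densities — the midpoint approximation is off by several
percent in the steep cis shoulder at this bin width and fails entirely in
the bin containing the longest chromosome's end.  Distances below 1 bp are
rejected with a warning and counted.

## The two-stage fit

1. **Cutoff.**  The initial cis fit uses bins strictly below the trough
   between the cis and trans peaks.  Automatic selection finds the two
   local maxima of greatest topographic prominence (raw bin heights are
   jagged at realistic counts, so prominence — not height — separates the
   real peaks from sampling sub-peaks inside the cis bulk) and returns the
   left edge of the minimum-count bin between them, ties broken toward
   larger distance.  Unimodal histograms raise and require an explicit
   cutoff.
2. **Initial fit.**  Weighted nonlinear least squares of a scaled Weibull
   to the sub-cutoff bins; the amplitude is a free nuisance parameter
   (parameterised as a fraction of the total so stage 1 is exactly stage 2
   with the trans component dropped).  Starting values come from method of
   moments on bin midpoints.  The reported *initial cis fraction* is
   count-based: records below the cutoff over the total.
3. **Final fit.**  The three free parameters (κ, λ, w) are fit to **all**
   bins, starting from the stage-1 values, with w constrained to [0, 1]
   (a fraction pinned at a bound is flagged in the diagnostics).

The objective is least squares on binned counts with approximate Poisson
weights, `sigma = sqrt(max(count, 1))` (unweighted available by flag);
zero-count bins inside the occupied span stay in the objective.  Standard
errors are the Jacobian-based covariance scaled by the residual variance.
The fit is fully deterministic.  Optimiser bounds: κ ∈ (0.1, 50),
λ ∈ (0.5, 10), w ∈ [0, 1].

For distance-truncated studies (association tested only within a fixed
window, e.g. 1 Mb), `fit_truncated` fits a Weibull renormalised by its CDF
at the truncation limit, with the cis fraction reported as 1.0 and no SE.

**Goodness of fit** is a one-sample Kolmogorov–Smirnov test of the unbinned
log10 distances against the fitted mixture CDF, computed for both the
Weibull-based and the Gaussian-based (mean, sd) cis model so they can be
compared.  The parameters are estimated from the same sample, so these
p-values are anti-conservative; they are used comparatively, and no
correction is applied.

## Cross-over distance

The cis/trans boundary is the root of `w·f_W(lx) = (1−w)·f_T(lx)`,
bracketed between the Weibull mode and the trans mode and solved by Brent's
method to 1e-13 in `lx` (density-gap residual below 1e-12).  Both densities
are per-log10-unit; since the change of variables multiplies both sides by
the same Jacobian, the root is identical in linear space.  Under the
equal-prior convention `w` is replaced by 1/2.  Should the gap change sign
more than once on the bracket (not observed at realistic parameters), the
largest root below the trans mode is returned with a warning.  At the
published primary-study parameters (κ = 6.777, λ = 4.478, w = 0.799) the
fitted-prior cross-over is ≈ 940 kbp and the equal-prior one ≈ 653 kbp.

**Confidence interval** — a parametric bootstrap: parameter vectors are
drawn from the multivariate normal at the optimum (the fit covariance, or a
diagonal covariance from reported SEs when only those are available) and
the cross-over recomputed per draw; the interval is the percentile range.
This was chosen as reproducible and assumption-light; a delta-method
interval would be the analytic alternative but requires the same covariance
and adds a linearisation the bootstrap avoids.  The bootstrap is vectorised
(80 bisection steps over all draws simultaneously, verified against the
scalar root-finder to 1e-9 relative) and deterministic given the seed.
Draws with non-physical parameters or no density crossing count as
failures; more than 5% failures aborts.  Default 10,000 draws.

`classify_qtl` operationalises the boundary: label cis iff the distance is
below the cross-over, with posterior `w·f_W/(w·f_W + (1−w)·f_T)`, which is
0.5 exactly at the fitted-prior cross-over.

## Preprocessing rules

Per study type, applied to schema-mapped summary tables (1-based
coordinates, strand-agnostic absolute distances):

- **pQTL**: drop interchromosomal pairs; honour a primary-rank flag when
  present; keep the strongest record per trait (ties: smaller distance,
  then smaller variant position — fully deterministic).  A trait mapping to
  several genes survives only through pairings whose gene shares the
  variant's chromosome.
- **eQTL**: keep |Z| ≥ 5.4485 (inclusive; the genome-wide 5e-8 equivalent),
  then the largest-|Z| record per gene.
- **Metabolite QTL**: a (metabolite, chromosome) pair is eligible only when
  the interacting-gene map lists exactly one gene for the metabolite on
  that chromosome; keep the smallest-p association per eligible pair if
  p < 5e-8 (strict).

Every rejected record appears exactly once in a rejection table with a
reason code, so records are conserved.  Genome-build remapping and gene
symbol curation are upstream of this package: inputs must be harmonised.

## Synthetic data

The generator draws each trait cis with probability `w` (log10 distance
from the Weibull, chromosome assigned proportional to length, draws beyond
the chromosome length redrawn) and trans otherwise (chromosome by the `N²`
weighting, two uniform positions, zero differences redrawn), emitting
integer distances ≥ 1 bp with the latent truth label.  Defaults are the
primary study's conditions: 2,051 traits, κ = 6.78, λ = 4.48, w = 0.799.

What it does *not* emulate: linkage disequilibrium between lead variants,
winner's-curse selection of lead SNPs, mis-assigned cognate genes, strand
or build errors, and any dependence of association strength on distance.
Passing recovery tests therefore demonstrates that the estimation machinery
is consistent under the model's own assumptions — not that real data meet
those assumptions.

## Problem sizes and numerical choices

Recovery tests use n = 2,000 traits (the scale of the real studies) and
samplers at n = 1e5 where distributional agreement is asserted; bootstrap
intervals use 10,000 draws.  At n = 2,000 the sampling noise of λ alone
moves the cross-over by ~5–10%, so closure of the simulate→fit→cross-over
loop is asserted at 10%.  Degenerate inputs raise informative errors:
fewer than three occupied bins below a cutoff, unimodal histograms, empty
distance lists, fractions pinned at bounds, truncation limits below the
occupied span.

## Known limitations

- The KS p-values are anti-conservative (parameters fit on the same data).
- Least-squares on binned counts is not full maximum likelihood; a Poisson
  or multinomial ML variant would be the natural extension.
- The single-strongest-association-per-trait design inherits the source
  studies' primary-signal definitions; secondary signals are out of scope.
- Interchromosomal trans-QTLs are excluded by construction; the model says
  nothing about them.
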