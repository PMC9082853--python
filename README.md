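# cistrans

Empirical cis/trans classification of molecular QTLs from the distribution
of variant-to-TSS distances.

## The problem

A GWAS of a molecular trait — protein, transcript or metabolite abundance —
reports a lead variant per trait, and the gene encoding (or biochemically
tied to) that trait is the natural causal-gene hypothesis.  Variants acting
directly on that *cognate* gene (cis-QTLs) sit close to its transcription
start site; variants acting through an intermediate gene (trans-QTLs) carry
no distance signal at all.  Studies have traditionally separated the two
with ad-hoc windows (250 kb, 500 kb, 1 Mb).  This package derives the
cutoff *empirically* from the data.

## The model

On `lx = log10(distance in bp)` the distances are a three-parameter mixture

    p(lx) = w · f_W(lx; κ, λ) + (1 − w) · f_T(lx)

- `f_W` — a Weibull with shape κ and scale λ: the cis, distance-dependent
  regime;
- `f_T` — the parameter-free distribution of two random positions
  conditioned on sharing a chromosome, built only from chromosome lengths
  `N_i` (a pair lands on chromosome i with probability `N_i²/ΣN_j²`, and at
  distance d with density ∝ `Σ 2(N_i − d)·[d < N_i]`): the trans,
  distance-independent regime;
- `w` — the cis ("Weibull") fraction.

Fitting is two-stage weighted least squares on 0.25-wide log10 bins
(initial Weibull below the histogram trough, then all three parameters over
every bin), with goodness of fit by a one-sample Kolmogorov–Smirnov test
against the mixture CDF.  The **cross-over distance** — where
`w·f_W = (1−w)·f_T` — is the empirical cis/trans boundary, with a
parametric-bootstrap confidence interval.  Because random same-chromosome
pairs are >1 Mb apart ~99% of the time while ~99.9% of the fitted cis mass
lies within 1 Mb, the regimes are cleanly separable; at published
proteomic-study parameters the boundary lands near 940 kbp (fitted prior)
or 650 kbp (equal prior).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a study at realistic conditions, fit it, and locate the boundary:

```
$ cistrans simulate --n 2051 --seed 7 --out sim.tsv
$ cistrans fit sim.tsv --out fit.json
initial_cutoff  initial_shape  initial_scale  initial_fraction  final_shape    final_scale    final_fraction  ks_p_weibull  ks_p_gaussian
6.0             6.5707         4.4506         0.7996            6.630 (0.148)  4.443 (0.020)  0.798 (0.010)   0.3377        0.0415
$ cistrans crossover fit.json --bootstrap 10000 --seed 7
prior   distance_kbp  ci_low_kbp  ci_high_kbp
fitted  921           810         1056
equal   637           573         711
```

Reading the fit row: the histogram trough sat at log10(d) = 6.0; the
initial cis-only Weibull fit gave (κ, λ) ≈ (6.57, 4.45) with 80.0% of
records below the trough; the final three-parameter fit lands at
κ = 6.630 ± 0.148, λ = 4.443 ± 0.020, cis fraction 0.798 ± 0.010 — within
sampling error of the generating values (6.78, 4.48, 0.799).  The Weibull
cis model fits the data (KS p = 0.34) where the Gaussian alternative fits
worse (p = 0.04).  The cross-over places the cis/trans boundary at 921 kbp
(95% CI 810–1056) under the fitted prior, 637 kbp under an equal prior —
the equal-prior boundary is always nearer when most QTLs are cis.

The same stages are available as library calls (`cistrans.fit_study`,
`cistrans.crossover_distance`, `cistrans.classify_qtl`, ...), and
`cistrans preprocess` converts raw study summary tables (pQTL, eQTL with a
|Z| ≥ 5.4485 floor, metabolite QTLs with the unique-interacting-gene rule)
into the canonical distance table.

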