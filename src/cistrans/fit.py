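"""Two-stage estimation of the cis/trans mixture from binned distances.

Stage 1 fits a scaled Weibull to the histogram bins below a cutoff (the
trough between the cis and trans peaks); stage 2 fits the full
three-parameter mixture — Weibull shape, scale and cis ("Weibull") fraction
— to every bin, starting from the stage-1 values, with the parameter-free
trans model supplying the long-range component.  Goodness of fit is judged
by a one-sample Kolmogorov-Smirnov test of the unbinned log10 distances
against the fitted mixture CDF, for both the Weibull-based and the
Gaussian-based cis model.

Fitting is weighted nonlinear least squares on binned counts with
approximate Poisson weights (sigma = sqrt(max(count, 1))); standard errors
come from the Jacobian-based covariance scaled by the residual variance.
The fit is deterministic: no randomness enters the estimation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .cis import GaussianParams, WeibullParams
from .genome import TransModel
from .histogram import DistanceHistogram, bin_distances, mixture_bin_probabilities

__all__ = [
    "FitError",
    "MixtureParams",
    "FitResult",
    "suggest_cutoff",
    "fit_initial_weibull",
    "fit_mixture",
    "fit_truncated",
    "ks_goodness_of_fit",
    "fit_study",
]

KAPPA_BOUNDS = (0.1, 50.0)
LAMBDA_BOUNDS = (0.5, 10.0)
FRACTION_BOUNDS = (0.0, 1.0)
GAUSS_MEAN_BOUNDS = (0.0, 10.0)
GAUSS_SD_BOUNDS = (0.01, 5.0)

_EPS = 1e-9


class FitError(RuntimeError):
    """Raised when a curve fit cannot be performed or does not converge."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class MixtureParams:
    """Fitted mixture: cis parameters plus the cis ("Weibull") fraction.

    ``weibull`` holds the cis component — :class:`WeibullParams` for the
    primary model, :class:`GaussianParams` for the alternative.
    """

    weibull: WeibullParams | GaussianParams
    weibull_fraction: float
    fraction_se: float | None = None
    source_total: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weibull_fraction <= 1.0:
            raise ValueError("weibull_fraction must lie in [0, 1]")
        if self.fraction_se is not None and self.fraction_se < 0:
            raise ValueError("standard errors must be non-negative")

    def cdf_log(self, lx, model: TransModel | None):
        """Mixture CDF on the log10 axis: w*F_cis + (1-w)*F_trans."""
        w = self.weibull_fraction
        out = w * self.weibull.frozen.cdf(np.asarray(lx, dtype=float))
        if model is not None:
            out = out + (1.0 - w) * model.cdf_log(lx)
        return out

    def to_dict(self) -> dict:
        cis = self.weibull
        if isinstance(cis, WeibullParams):
            cis_d = {"family": "weibull", "shape": cis.shape, "scale": cis.scale,
                     "shape_se": cis.shape_se, "scale_se": cis.scale_se}
        else:
            cis_d = {"family": "gaussian", "mean": cis.mean, "sd": cis.sd,
                     "mean_se": cis.mean_se, "sd_se": cis.sd_se}
        return {"cis": cis_d, "weibull_fraction": self.weibull_fraction,
                "fraction_se": self.fraction_se, "source_total": self.source_total}

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        c = d["cis"]
        if c["family"] == "weibull":
            cis = WeibullParams(c["shape"], c["scale"], c.get("shape_se"), c.get("scale_se"))
        else:
            cis = GaussianParams(c["mean"], c["sd"], c.get("mean_se"), c.get("sd_se"))
        return cls(cis, d["weibull_fraction"], d.get("fraction_se"), d.get("source_total", 0))


@dataclass
class FitResult:
    """Full two-stage fit with goodness-of-fit diagnostics."""

    initial: MixtureParams
    final: MixtureParams
    initial_cutoff: float
    ks_pvalue_weibull: float | None = None
    ks_pvalue_gaussian: float | None = None
    covariance: np.ndarray | None = None   # (shape, scale, fraction) order
    residual_norm: float | None = None
    n_function_evals: int | None = None
    warnings: list[str] = field(default_factory=list)
    gaussian_final: MixtureParams | None = None
    bin_width: float = 0.25
    chromosome_build: str = "GRCh38"

    def to_dict(self) -> dict:
        return {
            "initial": self.initial.to_dict(),
            "final": self.final.to_dict(),
            "initial_cutoff": self.initial_cutoff,
            "ks_pvalue_weibull": self.ks_pvalue_weibull,
            "ks_pvalue_gaussian": self.ks_pvalue_gaussian,
            "covariance": None if self.covariance is None else np.asarray(self.covariance).tolist(),
            "residual_norm": self.residual_norm,
            "n_function_evals": self.n_function_evals,
            "warnings": list(self.warnings),
            "gaussian_final": None if self.gaussian_final is None else self.gaussian_final.to_dict(),
            "bin_width": self.bin_width,
            "chromosome_build": self.chromosome_build,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            initial=MixtureParams.from_dict(d["initial"]),
            final=MixtureParams.from_dict(d["final"]),
            initial_cutoff=d["initial_cutoff"],
            ks_pvalue_weibull=d.get("ks_pvalue_weibull"),
            ks_pvalue_gaussian=d.get("ks_pvalue_gaussian"),
            covariance=None if d.get("covariance") is None else np.asarray(d["covariance"]),
            residual_norm=d.get("residual_norm"),
            n_function_evals=d.get("n_function_evals"),
            warnings=list(d.get("warnings", [])),
            gaussian_final=(None if d.get("gaussian_final") is None
                            else MixtureParams.from_dict(d["gaussian_final"])),
            bin_width=d.get("bin_width", 0.25),
            chromosome_build=d.get("chromosome_build", "GRCh38"),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------- #
# cutoff selection


def suggest_cutoff(hist: DistanceHistogram) -> float:
    """Left edge of the trough bin between the two dominant histogram peaks.

    The cis and trans peaks are identified as the two local maxima of
    greatest topographic prominence (raw bin heights are jagged at realistic
    counts, so prominence rather than height separates the real peaks from
    sampling noise within the cis bulk).  The trough is the minimum-count
    bin strictly between them, ties broken toward larger log10 distance.  A
    histogram without two separated peaks raises :class:`FitError` asking
    for an explicit cutoff.
    """
    from scipy.signal import find_peaks, peak_prominences

    c = hist.counts.astype(float)
    padded = np.concatenate([[-1.0], c, [-1.0]])
    peak_idx, _ = find_peaks(padded)
    peak_idx = peak_idx - 1
    if len(peak_idx) < 2:
        raise FitError("histogram has no two separated peaks; supply an explicit cutoff")
    prom = peak_prominences(padded, peak_idx + 1)[0]
    order = np.argsort(prom, kind="stable")[::-1]
    top2 = np.sort(peak_idx[order[:2]])
    i, j = int(top2[0]), int(top2[1])
    if j - i < 2:
        raise FitError("the two dominant peaks are adjacent; supply an explicit cutoff")
    between = c[i + 1: j]
    # ties broken toward the larger lx
    rel = len(between) - 1 - int(np.argmin(between[::-1]))
    return float(hist.labels[i + 1 + rel])


# ---------------------------------------------------------------------- #
# core weighted least squares on binned counts


def _curve_fit_counts(hist, predict, p0, bounds, weighted=True):
    counts = hist.counts.astype(float)
    sigma = np.sqrt(np.maximum(counts, 1.0)) if weighted else None
    x = np.arange(len(counts), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                predict, x, counts, p0=p0, sigma=sigma,
                bounds=bounds, maxfev=50_000, full_output=False,
            )
        except RuntimeError as err:
            raise FitError(f"curve fit did not converge: {err}", last_iterate=p0) from err
    resid = predict(x, *popt) - counts
    if sigma is not None:
        resid = resid / sigma
    return popt, pcov, float(np.linalg.norm(resid))


def _weibull_moment_init(hist: DistanceHistogram) -> tuple[float, float]:
    """Method-of-moments starting values from bin midpoints."""
    mid = hist.labels + hist.bin_width / 2.0
    w = hist.counts / max(hist.total, 1)
    m = float(np.sum(w * mid))
    s = float(np.sqrt(np.sum(w * (mid - m) ** 2)))
    cv = s / m if m > 0 else 0.5
    from scipy.special import gamma as G

    def cv_of(kappa):
        g1, g2 = G(1 + 1 / kappa), G(1 + 2 / kappa)
        return np.sqrt(max(g2 - g1 ** 2, 1e-300)) / g1

    try:
        kappa0 = optimize.brentq(lambda k: cv_of(k) - cv, 0.2, 100.0)
    except ValueError:
        kappa0 = 5.0
    kappa0 = float(np.clip(kappa0, *KAPPA_BOUNDS))
    lam0 = float(np.clip(m / G(1 + 1 / kappa0), *LAMBDA_BOUNDS))
    return kappa0, lam0


def fit_initial_weibull(
    hist: DistanceHistogram,
    cutoff: float,
    total: int | None = None,
    weighted: bool = True,
) -> tuple[WeibullParams, float]:
    """Stage-1 fit: scaled Weibull to the bins strictly below ``cutoff``.

    The amplitude is a free nuisance fraction of ``total`` (defaulting to the
    full histogram total), so the returned shape/scale are exactly those of
    :func:`fit_mixture` run with no trans component on the same bins.  The
    second return value is the count-based initial cis fraction:
    (records below cutoff) / total.

    Raises :class:`FitError` if fewer than three occupied bins lie below the
    cutoff, or on non-convergence.
    """
    total = hist.total if total is None else total
    try:
        sub = hist.restrict(hi=cutoff)
    except ValueError as err:
        raise FitError(str(err)) from err
    if np.count_nonzero(sub.counts) < 3:
        raise FitError("need at least three occupied bins below the cutoff")
    kappa0, lam0 = _weibull_moment_init(sub)
    frac0 = min(max(sub.total / max(total, 1), 1e-3), 1.0 - 1e-6)

    def predict(_x, kappa, lam, w):
        p = WeibullParams(kappa, lam)
        return total * mixture_bin_probabilities(sub.labels, sub.right_edges, p, w, None)

    popt, pcov, _ = _curve_fit_counts(
        sub, predict, p0=[kappa0, lam0, frac0],
        bounds=([KAPPA_BOUNDS[0], LAMBDA_BOUNDS[0], 0.0],
                [KAPPA_BOUNDS[1], LAMBDA_BOUNDS[1], 1.0]),
        weighted=weighted,
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    params = WeibullParams(popt[0], popt[1], float(se[0]), float(se[1]))
    initial_fraction = sub.total / max(total, 1)
    return params, float(initial_fraction)


def fit_mixture(
    hist: DistanceHistogram,
    init: MixtureParams,
    model: TransModel | None,
    fix_fraction: float | None = None,
    weighted: bool = True,
) -> FitResult:
    """Stage-2 fit of the full mixture over every bin of ``hist``.

    Free parameters are the cis shape/scale (or mean/sd for a Gaussian cis
    component) and the cis fraction ``w``, constrained to [0, 1]; starting
    values must come from ``init`` (normally the stage-1 fit).  Standard
    errors are the scaled Jacobian-based covariance at the optimum; a
    fraction pinned at a bound is recorded as a warning in the diagnostics.
    """
    total = hist.total
    gaussian = isinstance(init.weibull, GaussianParams)
    if gaussian:
        p1_bounds, p2_bounds = GAUSS_MEAN_BOUNDS, GAUSS_SD_BOUNDS
        theta0 = [init.weibull.mean, init.weibull.sd]
        make = lambda a, b: GaussianParams(a, b)
    else:
        p1_bounds, p2_bounds = KAPPA_BOUNDS, LAMBDA_BOUNDS
        theta0 = [init.weibull.shape, init.weibull.scale]
        make = lambda a, b: WeibullParams(a, b)

    if fix_fraction is None:
        w0 = float(np.clip(init.weibull_fraction, 1e-6, 1.0 - 1e-6))
        if not 0.0 < init.weibull_fraction < 1.0:
            raise ValueError("initial weibull_fraction must lie strictly in (0, 1)")

        def predict(_x, a, b, w):
            return total * mixture_bin_probabilities(
                hist.labels, hist.right_edges, make(a, b), w, model)

        popt, pcov, rnorm = _curve_fit_counts(
            hist, predict, p0=theta0 + [w0],
            bounds=([p1_bounds[0], p2_bounds[0], 0.0], [p1_bounds[1], p2_bounds[1], 1.0]),
            weighted=weighted,
        )
        w_hat, w_se = float(popt[2]), float(np.sqrt(max(pcov[2, 2], 0.0)))
    else:
        def predict(_x, a, b):
            return total * mixture_bin_probabilities(
                hist.labels, hist.right_edges, make(a, b), fix_fraction, model)

        popt, pcov, rnorm = _curve_fit_counts(
            hist, predict, p0=theta0,
            bounds=([p1_bounds[0], p2_bounds[0]], [p1_bounds[1], p2_bounds[1]]),
            weighted=weighted,
        )
        w_hat, w_se = float(fix_fraction), None

    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    warns: list[str] = []
    if fix_fraction is None and (w_hat < 1e-6 or w_hat > 1.0 - 1e-6):
        warns.append(f"cis fraction pinned at bound: w = {w_hat:.6f}")
    if gaussian:
        cis = GaussianParams(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]))
    else:
        cis = WeibullParams(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]))
    final = MixtureParams(cis, w_hat, w_se, source_total=total)
    cov3 = pcov if fix_fraction is None else None
    return FitResult(
        initial=init, final=final, initial_cutoff=float("nan"),
        covariance=cov3, residual_norm=rnorm, warnings=warns,
        bin_width=hist.bin_width,
    )


def fit_truncated(
    hist: DistanceHistogram,
    limit: float,
    weighted: bool = True,
) -> MixtureParams:
    """Weibull-only fit to bins below ``limit`` for distance-truncated studies.

    For studies that only test variants within a fixed window (e.g. 1 Mb of
    the gene) the observable sample is a truncated Weibull; expected counts
    are renormalised by the Weibull CDF at the truncation limit.  The cis
    fraction is reported as 1.0 with no standard error.
    """
    try:
        sub = hist.restrict(hi=limit)
    except ValueError as err:
        raise FitError(str(err)) from err
    if np.count_nonzero(sub.counts) < 3:
        raise FitError("need at least three occupied bins below the truncation limit")
    n = sub.total
    kappa0, lam0 = _weibull_moment_init(sub)

    def predict(_x, kappa, lam):
        p = WeibullParams(kappa, lam)
        norm = p.frozen.cdf(limit)
        dF = p.frozen.cdf(sub.right_edges) - p.frozen.cdf(sub.labels)
        return n * dF / max(norm, 1e-300)

    popt, pcov, _ = _curve_fit_counts(
        sub, predict, p0=[kappa0, lam0],
        bounds=([KAPPA_BOUNDS[0], LAMBDA_BOUNDS[0]], [KAPPA_BOUNDS[1], LAMBDA_BOUNDS[1]]),
        weighted=weighted,
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    params = WeibullParams(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]))
    return MixtureParams(params, 1.0, None, source_total=n)


# ---------------------------------------------------------------------- #
# goodness of fit


def ks_goodness_of_fit(
    distances,
    fitted: MixtureParams,
    model: TransModel | None,
) -> float:
    """One-sample KS p-value of unbinned log10 distances vs the mixture CDF.

    The parameters were estimated from the same sample, so the test is
    anti-conservative; it is used comparatively (Weibull vs Gaussian cis
    component), not as a calibrated test.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    lx = np.log10(np.maximum(d, 1.0))
    res = stats.kstest(lx, lambda v: fitted.cdf_log(v, model))
    return float(res.pvalue)


# ---------------------------------------------------------------------- #
# end-to-end pipeline


def fit_study(
    distances,
    model: TransModel | None = None,
    bin_width: float = 0.25,
    cutoff: float | Literal["auto"] = "auto",
    weighted: bool = True,
) -> FitResult:
    """Run the full protocol on raw distances: bin, stage-1 fit, stage-2
    mixture fit, and KS comparison of the Weibull vs Gaussian cis models.
    """
    model = model if model is not None else TransModel()
    d = np.asarray(distances, dtype=float)
    hist = bin_distances(d, bin_width)
    cut = suggest_cutoff(hist) if cutoff == "auto" else float(cutoff)

    w_init, frac0 = fit_initial_weibull(hist, cut, weighted=weighted)
    initial = MixtureParams(w_init, frac0, source_total=hist.total)
    result = fit_mixture(hist, initial, model, weighted=weighted)
    result.initial_cutoff = cut
    result.chromosome_build = model.chromosomes.build

    # Gaussian-cis alternative: moment-matched start below the same cutoff
    sub = hist.restrict(hi=cut)
    mid = sub.labels + bin_width / 2.0
    wts = sub.counts / max(sub.total, 1)
    mu0 = float(np.sum(wts * mid))
    sd0 = float(max(np.sqrt(np.sum(wts * (mid - mu0) ** 2)), 0.05))
    g_init = MixtureParams(GaussianParams(mu0, sd0), frac0, source_total=hist.total)
    try:
        g_result = fit_mixture(hist, g_init, model, weighted=weighted)
        result.gaussian_final = g_result.final
        result.ks_pvalue_gaussian = ks_goodness_of_fit(d[d >= 1], g_result.final, model)
    except FitError as err:
        result.warnings.append(f"gaussian alternative fit failed: {err}")

    result.ks_pvalue_weibull = ks_goodness_of_fit(d[d >= 1], result.final, model)
    return result
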