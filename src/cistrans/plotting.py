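"""Thin plotting helpers: histogram with fitted cis/trans/mixture overlays."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cis import weibull_density_log, gaussian_density_log, WeibullParams
from .fit import FitResult
from .genome import TransModel
from .histogram import DistanceHistogram, expected_counts


def plot_histogram_fit(
    hist: DistanceHistogram,
    fit: FitResult,
    model: TransModel,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Log10-distance histogram with cis, trans and combined model curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    final = fit.final
    w = final.weibull_fraction
    total = hist.total
    bw = hist.bin_width
    lx = np.linspace(max(hist.labels[0], 1e-3), hist.labels[-1] + bw, 600)

    cis_pdf = (weibull_density_log(lx, final.weibull)
               if isinstance(final.weibull, WeibullParams)
               else gaussian_density_log(lx, final.weibull))
    trans_pdf = model.density_log(lx)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.bar(hist.labels, hist.counts, width=bw, align="edge",
           color="lightgray", edgecolor="gray", label="observed")
    ax.plot(lx, total * bw * w * cis_pdf, "r-", label="cis (Weibull)")
    ax.plot(lx, total * bw * (1 - w) * trans_pdf, "b-", label="trans (random pair)")
    mids = hist.labels + bw / 2
    ax.plot(mids, expected_counts(hist, final, model), "--", color="purple",
            label="combined model")
    ax.set_xlabel("log10 variant-TSS distance (bp)")
    ax.set_ylabel("QTLs per bin")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
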