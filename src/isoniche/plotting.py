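"""Optional report figures: size box plots, overlap posteriors, ellipse panels."""

from __future__ import annotations

import itertools
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import chi2


def plot_size_boxplot(sizes, path):
    """Box plot of the posterior niche-size distribution per species."""
    labels = sorted(sizes)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(
        [sizes[lab].volumes for lab in labels],
        tick_labels=labels,
        whis=(10, 90),
        showfliers=True,
    )
    ax.set_ylabel("niche hypervolume (‰³)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_overlap_posteriors(overlaps, path):
    """Histogram grid of directional overlap posteriors with mean and 95% CI."""
    pairs = sorted(overlaps)
    ncols = min(3, len(pairs))
    nrows = int(np.ceil(len(pairs) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
    for ax, pair in zip(axes.ravel(), pairs):
        dist = overlaps[pair]
        ax.hist(dist.overlaps, bins=40, color="0.7")
        ax.axvline(dist.mean, color="k")
        for edge in dist.ci95:
            ax.axvline(edge, color="k", linestyle="--")
        ax.set_title(f"{pair[0]} in {pair[1]} niche", fontsize=9)
        ax.set_xlabel("overlap (%)", fontsize=8)
    for ax in axes.ravel()[len(pairs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _ellipse_xy(mu2, sigma2, alpha, num=100):
    theta = np.linspace(0, 2 * np.pi, num)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    L = np.linalg.cholesky(sigma2 * chi2.ppf(alpha, 2))
    pts = (L @ circle).T + mu2
    return pts[:, 0], pts[:, 1]


def plot_ellipse_panels(posteriors, isotopes, alpha, path, n_show=10, seed=0):
    """2-D projections of a few random posterior-draw ellipses per species pair."""
    rng = np.random.default_rng(seed)
    axes_pairs = list(itertools.combinations(range(len(isotopes)), 2))
    labels = sorted(posteriors)
    fig, axes = plt.subplots(
        len(axes_pairs), 1, figsize=(4.5, 3.4 * len(axes_pairs)), squeeze=False
    )
    colors = plt.cm.tab10(np.linspace(0, 1, len(labels)))
    for row, (i, j) in enumerate(axes_pairs):
        ax = axes[row, 0]
        for color, lab in zip(colors, labels):
            draws = posteriors[lab]
            idx = rng.choice(draws.n_draws, size=min(n_show, draws.n_draws), replace=False)
            for k in idx:
                mu2 = draws.mu_draws[k][[i, j]]
                sig2 = draws.sigma_draws[k][np.ix_([i, j], [i, j])]
                x, y = _ellipse_xy(mu2, sig2, alpha)
                ax.plot(x, y, color=color, alpha=0.35, lw=0.8)
            ax.plot([], [], color=color, label=lab)
        ax.set_xlabel(f"{isotopes[i]} (‰)")
        ax.set_ylabel(f"{isotopes[j]} (‰)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_report(report, outdir):
    """Write all figures for a RunReport into ``outdir``."""
    outdir = Path(outdir)
    plot_size_boxplot(report.sizes, outdir / "niche_sizes_boxplot.png")
    if report.overlaps:
        plot_overlap_posteriors(report.overlaps, outdir / "overlap_posteriors.png")
    if report.posteriors:
        plot_ellipse_panels(
            report.posteriors,
            report.isotopes,
            report.alpha,
            outdir / "ellipse_panels.png",
        )
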