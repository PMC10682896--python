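"""Conjugate Normal-Inverse-Wishart posterior sampling.

For data X (n individuals, d isotopes) assumed multivariate normal with
unknown mean mu and covariance Sigma, the noninformative (Jeffreys-type)
limit of the Normal-Inverse-Wishart family gives the closed-form posterior

    Sigma | X  ~  Inverse-Wishart(df = n - 1, scale = S),
    mu | Sigma, X  ~  Normal(xbar, Sigma / n),

with xbar the sample mean and S the centred scatter matrix
sum_i (x_i - xbar)(x_i - xbar)'.  Conjugacy makes the posterior exactly
samplable, so draws are independent — no chain, no burn-in, no thinning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .data_io import SpeciesDataset

#: scatter matrices worse-conditioned than this are treated as singular
_MAX_CONDITION = 1e12


@dataclass(frozen=True)
class PosteriorDraws:
    """Paired joint posterior draws of (mu, Sigma) for one species.

    Draw i is a joint sample: ``mu_draws[i]`` was drawn conditionally on
    ``sigma_draws[i]``.
    """

    species_label: str
    mu_draws: np.ndarray      # (N, d), ‰
    sigma_draws: np.ndarray   # (N, d, d), ‰²
    source_n: int             # size of the data sample the posterior is based on

    @property
    def n_draws(self) -> int:
        return self.mu_draws.shape[0]

    @property
    def d(self) -> int:
        return self.mu_draws.shape[1]


def sample_niw_posterior(dataset, n_draws: int = 10_000, seed=None) -> PosteriorDraws:
    """Draw iid joint posterior samples of (mu, Sigma) for one species.

    Parameters
    ----------
    dataset : SpeciesDataset or array-like of shape (n, d)
        Observed isotope values; requires n >= d + 2 so the Inverse-Wishart
        posterior for Sigma is proper with finite mean.
    n_draws : int
        Number of joint posterior draws (default 10,000).
    seed : int, numpy Generator, or None
        Single seed stream drives both Sigma and mu | Sigma; the same seed
        yields bit-identical draws.

    Returns
    -------
    PosteriorDraws
    """
    if isinstance(dataset, SpeciesDataset):
        X, label = dataset.values, dataset.species_label
    else:
        X = np.atleast_2d(np.asarray(dataset, dtype=float))
        label = "data"
    n, d = X.shape
    if n < d + 2:
        raise ValueError(
            f"need n >= d + 2 = {d + 2} observations for a proper posterior, got n = {n}"
        )
    xbar = X.mean(axis=0)
    centered = X - xbar
    scatter = centered.T @ centered
    cond = np.linalg.cond(scatter)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            "scatter matrix is numerically singular (degenerate data)"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Sigma first, then mu | Sigma, from the single stream.
    sigmas = invwishart.rvs(df=n - 1, scale=scatter, size=n_draws, random_state=rng)
    sigmas = np.asarray(sigmas, dtype=float).reshape(n_draws, d, d)
    chol = np.linalg.cholesky(sigmas / n)
    z = rng.standard_normal((n_draws, d))
    mus = xbar + np.einsum("nij,nj->ni", chol, z)
    return PosteriorDraws(label, mus, sigmas, source_n=n)


def draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Flatten draws to a table: draw index, mu components, lower-triangle Sigma."""
    d = draws.d
    cols = {"draw": np.arange(draws.n_draws)}
    for j in range(d):
        cols[f"mu_{j}"] = draws.mu_draws[:, j]
    for i in range(d):
        for j in range(i + 1):
            cols[f"sigma_{i}{j}"] = draws.sigma_draws[:, i, j]
    return pd.DataFrame(cols)


def export_draws_csv(draws: PosteriorDraws, path) -> None:
    """Audit export of posterior draws to CSV."""
    draws_to_frame(draws).to_csv(path, index=False)
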