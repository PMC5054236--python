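"""Bootstrap confidence intervals and robust-feature ranking.

A regularized logistic model is refit on B bootstrap resamples of the
documents (sampling rows with replacement); per-feature coefficient means
and SDs over the replicates give normal-approximation 95% confidence
intervals (mean +/- 1.96 SD).  Features are then ranked by the CI bound
facing away from zero: positively predictive features by descending CI
*lower* bound, negatively predictive features by ascending CI *upper*
bound — a feature ranks highly only if its coefficient is consistently
far from zero across resamples, not merely large once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .logreg import fit_logreg

logger = logging.getLogger("newsworthy")

Z_95 = 1.96  # normal-approximation 95% interval


@dataclass
class BootstrapSummary:
    """Per-feature coefficient statistics over bootstrap replicates."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    B: int
    lambda_policy: float
    seed: int
    samples: np.ndarray | None = None  # (B, n_features) if retained
    n_redraws: int = 0


def bootstrap_coefficients(
    X,
    y,
    lam: float,
    B: int = 1000,
    seed: int = 0,
    feature_names: list[str] | None = None,
    keep_samples: bool = False,
    stratified: bool = False,
    tol: float = 1e-4,
) -> BootstrapSummary:
    """Refit the model on B document resamples and summarize coefficients.

    ``lam`` is held fixed across replicates (typically the full-data
    cross-validated choice).  A replicate that happens to draw only one
    class is redrawn (logged); more than 10% redraws aborts, since then the
    bootstrap distribution is no longer a plain resample.  ``stratified``
    resamples within each class instead, preserving the class balance.
    The default optimizer tolerance is modest because between-replicate
    resampling variation dwarfs the last digits of each fit.
    """
    y = np.asarray(y).ravel()
    n = y.shape[0]
    if B < 2:
        raise ValueError("B must be >= 2")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length must match X columns")

    import scipy.sparse as sp
    if sp.issparse(X) and X.dtype != np.float64:
        X = X.astype(np.float64)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == np.max(y))
    neg_idx = np.flatnonzero(y != np.max(y))
    coefs = np.empty((B, p))
    n_redraws = 0
    max_redraws = int(np.ceil(0.1 * B))
    for b in range(B):
        while True:
            if stratified:
                idx = np.concatenate([
                    rng.choice(pos_idx, size=pos_idx.size, replace=True),
                    rng.choice(neg_idx, size=neg_idx.size, replace=True),
                ])
            else:
                idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == 2:
                break
            n_redraws += 1
            logger.warning("bootstrap replicate %d drew a single class; redrawing", b)
            if n_redraws > max_redraws:
                raise RuntimeError(
                    f"more than 10% of bootstrap replicates ({n_redraws}) drew a single class"
                )
        coefs[b] = fit_logreg(X[idx], y[idx], lam, tol=tol).w

    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    return BootstrapSummary(
        features=list(feature_names),
        mean=mean,
        sd=sd,
        ci_lower=mean - Z_95 * sd,
        ci_upper=mean + Z_95 * sd,
        B=B,
        lambda_policy=lam,
        seed=seed,
        samples=coefs if keep_samples else None,
        n_redraws=n_redraws,
    )


def rank_features(
    summary: BootstrapSummary, direction: str = "positive", top_n: int = 25
) -> list[dict]:
    """Rank features by the conservative CI bound.

    direction="positive": descending CI lower bound (a high lower bound
    means the coefficient is reliably positive); direction="negative":
    ascending CI upper bound.  Ties break by mean, then lexicographically.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    n_feat = len(summary.features)
    if top_n > n_feat:
        logger.info("top_n=%d exceeds feature count %d; returning all", top_n, n_feat)
        top_n = n_feat
    rows = list(range(n_feat))
    if direction == "positive":
        rows.sort(key=lambda j: (-summary.ci_lower[j], -summary.mean[j], summary.features[j]))
    else:
        rows.sort(key=lambda j: (summary.ci_upper[j], summary.mean[j], summary.features[j]))
    return [
        {
            "rank": r + 1,
            "feature": summary.features[j],
            "mean": float(summary.mean[j]),
            "ci_lower": float(summary.ci_lower[j]),
            "ci_upper": float(summary.ci_upper[j]),
        }
        for r, j in enumerate(rows[:top_n])
    ]


def coefficient_density(
    summary: BootstrapSummary, feature: str, n_points: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density estimate of a feature's bootstrap coefficient values.

    Gaussian KDE with Silverman's bandwidth, evaluated on a regular grid
    padded by three bandwidths, renormalized so the trapezoid-rule integral
    is 1.  Requires replicate samples retained via ``keep_samples=True``.
    """
    if summary.samples is None:
        raise ValueError(
            "replicate samples were not retained; rerun bootstrap_coefficients(keep_samples=True)"
        )
    try:
        j = summary.features.index(feature)
    except ValueError:
        raise KeyError(f"unknown feature {feature!r}") from None
    vals = summary.samples[:, j]
    spread = vals.std(ddof=1) if vals.size > 1 else 0.0
    if spread == 0.0:
        # degenerate replicates: represent a spike at the common value
        c = float(vals[0])
        h = max(abs(c), 1.0) * 1e-6
        grid = np.linspace(c - 4 * h, c + 4 * h, n_points)
        dens = np.exp(-0.5 * ((grid - c) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    else:
        kde = gaussian_kde(vals, bw_method="silverman")
        h = spread * kde.factor
        grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, n_points)
        dens = kde(grid)
    dens = dens / np.trapezoid(dens, grid)
    return grid, dens
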