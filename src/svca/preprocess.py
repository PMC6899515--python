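"""Expression preprocessing chain for count-based spatial data.

Raw counts from multiplexed imaging are approximately negative-binomially
distributed (variance = mu + phi * mu^2). The chain applied before model
fitting is:

1. fit a global NB dispersion phi across genes,
2. variance-stabilize counts with the Anscombe-type transform
   y = log(x + 1/(2*phi)),
3. regress the log total per-cell signal out of every gene (removes
   cell-level "brightness" batch effects),
4. rank-Gaussianize the target gene only (probit of r/(N+1)), which makes
   the Gaussian-noise assumption of the model robust to outliers.

Steps 1-3 produce the cell-state matrix X; step 4 produces the modeled
target vector y. For data that is already continuous (e.g. simulated
Gaussian fields), steps 1-2 are skipped.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "fit_dispersion",
    "stabilize",
    "regress_out_total",
    "rank_gauss",
    "preprocess_counts",
    "standardize_columns",
]


def fit_dispersion(counts: np.ndarray) -> float:
    """Least-squares NB dispersion from the per-gene moment relation.

    Minimizes sum_d (var_d - mean_d - phi * mean_d**2)**2 over phi >= 0;
    the objective is quadratic in phi so the minimizer is closed-form.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    mu = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    if np.count_nonzero(var > 0) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    denom = float(np.sum(mu**4))
    if denom == 0:
        raise ValueError("all-zero counts: no signal to estimate dispersion")
    phi = float(np.sum((var - mu) * mu**2) / denom)
    return max(phi, 0.0)


def stabilize(counts: np.ndarray, phi: float) -> np.ndarray:
    """Anscombe-type variance stabilization for NB counts: log(x + 1/(2 phi))."""
    counts = np.asarray(counts, dtype=float)
    if phi <= 0:
        warnings.warn(
            "dispersion is zero (Poisson-like); falling back to log(x + 0.5)",
            stacklevel=2,
        )
        return np.log(counts + 0.5)
    return np.log(counts + 1.0 / (2.0 * phi))


def regress_out_total(stabilized: np.ndarray, raw_totals: np.ndarray) -> np.ndarray:
    """OLS residuals of each gene on [1, log(total signal)].

    Removes per-cell scaling ("brightness") effects; residuals are mean-zero
    per gene and orthogonal to the log totals.
    """
    stabilized = np.asarray(stabilized, dtype=float)
    raw_totals = np.asarray(raw_totals, dtype=float)
    if np.any(raw_totals <= 0):
        raise ValueError("totals must be strictly positive")
    log_t = np.log(raw_totals)
    if np.ptp(log_t) == 0:
        warnings.warn("log total is constant across cells; only centering", stacklevel=2)
        return stabilized - stabilized.mean(axis=0)
    design = np.column_stack([np.ones_like(log_t), log_t])
    coef, *_ = np.linalg.lstsq(design, stabilized, rcond=None)
    return stabilized - design @ coef


def rank_gauss(y: np.ndarray) -> np.ndarray:
    """Rank-based Gaussianization: probit of r/(N+1), ties get average ranks."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant vector: ranks undefined for modeling")
    ranks = rankdata(y, method="average")
    return ndtri(ranks / (n + 1.0))


def preprocess_counts(counts: np.ndarray, phi: float | None = None) -> np.ndarray:
    """Full matrix chain: stabilize NB counts then regress out the log total.

    ``phi`` defaults to the globally fitted dispersion of ``counts``.
    """
    counts = np.asarray(counts, dtype=float)
    if phi is None:
        phi = fit_dispersion(counts)
    stab = stabilize(counts, phi)
    totals = counts.sum(axis=1)
    return regress_out_total(stab, totals)


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Mean-center and unit-variance scale columns; constant columns stay zero."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd
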