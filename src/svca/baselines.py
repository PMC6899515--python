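"""Baseline comparison models: three ridge regressions with different
neighborhood featurizations, and the reduced GP without the environmental
term.

The ridge baselines model the target gene as a linear function of the
cell's own state block (all other genes) plus an interaction block built
from neighbor profiles; their cell-cell variance attribution is the
empirical variance of the fitted interaction-block contribution divided by
the variance of the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import RidgeCV

from .data import SpatialExpressionImage, pairwise_distances
from .model import FittedModel, fit, variance_signature
from .preprocess import rank_gauss, standardize_columns
from .simulate import LinearSimConfig, simulate_linear

__all__ = [
    "BaselineSpec",
    "build_features",
    "fit_ridge",
    "fit_reduced_gp",
    "ridge_cell_cell_fraction",
    "benchmark",
]

RIDGE_KINDS = ("ridge_all_weighted", "ridge_knn_mean", "ridge_knn_weighted")
DEFAULT_ALPHAS = np.logspace(-3, 3, 13)


@dataclass
class BaselineSpec:
    """Which baseline to run and its neighborhood settings."""

    kind: str = "ridge_knn_mean"
    k_neighbors: int = 5

    def __post_init__(self):
        if self.kind not in RIDGE_KINDS + ("reduced_gp",):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _inverse_square(d: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / d**2
    if np.any(np.isinf(w)):
        finite = w[np.isfinite(w)]
        cap = finite[finite > 0].max() if np.any(finite > 0) else 1.0
        w = np.where(np.isinf(w), cap, w)
    return w


def build_features(
    image: SpatialExpressionImage, spec: BaselineSpec, target_gene: str
) -> tuple[np.ndarray, np.ndarray]:
    """(intrinsic block, interaction block) for a ridge baseline.

    Intrinsic block: standardized expression of all genes but the target.
    Interaction block: neighbor profiles aggregated per ``spec.kind`` --
    inverse-square-distance weights over all cells, the plain mean of the k
    nearest neighbors, or their inverse-square-weighted average.
    """
    if spec.kind == "reduced_gp":
        raise ValueError("reduced_gp has no feature representation")
    gi = image.gene_index(target_gene)
    x = standardize_columns(np.delete(image.expression, gi, axis=1))
    d = pairwise_distances(image)
    n = image.n_cells
    w = _inverse_square(d)
    np.fill_diagonal(w, 0.0)
    if spec.kind == "ridge_all_weighted":
        z = w
    else:
        z = np.zeros((n, n))
        for i in range(n):
            dd = d[i].copy()
            dd[i] = np.inf
            nbr = np.argsort(dd, kind="stable")[: spec.k_neighbors]
            if spec.kind == "ridge_knn_mean":
                z[i, nbr] = 1.0 / spec.k_neighbors
            else:  # ridge_knn_weighted
                ww = w[i, nbr]
                z[i, nbr] = ww / ww.sum()
    return x, z @ x


def fit_ridge(features: tuple[np.ndarray, np.ndarray], y: np.ndarray, cv_folds: int = 5):
    """Ridge fit over both blocks with CV-chosen penalty and variance attribution.

    Returns (fitted RidgeCV model, estimated cell-cell variance fraction):
    the fraction is var(interaction-block contribution) / var(y).
    """
    intr, inter = features
    intr = standardize_columns(intr)
    inter = standardize_columns(inter)
    design = np.column_stack([intr, inter])
    if not np.all(np.isfinite(design)):
        raise ValueError("non-finite features")
    y = np.asarray(y, dtype=float)
    model = RidgeCV(alphas=DEFAULT_ALPHAS, cv=cv_folds)
    model.fit(design, y)
    coef = model.coef_
    contrib_cc = inter @ coef[intr.shape[1]:]
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("target has zero variance")
    fraction = float(np.var(contrib_cc) / var_y)
    return model, fraction


def ridge_cell_cell_fraction(
    image: SpatialExpressionImage, target_gene: str, spec: BaselineSpec, cv_folds: int = 5
) -> float:
    """Convenience wrapper: features + rank-Gaussianized target + ridge fit."""
    feats = build_features(image, spec, target_gene)
    y = rank_gauss(image.expression[:, image.gene_index(target_gene)])
    _, fraction = fit_ridge(feats, y, cv_folds=cv_folds)
    return fraction


def fit_reduced_gp(
    image: SpatialExpressionImage, gene: str, grid=None, n_restarts: int = 1, seed: int = 0
) -> FittedModel:
    """The GP model without the environmental term (intrinsic + cell-cell + noise)."""
    return fit(
        image,
        gene,
        grid=grid,
        components=("intrinsic", "cell_cell"),
        n_restarts=n_restarts,
        seed=seed,
    )


def benchmark(
    images,
    configs,
    methods=("svca", "reduced_gp") + RIDGE_KINDS,
    *,
    grid_size: int = 5,
    n_restarts: int = 1,
    target_name: str = "target",
) -> pd.DataFrame:
    """Run the linear-simulation benchmark over methods and settings.

    For each image and each LinearSimConfig, an in-silico target gene is
    simulated, every requested method is fitted on the (mis-segmentation-
    perturbed) data, and the estimated cell-cell variance fraction plus its
    signed error against the simulated share eta_cc is recorded.
    """
    from .model import default_length_grid

    rows = []
    for image in images:
        for config in configs:
            y, y_tilde, x_tilde = simulate_linear(image, config)
            expr = np.column_stack([x_tilde, y_tilde])
            sim_img = SpatialExpressionImage(
                image.image_id,
                image.positions,
                expr,
                list(image.gene_names) + [target_name],
            )
            grid = default_length_grid(sim_img, grid_size)
            for method in methods:
                try:
                    if method == "svca":
                        m = fit(sim_img, target_name, grid=grid,
                                n_restarts=n_restarts, seed=config.seed)
                        est = variance_signature(m).cell_cell
                    elif method == "reduced_gp":
                        m = fit_reduced_gp(sim_img, target_name, grid=grid,
                                           n_restarts=n_restarts, seed=config.seed)
                        est = variance_signature(m).cell_cell
                    else:
                        est = ridge_cell_cell_fraction(
                            sim_img, target_name, BaselineSpec(kind=method)
                        )
                except (RuntimeError, ValueError) as exc:  # pragma: no cover
                    import warnings

                    warnings.warn(f"{method} failed on {image.image_id}: {exc}", stacklevel=2)
                    continue
                rows.append(
                    {
                        "image_id": image.image_id,
                        "method": method,
                        "eta_cc": config.eta_cc,
                        "eta_mis": config.eta_mis,
                        "n_nn": config.n_nn,
                        "seed": config.seed,
                        "estimate": est,
                        "error": est - config.eta_cc,
                    }
                )
    return pd.DataFrame(rows)
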