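"""Gaussian-process variance component model for one (image, target gene).

The processed target vector y is modeled as

    y ~ N(0, s_int * K_int + s_env * K_env + s_cc * K_cc + s_noise * I)

with Gower-normalized kernels, so each non-negative scale s reads directly
as a variance contribution. Scales are optimized by L-BFGS on log-scales
(positivity by construction) with analytic gradients; the shared length
scale of the environmental and neighborhood kernels is chosen by grid
search over a log-spaced grid anchored at the image's median pairwise cell
distance. Variance fractions are ratios of Gower factors of the fitted
terms; held-out cells are predicted by the GP posterior mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError
from scipy.optimize import minimize

from . import kernels as _k
from .data import SpatialExpressionImage
from .preprocess import rank_gauss, standardize_columns

__all__ = [
    "SVCAParameters",
    "FittedModel",
    "VarianceSignature",
    "log_marginal_likelihood",
    "fit",
    "variance_signature",
    "predict",
    "cross_validate",
    "default_length_grid",
]

FULL_COMPONENTS = ("intrinsic", "environmental", "cell_cell")
_JITTER = 1e-6
_NOISE_FLOOR = 1e-8


@dataclass
class SVCAParameters:
    """Variance scales (processed-target units) and shared length scale (um)."""

    sigma2_int: float = 0.0
    sigma2_env: float = 0.0
    sigma2_cc: float = 0.0
    sigma2_noise: float = 1.0
    length_scale: float | None = None

    def scale(self, component: str) -> float:
        return {
            "intrinsic": self.sigma2_int,
            "environmental": self.sigma2_env,
            "cell_cell": self.sigma2_cc,
            "noise": self.sigma2_noise,
        }[component]


@dataclass
class VarianceSignature:
    """Per (image, gene) variance fractions; they sum to one."""

    image_id: str
    gene: str
    intrinsic: float
    environmental: float
    cell_cell: float
    noise: float

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.intrinsic, self.environmental, self.cell_cell, self.noise])


@dataclass
class FittedModel:
    """A fitted variance component model for one image and target gene."""

    image_id: str
    gene: str
    parameters: SVCAParameters
    included_components: tuple[str, ...]
    log_marginal_likelihood: float
    terms: dict = field(repr=False)
    # training data cached for prediction / null simulation
    y: np.ndarray = field(repr=False, default=None)
    x_state: np.ndarray = field(repr=False, default=None)
    positions: np.ndarray = field(repr=False, default=None)
    grid: np.ndarray = field(repr=False, default=None)

    def total_covariance(self) -> np.ndarray:
        k = np.zeros_like(self.terms["noise"].matrix)
        for name, term in self.terms.items():
            k = k + self.parameters.scale(name) * term.matrix
        return k


def log_marginal_likelihood(params: SVCAParameters, terms: dict, y: np.ndarray) -> float:
    """Exact Gaussian log density of y under N(0, sum_k s_k K_k).

    Computed through a Cholesky factorization (never an explicit inverse).
    """
    y = np.asarray(y, dtype=float)
    k = np.zeros((y.shape[0], y.shape[0]))
    for name, term in terms.items():
        k = k + params.scale(name) * term.matrix
    return _gaussian_logpdf(k, y)


def _gaussian_logpdf(k: np.ndarray, y: np.ndarray) -> float:
    n = y.shape[0]
    jitter = _JITTER * max(np.trace(k) / n, 1.0)
    for _ in range(6):
        try:
            c, lower = cho_factor(k + jitter * np.eye(n), lower=True)
            break
        except LinAlgError:
            jitter *= 10.0
    else:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (trace {np.trace(k):.3g}, "
            f"final jitter {jitter:.3g})"
        )
    alpha = cho_solve((c, lower), y)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi))


def default_length_grid(image_or_distances, n_grid: int = 8) -> np.ndarray:
    """Log-spaced grid from 0.05x to 1.0x the median pairwise cell distance."""
    if isinstance(image_or_distances, SpatialExpressionImage):
        med = image_or_distances.median_distance()
    else:
        d = np.asarray(image_or_distances, dtype=float)
        med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if med <= 0:
        raise ValueError("median pairwise distance must be positive")
    return np.geomspace(0.05 * med, med, n_grid)


def _nll_and_grad(theta: np.ndarray, mats: list[np.ndarray], y: np.ndarray):
    """Negative log marginal likelihood and gradient w.r.t. log-scales."""
    n = y.shape[0]
    s = np.exp(theta)
    k = np.zeros((n, n))
    for si, m in zip(s, mats):
        k += si * m
    jitter = _JITTER * max(np.trace(k) / n, 1.0)
    k[np.diag_indices_from(k)] += jitter
    try:
        c = cholesky(k, lower=True)
    except LinAlgError:
        return np.inf, np.zeros_like(theta)
    alpha = cho_solve((c, True), y)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.5 * (y @ alpha) + 0.5 * logdet + 0.5 * n * np.log(2.0 * np.pi)
    kinv = cho_solve((c, True), np.eye(n))
    grad = np.empty_like(theta)
    for i, m in enumerate(mats):
        # d(-ll)/d s_i = 0.5 * (tr(K^-1 M) - alpha^T M alpha); chain rule for log-scale
        grad[i] = 0.5 * s[i] * (np.sum(kinv * m) - alpha @ (m @ alpha))
    return float(nll), grad


def _optimize_scales(mats, y, theta0_list, maxiter=500, tol=1e-6):
    best = None
    for theta0 in theta0_list:
        res = minimize(
            _nll_and_grad,
            np.clip(theta0, -30, 30),
            args=(mats, y),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-30.0, 30.0)] * len(theta0),
            options={"maxiter": maxiter, "ftol": tol},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit(
    image: SpatialExpressionImage,
    gene: str,
    grid=None,
    components=FULL_COMPONENTS,
    *,
    cell_indices=None,
    n_restarts: int = 3,
    seed: int = 0,
    assume_processed: bool = True,
) -> FittedModel:
    """Fit the variance component model for one target gene of one image.

    The image's expression matrix is expected to be on a continuous scale
    (counts should be run through the preprocessing chain first). Internally
    the non-target columns are standardized and the target is
    rank-Gaussianized; ``cell_indices`` restricts fitting to a subset of
    cells (processing statistics still use all cells, so cross-validation
    folds are commensurable).
    """
    if image.n_cells < 10:
        raise ValueError("model fitting requires at least 10 cells")
    components = tuple(c for c in FULL_COMPONENTS if c in components)
    if not components:
        raise ValueError("at least one structured component is required")
    gi = image.gene_index(gene)
    x_all = standardize_columns(np.delete(image.expression, gi, axis=1))
    y_all = rank_gauss(image.expression[:, gi])
    if cell_indices is None:
        idx = np.arange(image.n_cells)
    else:
        idx = np.asarray(cell_indices, dtype=int)
    x, y = x_all[idx], y_all[idx]
    positions = image.positions[idx]
    d = np.sqrt(_sq(positions))
    np.fill_diagonal(d, 0.0)

    needs_l = bool({"environmental", "cell_cell"} & set(components))
    if needs_l:
        grid = default_length_grid(d) if grid is None else np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("length-scale grid must be non-empty")
    else:
        grid = np.array([np.nan])

    rng = np.random.default_rng(seed)
    var_y = max(float(np.var(y)), 1e-3)
    n_scales = len(components) + 1
    theta_base = np.full(n_scales, np.log(var_y / n_scales))

    best = None  # (nll, l, scales, terms)
    warm = None
    for l in grid:
        l_val = None if np.isnan(l) else float(l)
        terms = _k.build_terms(x, d, l_val, components)
        mats = [terms[c].matrix for c in components] + [terms["noise"].matrix]
        starts = [theta_base]
        if warm is not None:
            starts.append(warm)
        starts += [theta_base + rng.normal(0, 1, n_scales) for _ in range(max(n_restarts - 1, 0))]
        res = _optimize_scales(mats, y, starts)
        if res is None:
            warnings.warn(f"optimization failed at length scale {l_val}", stacklevel=2)
            continue
        warm = res.x
        if best is None or res.fun < best[0] - 1e-12:
            best = (res.fun, l_val, np.exp(res.x), terms)
    if best is None:
        raise RuntimeError("model fitting failed at every length-scale grid point")

    nll, l_best, scales, terms = best
    by_comp = dict(zip(components, scales[:-1]))
    params = SVCAParameters(
        sigma2_int=by_comp.get("intrinsic", 0.0),
        sigma2_env=by_comp.get("environmental", 0.0),
        sigma2_cc=by_comp.get("cell_cell", 0.0),
        sigma2_noise=max(float(scales[-1]), _NOISE_FLOOR),
        length_scale=l_best,
    )
    return FittedModel(
        image_id=image.image_id,
        gene=gene,
        parameters=params,
        included_components=components,
        log_marginal_likelihood=-nll,
        terms=terms,
        y=y,
        x_state=x,
        positions=positions,
        grid=None if not needs_l else grid,
    )


def variance_signature(model: FittedModel) -> VarianceSignature:
    """Variance fractions: Gower factor of each scaled term over their sum."""
    gowers = {
        name: _k.gower_factor(model.parameters.scale(name) * term.matrix)
        for name, term in model.terms.items()
    }
    total = sum(gowers.values())
    if total <= 0:
        raise ValueError("degenerate fit: all variance scales are zero")
    frac = {name: g / total for name, g in gowers.items()}
    return VarianceSignature(
        image_id=model.image_id,
        gene=model.gene,
        intrinsic=frac.get("intrinsic", 0.0),
        environmental=frac.get("environmental", 0.0),
        cell_cell=frac.get("cell_cell", 0.0),
        noise=frac["noise"],
    )


def _cross_terms(model: FittedModel, x_test, pos_test) -> np.ndarray:
    """Cross-covariance K(test, train) using the fitted kernels.

    The intrinsic block uses test-cell state profiles; the environmental
    block uses test-train distances; the interaction block builds test-cell
    neighborhoods from training cells only (held-out target values must not
    leak through their own neighborhoods).
    """
    p = model.parameters
    n_test, n_train = x_test.shape[0], model.x_state.shape[0]
    k = np.zeros((n_test, n_train))
    # reuse the training Gower normalizations so cross blocks are on the same scale
    if "intrinsic" in model.terms:
        raw = model.x_state @ model.x_state.T
        _, g = _k.gower_normalize(raw)
        k += p.sigma2_int * (x_test @ model.x_state.T) / g
    d_cross = np.sqrt(
        ((pos_test[:, None, :] - model.positions[None, :, :]) ** 2).sum(-1)
    )
    if "environmental" in model.terms:
        raw = np.exp(
            -_sq(model.positions) / (2 * p.length_scale**2)
        )
        _, g = _k.gower_normalize(raw)
        k += p.sigma2_env * np.exp(-(d_cross**2) / (2 * p.length_scale**2)) / g
    if "cell_cell" in model.terms:
        z_train = _k.neighborhood_weights(
            np.sqrt(_sq(model.positions)), p.length_scale
        )
        b_train = z_train @ model.x_state
        _, g = _k.gower_normalize(b_train @ b_train.T)
        z_cross = np.exp(-(d_cross**2) / (2 * p.length_scale**2))
        b_test = z_cross @ model.x_state  # train-only neighborhoods
        k += p.sigma2_cc * (b_test @ b_train.T) / g
    return k


def _sq(pos: np.ndarray) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    return (diff**2).sum(-1)


def predict(model: FittedModel, train_idx, test_idx, image: SpatialExpressionImage) -> np.ndarray:
    """GP posterior mean for held-out cells: K_*(K + s_noise I)^-1 y."""
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if test_idx.size == 0:
        raise ValueError("empty test set")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets must be disjoint")
    gi = image.gene_index(model.gene)
    x_all = standardize_columns(np.delete(image.expression, gi, axis=1))
    x_test = x_all[test_idx]
    pos_test = image.positions[test_idx]
    k_cross = _cross_terms(model, x_test, pos_test)
    k_train = model.total_covariance()
    n = k_train.shape[0]
    jitter = _JITTER * max(np.trace(k_train) / n, 1.0)
    c = cho_factor(k_train + jitter * np.eye(n), lower=True)
    return k_cross @ cho_solve(c, model.y)


def cross_validate(
    image: SpatialExpressionImage,
    gene: str,
    k: int = 5,
    seed: int = 0,
    variants: dict | None = None,
    grid=None,
    n_restarts: int = 1,
) -> dict[str, float]:
    """k-fold out-of-sample r^2 of the GP posterior mean, per model variant.

    Default variants: intrinsic only; intrinsic + cell-cell ("local");
    the full three-component model.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if image.n_cells < 5 * k:
        raise ValueError("too few cells for the requested fold count")
    if variants is None:
        variants = {
            "intrinsic": ("intrinsic",),
            "intrinsic_local": ("intrinsic", "cell_cell"),
            "full": FULL_COMPONENTS,
        }
    rng = np.random.default_rng(seed)
    n = image.n_cells
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    gi = image.gene_index(gene)
    y_all = rank_gauss(image.expression[:, gi])

    out = {}
    for name, comps in variants.items():
        preds = np.empty(n)
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            m = fit(
                image, gene, grid=grid, components=comps,
                cell_indices=train, n_restarts=n_restarts, seed=seed,
            )
            preds[fold] = predict(m, train, fold, image)
        ss_res = float(np.sum((y_all - preds) ** 2))
        ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
        out[name] = 1.0 - ss_res / ss_tot
    return out
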