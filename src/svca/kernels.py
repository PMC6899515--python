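"""Covariance terms of the spatial variance component model.

Three structured terms plus iid noise enter the model covariance:

- intrinsic: linear kernel X X^T on the standardized cell-state matrix
  (all genes except the target) -- similarity of cells' own states;
- environmental: squared-exponential kernel exp(-d_ij^2 / (2 l^2)) on the
  pairwise cell distances -- smooth unobserved spatial factors;
- cell-cell interaction: Z X X^T Z^T, where Z is a zero-diagonal
  Gaussian-decay neighborhood weight matrix -- similarity of cells'
  distance-weighted neighborhood compositions.

Each structured kernel is divided by its own Gower factor before a scale
parameter multiplies it, so fitted scales read directly as variance
contributions on the scale of the (processed) target gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CovarianceTerm",
    "gower_factor",
    "gower_normalize",
    "intrinsic_covariance",
    "environmental_covariance",
    "neighborhood_weights",
    "interaction_covariance",
    "noise_covariance",
]

COMPONENTS = ("intrinsic", "environmental", "cell_cell")
KINDS = COMPONENTS + ("noise",)


@dataclass
class CovarianceTerm:
    """A named N x N covariance term, Gower-normalized unless degenerate."""

    kind: str
    matrix: np.ndarray
    length_scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        self.matrix = 0.5 * (m + m.T)


def gower_factor(k: np.ndarray) -> float:
    """Gower factor G(K) = tr(P K P) / (n - 1), P = I - 11^T/n.

    Equals the expected sample variance of a draw y ~ N(0, K):
    G(I) = 1 and G(ones) = 0.
    """
    k = np.asarray(k, dtype=float)
    n = k.shape[0]
    if k.ndim != 2 or k.shape[1] != n:
        raise ValueError("K must be square")
    if n < 2:
        raise ValueError("Gower factor requires at least 2 cells")
    # tr(PKP) = tr(KP) for symmetric K and projector P = tr(K) - 1^T K 1 / n
    return float((np.trace(k) - k.sum() / n) / (n - 1))


def gower_normalize(k: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide K by its Gower factor; a (near-)zero factor leaves K untouched.

    Returns the normalized matrix and the factor used (1.0 when degenerate).
    """
    g = gower_factor(k)
    scale = float(np.abs(k).max()) if k.size else 0.0
    if g <= 1e-12 * max(scale, 1.0):
        return k.copy(), 1.0
    return k / g, g


def intrinsic_covariance(x_minus_target: np.ndarray) -> CovarianceTerm:
    """Gower-normalized linear kernel X X^T on the standardized state matrix."""
    x = np.asarray(x_minus_target, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("state matrix must have at least one gene column")
    k, _ = gower_normalize(x @ x.T)
    return CovarianceTerm("intrinsic", k)


def environmental_covariance(distances: np.ndarray, length_scale: float) -> CovarianceTerm:
    """Gower-normalized squared-exponential kernel on cell distances."""
    if length_scale <= 0:
        raise ValueError("length scale must be positive")
    d = np.asarray(distances, dtype=float)
    k = np.exp(-(d**2) / (2.0 * length_scale**2))
    k, _ = gower_normalize(k)
    return CovarianceTerm("environmental", k, length_scale=length_scale)


def neighborhood_weights(distances: np.ndarray, length_scale: float) -> np.ndarray:
    """Zero-diagonal Gaussian-decay neighborhood weights Z_ij = exp(-d^2/(2 l^2))."""
    if length_scale <= 0:
        raise ValueError("length scale must be positive")
    d = np.asarray(distances, dtype=float)
    z = np.exp(-(d**2) / (2.0 * length_scale**2))
    np.fill_diagonal(z, 0.0)
    return z


def interaction_covariance(
    z: np.ndarray, x_minus_target: np.ndarray, length_scale: float | None = None
) -> CovarianceTerm:
    """Gower-normalized Z X X^T Z^T: covariance of neighborhood compositions."""
    x = np.asarray(x_minus_target, dtype=float)
    b = np.asarray(z, dtype=float) @ x
    k, _ = gower_normalize(b @ b.T)
    return CovarianceTerm("cell_cell", k, length_scale=length_scale)


def noise_covariance(n: int) -> CovarianceTerm:
    return CovarianceTerm("noise", np.eye(n))


def build_terms(
    x_minus_target: np.ndarray,
    distances: np.ndarray,
    length_scale: float | None,
    components=COMPONENTS,
) -> dict[str, CovarianceTerm]:
    """All requested structured terms (plus noise) at one shared length scale."""
    n = distances.shape[0]
    if length_scale is None and ({"environmental", "cell_cell"} & set(components)):
        raise ValueError("a length scale is required for spatial components")
    terms: dict[str, CovarianceTerm] = {}
    if "intrinsic" in components:
        terms["intrinsic"] = intrinsic_covariance(x_minus_target)
    if "environmental" in components:
        terms["environmental"] = environmental_covariance(distances, length_scale)
    if "cell_cell" in components:
        z = neighborhood_weights(distances, length_scale)
        terms["cell_cell"] = interaction_covariance(z, x_minus_target, length_scale)
    terms["noise"] = noise_covariance(n)
    return terms


def is_psd(k: np.ndarray, rtol: float = 1e-8) -> bool:
    """PSD check used by tests: min eigenvalue >= -rtol * trace / n."""
    w = np.linalg.eigvalsh(0.5 * (k + k.T))
    n = k.shape[0]
    return bool(w.min() >= -rtol * max(np.trace(k) / n, 1e-12))
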