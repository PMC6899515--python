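"""Data model for spatial expression images and the tabular formats around them.

An image is a set of segmented cells with 2D centroid coordinates (micrometers
by convention) and a cells x genes expression matrix. Cells are identified by
row order; the two tables of an image must therefore be row-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "SpatialExpressionImage",
    "load_image",
    "save_images_h5",
    "load_images_h5",
    "pairwise_distances",
    "write_signatures",
    "read_signatures",
]


@dataclass
class SpatialExpressionImage:
    """One image: cell positions, expression matrix and gene names.

    Parameters
    ----------
    image_id : str
        Identifier of the image.
    positions : (N, 2) ndarray
        Cell centroid coordinates, micrometers by convention.
    expression : (N, D) ndarray
        Expression values (raw counts or processed), one row per cell.
    gene_names : sequence of str
        Unique names for the D genes/proteins.
    """

    image_id: str
    positions: np.ndarray
    expression: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an N x 2 matrix")
        if self.expression.ndim != 2:
            raise ValueError("expression must be an N x D matrix")
        if self.positions.shape[0] != self.expression.shape[0]:
            raise ValueError(
                f"row count mismatch: {self.positions.shape[0]} positions vs "
                f"{self.expression.shape[0]} expression rows"
            )
        if len(self.gene_names) != self.expression.shape[1]:
            raise ValueError("gene_names length must equal number of expression columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene_names must be unique")
        if not np.all(np.isfinite(self.positions)):
            i, j = np.argwhere(~np.isfinite(self.positions))[0]
            raise ValueError(f"non-finite value in positions at row {i}, column {j}")
        if not np.all(np.isfinite(self.expression)):
            i, j = np.argwhere(~np.isfinite(self.expression))[0]
            raise ValueError(
                f"non-finite value in expression at row {i}, gene {self.gene_names[j]!r}"
            )
        if self.expression.shape[1] < 2:
            raise ValueError("at least 2 genes are required (D >= 2)")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in image {self.image_id!r}") from None

    def median_distance(self) -> float:
        """Median pairwise Euclidean cell distance (length-scale grid anchor)."""
        return float(np.median(pdist(self.positions)))


def load_image(expression_path, positions_path, image_id: str) -> SpatialExpressionImage:
    """Load an image from two row-aligned CSV files.

    The expression file has a header row of gene names, one row per cell.
    The positions file has columns named ``x`` and ``y``.
    """
    expr = pd.read_csv(expression_path)
    pos = pd.read_csv(positions_path)
    for col in ("x", "y"):
        if col not in pos.columns:
            raise ValueError(f"positions file must have a column named {col!r}")
    if len(expr) != len(pos):
        raise ValueError(
            f"row count mismatch: expression has {len(expr)} rows, positions {len(pos)}"
        )
    expr_values = expr.to_numpy()
    if not np.issubdtype(expr_values.dtype, np.number):
        bad = expr.columns[[not np.issubdtype(dt, np.number) for dt in expr.dtypes]]
        raise ValueError(f"non-numeric expression values in columns: {list(bad)}")
    return SpatialExpressionImage(
        image_id=image_id,
        positions=pos[["x", "y"]].to_numpy(dtype=float),
        expression=expr_values.astype(float),
        gene_names=list(expr.columns),
    )


def pairwise_distances(image: SpatialExpressionImage) -> np.ndarray:
    """Symmetric N x N matrix of Euclidean distances between cell centroids."""
    d = cdist(image.positions, image.positions)
    # enforce exact symmetry / zero diagonal against fp round-off
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


_SIGNATURE_COLUMNS = ["image_id", "gene", "intrinsic", "environmental", "cell_cell", "noise"]


def write_signatures(signatures, path) -> None:
    """Write variance signatures as a CSV table.

    ``signatures`` is an iterable of objects with attributes image_id, gene
    and fractions (intrinsic, environmental, cell_cell, noise), or an already
    assembled DataFrame with those columns.
    """
    if isinstance(signatures, pd.DataFrame):
        df = signatures[_SIGNATURE_COLUMNS]
    else:
        rows = [
            {
                "image_id": s.image_id,
                "gene": s.gene,
                "intrinsic": s.intrinsic,
                "environmental": s.environmental,
                "cell_cell": s.cell_cell,
                "noise": s.noise,
            }
            for s in signatures
        ]
        if not rows:
            raise ValueError("no signatures to write")
        df = pd.DataFrame(rows, columns=_SIGNATURE_COLUMNS)
    if df.empty:
        raise ValueError("no signatures to write")
    df.to_csv(path, index=False, float_format="%.8g")


def read_signatures(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_images_h5(images, path) -> None:
    """Bundle several images into one HDF5 file (one group per image)."""
    with h5py.File(path, "w") as f:
        for img in images:
            g = f.create_group(img.image_id)
            g.create_dataset("positions", data=img.positions)
            g.create_dataset("expression", data=img.expression)
            g.create_dataset(
                "gene_names", data=np.array(img.gene_names, dtype=h5py.string_dtype())
            )


def load_images_h5(path) -> list[SpatialExpressionImage]:
    images = []
    with h5py.File(path, "r") as f:
        for image_id in f:
            g = f[image_id]
            images.append(
                SpatialExpressionImage(
                    image_id=image_id,
                    positions=g["positions"][...],
                    expression=g["expression"][...],
                    gene_names=[s.decode() if isinstance(s, bytes) else str(s)
                                for s in g["gene_names"][...]],
                )
            )
    return images


def distance_matrix_valid(d: np.ndarray, atol: float = 1e-10) -> bool:
    """Check the invariants of a distance matrix (symmetry, zero diagonal, >= 0)."""
    return (
        d.ndim == 2
        and d.shape[0] == d.shape[1]
        and np.allclose(d, d.T, atol=atol)
        and np.allclose(np.diag(d), 0.0, atol=atol)
        and bool(np.all(d >= -atol))
    )
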