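"""Signature-level downstream analyses.

Variance signatures from many images are stacked into an images x
(gene, component) matrix, summarized by PCA, tested for gene-category
enrichment with a permutation running-sum statistic, and scored for
class separation along the centroid-connecting axis in PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .significance import bh_adjust

__all__ = [
    "stack_signatures",
    "pca_signatures",
    "enrichment_test",
    "separation_score",
    "EnrichmentResult",
]

_COMPONENTS = ("intrinsic", "environmental", "cell_cell", "noise")


@dataclass
class EnrichmentResult:
    category: str
    statistic: float
    p_value: float
    q_value: float = np.nan


def stack_signatures(signatures) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-image signatures into an images x (gene, component) matrix.

    ``signatures`` is an iterable of VarianceSignature-like objects or a tidy
    DataFrame with columns image_id, gene and the four fraction columns.
    Genes absent from any image are dropped with a warning. Returns the
    aligned matrix (MultiIndex columns) and per-gene cross-image mean
    fractions.
    """
    if isinstance(signatures, pd.DataFrame):
        df = signatures.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "image_id": s.image_id,
                    "gene": s.gene,
                    **{c: getattr(s, c) for c in _COMPONENTS},
                }
                for s in signatures
            ]
        )
    if df.empty:
        raise ValueError("no signatures provided")
    wide = df.pivot_table(
        index="image_id", columns="gene", values=list(_COMPONENTS), sort=False
    )
    wide = wide.swaplevel(axis=1).sort_index(axis=1)
    incomplete = [g for g in wide.columns.levels[0] if wide[g].isna().any().any()]
    if incomplete:
        warnings.warn(f"dropping genes missing in some images: {incomplete}", stacklevel=2)
        wide = wide.drop(columns=incomplete, level=0)
    if wide.shape[1] == 0 or wide.shape[0] < 2:
        raise ValueError("need at least 2 images sharing at least one gene")
    means = df.groupby("gene")[list(_COMPONENTS)].mean()
    return wide, means


def pca_signatures(matrix: pd.DataFrame, n_components: int = 2):
    """PCA of the column-centered signature matrix.

    Returns (scores DataFrame, loadings DataFrame, explained variance
    ratios). Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 images for PCA")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic signs
    for i in range(n_components):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = pd.DataFrame(
        u * s,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        vt.T, index=matrix.columns, columns=scores.columns
    )
    explained = (s**2) / max(np.sum(np.linalg.svd(centered, compute_uv=False) ** 2), 1e-300)
    return scores, loadings, explained


def _running_sum_height(order: np.ndarray, in_set: np.ndarray) -> float:
    """Maximum height of the unweighted running-sum (KS-like) trace."""
    member = in_set[order]
    n_in = int(member.sum())
    n_out = member.size - n_in
    steps = np.where(member, 1.0 / n_in, -1.0 / n_out)
    return float(np.max(np.cumsum(steps)))


def enrichment_test(
    component_values: pd.Series,
    categories: dict[str, str],
    n_perm: int = 10000,
    seed: int = 0,
    min_size: int = 6,
) -> pd.DataFrame:
    """Permutation enrichment of gene categories at the top of a ranking.

    Genes are ranked descending by ``component_values`` (e.g. per-gene mean
    cell-cell fractions); for each category with at least ``min_size`` genes
    the statistic is the maximum of the unweighted running-sum trace, and the
    empirical p-value is the add-one exceedance fraction over label
    permutations. Q-values are BH-adjusted across categories.
    """
    values = pd.Series(component_values).dropna()
    if values.empty:
        raise ValueError("empty ranking")
    genes = values.sort_values(ascending=False).index.to_numpy()
    cat_of = {g: categories.get(g) for g in genes}
    labels = sorted({c for c in cat_of.values() if c is not None})
    rng = np.random.default_rng(seed)
    order = np.arange(genes.size)

    rows = []
    memberships = {}
    for cat in labels:
        in_set = np.array([cat_of[g] == cat for g in genes])
        size = int(in_set.sum())
        if size < min_size or size == genes.size:
            warnings.warn(f"category {cat!r} has {size} genes; excluded", stacklevel=2)
            continue
        memberships[cat] = in_set
    if not memberships:
        raise ValueError("no category passes the minimum size filter")
    for cat, in_set in memberships.items():
        observed = _running_sum_height(order, in_set)
        exceed = 0
        for _ in range(n_perm):
            exceed += _running_sum_height(order, rng.permutation(in_set)) >= observed
        p = (1.0 + exceed) / (n_perm + 1.0)
        rows.append({"category": cat, "statistic": observed, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def separation_score(
    scores: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-class separation along the centroid-connecting axis in PC space.

    Samples are projected on the line between the two class centroids; the
    threshold maximizing 1 - sqrt((1-specificity)^2 + (1-sensitivity)^2) over
    both orientations gives the score. The permutation p-value shuffles the
    labels.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 members")

    def score_for(lab):
        a, b = (x[lab == c] for c in classes)
        axis = b.mean(axis=0) - a.mean(axis=0)
        norm = np.linalg.norm(axis)
        if norm == 0:
            return 1.0 - np.sqrt(0.5)  # coincident centroids: chance level
        proj = x @ (axis / norm)
        pos = lab == classes[1]
        cuts = np.concatenate([[proj.min() - 1], np.sort(proj)]) + 0.0
        best = -np.inf
        for t in cuts:
            above = proj > t
            for positive_side in (above, ~above):
                tp = np.sum(positive_side & pos)
                tn = np.sum(~positive_side & ~pos)
                sens = tp / pos.sum()
                spec = tn / (~pos).sum()
                s = 1.0 - np.sqrt((1 - spec) ** 2 + (1 - sens) ** 2)
                best = max(best, s)
        return float(best)

    observed = score_for(labels)
    rng = np.random.default_rng(seed)
    exceed = sum(score_for(rng.permutation(labels)) >= observed for _ in range(n_perm))
    p = (1.0 + exceed) / (n_perm + 1.0)
    return observed, float(p)
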