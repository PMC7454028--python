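"""Discriminant Analysis of Principal Components (DAPC).

Genotypes are encoded as per-(locus, allele) copy counts, mean-imputed and
centered, reduced by PCA, and the retained principal components are rotated
onto linear discriminant axes that maximize the between-group to
within-group variance ratio. Euclidean distances between group centroids in
the retained discriminant space serve as the genetic distance between demes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA

from .genotypes import GroupedGenotypes

logger = logging.getLogger(__name__)

__all__ = ["DapcModel", "encode_genotypes", "fit_dapc", "centroid_distance"]


def encode_genotypes(
    data: GroupedGenotypes, center: bool = True, scale: bool = False
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Numeric predictor matrix: one column per (locus, allele) holding that
    allele's copy count in {0, 1, 2}.

    Missing calls are imputed with the column mean; all-missing columns are
    dropped with a warning. Columns are centered by default (variance
    scaling optional). Returns the matrix and the (locus, allele) column key.
    """
    if data.n_individuals == 0:
        raise ValueError("empty genotype table")
    scored = data.scored_mask()
    cols, keys = [], []
    for l, locus in enumerate(data.loci):
        ok = scored[:, l]
        if not ok.any():
            logger.warning("locus %s is entirely missing; dropped", locus)
            continue
        pair = data.calls[:, l, :]
        for a in data.alleles(l):
            d = (pair == a).sum(axis=1).astype(np.float64)
            mean = d[ok].mean()
            d[~ok] = mean
            cols.append(d)
            keys.append((locus, int(a)))
    X = np.column_stack(cols) if cols else np.empty((data.n_individuals, 0))
    if center and X.size:
        X = X - X.mean(axis=0)
    if scale and X.size:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    return X, keys


@dataclass
class DapcModel:
    groups: list
    labels: np.ndarray  # group key per individual
    coords: np.ndarray  # (n, n_da_retained) discriminant coordinates
    centroids: dict  # group -> centroid in discriminant space
    eigenvalues: np.ndarray  # between/within ratios of all discriminant axes
    explained_variance: np.ndarray  # per retained axis, fraction of sum(eig)
    n_pca_retained: int
    n_da_retained: int
    pca_explained_variance_ratio: np.ndarray


def fit_dapc(
    data: GroupedGenotypes | np.ndarray,
    group_by: str | list[str] = "deme",
    labels: np.ndarray | None = None,
    n_pca: int = 50,
    n_da: int = 2,
    ridge: float = 1e-8,
) -> DapcModel:
    """Fit a DAPC with ``min(n_pca, rank)`` principal components and
    ``min(n_da, n_groups - 1)`` discriminant axes.

    Accepts a genotype table (grouped by ``group_by``) or a pre-encoded
    numeric matrix plus explicit ``labels``. A singular within-group scatter
    is ridge-regularized (logged).
    """
    if isinstance(data, GroupedGenotypes):
        X, _ = encode_genotypes(data)
        codes, keys = data.group_codes(group_by)
    else:
        if labels is None:
            raise ValueError("labels required with a raw matrix")
        X = np.asarray(data, dtype=float)
        keys_raw = list(labels)
        keys = list(dict.fromkeys(keys_raw))
        codes = np.asarray([keys.index(k) for k in keys_raw])
    P = len(keys)
    if P < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes, minlength=P)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two individuals")
    n = X.shape[0]

    rank = min(n - 1, X.shape[1])
    r = max(1, min(n_pca, rank))
    pca = PCA(n_components=r, svd_solver="full")
    Y = pca.fit_transform(X)
    # drop numerically null components (rank deficiency)
    keep = pca.explained_variance_ > max(
        1e-12, 1e-9 * pca.explained_variance_[0]
    )
    Y = Y[:, keep]
    r = Y.shape[1]

    # pooled within-group and between-group scatter on the PC scores
    means = np.vstack([Y[codes == g].mean(axis=0) for g in range(P)])
    Sw = np.zeros((r, r))
    for g in range(P):
        Z = Y[codes == g] - means[g]
        Sw += Z.T @ Z
    Sw /= max(1, n - P)
    grand = Y.mean(axis=0)
    Sb = np.zeros((r, r))
    for g in range(P):
        diff = (means[g] - grand)[:, None]
        Sb += sizes[g] * (diff @ diff.T)
    Sb /= max(1, P - 1)

    eps = 0.0
    for attempt in range(6):
        try:
            evals, evecs = scipy.linalg.eigh(Sb, Sw + eps * np.eye(r))
            break
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            eps = max(ridge * np.trace(Sw) / r, eps * 10 if eps else ridge)
            logger.warning("singular within-group scatter; ridge eps=%.3e", eps)
    else:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("discriminant eigenproblem failed")

    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    n_axes = min(n_da, P - 1, r)
    W = evecs[:, :n_axes]
    coords = Y @ W
    centroids = {keys[g]: coords[codes == g].mean(axis=0) for g in range(P)}
    total = evals[: P - 1].sum()
    explained = evals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    # keep tuple-valued group keys as scalars of an object array
    label_arr = np.empty(len(codes), dtype=object)
    label_arr[:] = [keys[c] for c in codes]
    return DapcModel(
        groups=keys,
        labels=label_arr,
        coords=coords,
        centroids=centroids,
        eigenvalues=evals[: P - 1],
        explained_variance=explained,
        n_pca_retained=r,
        n_da_retained=n_axes,
        pca_explained_variance_ratio=pca.explained_variance_ratio_[keep],
    )


def centroid_distance(model: DapcModel, group_a, group_b) -> float:
    """Euclidean distance between two group centroids across the retained
    discriminant axes (symmetric, >= 0)."""
    for g in (group_a, group_b):
        if g not in model.centroids:
            raise ValueError(f"unknown group {g!r}")
    return float(
        np.linalg.norm(model.centroids[group_a] - model.centroids[group_b])
    )


def centroid_distance_table(model: DapcModel):
    """All pairwise centroid distances as a tidy DataFrame."""
    import pandas as pd

    rows = []
    gs = model.groups
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            rows.append(
                {
                    "group_a": gs[i],
                    "group_b": gs[j],
                    "distance": centroid_distance(model, gs[i], gs[j]),
                }
            )
    return pd.DataFrame(rows)
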