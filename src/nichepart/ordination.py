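"""Ordination and permutational multivariate ANOVA.

Niche-overlap matrices are turned into dissimilarities (D = 1 - C by
default) and projected by principal coordinates analysis (PCoA, metric
multidimensional scaling): Gower double-centering B = -1/2 J D^2 J followed
by an eigendecomposition, keeping coordinates for positive eigenvalues and
reporting negative ones rather than hiding them.  A plain PCA of the binary
presence/absence matrix identifies the prey species driving sample
similarity.  Group effects (season, predator species) on a dissimilarity
matrix are tested with PERMANOVA: a pseudo-F from the partition of the
squared-distance sum, with a permutation p-value over random relabelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "PcoaResult",
    "PermanovaResult",
    "overlap_to_distance",
    "pcoa",
    "pca_presence",
    "permanova",
]


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    negative_eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    transform: str = "1-C"


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA table entry."""

    pseudo_F: float
    df_between: int
    df_within: int
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None


def overlap_to_distance(C: pd.DataFrame, sqrt: bool = False) -> pd.DataFrame:
    """Dissimilarity from an overlap matrix: D = 1 - C (or sqrt(1 - C)).

    The square-root form is metric for many overlap indices; the linear
    form is the default and negative eigenvalues it may induce in PCoA are
    reported, not dropped.
    """
    D = 1.0 - C
    if sqrt:
        D = np.sqrt(D.clip(lower=0.0))
    np.fill_diagonal(D.values, 0.0)
    return D


def _check_distance(D: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr


def pcoa(D: pd.DataFrame, n_axes: int | None = None,
         cailliez: bool = False) -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only; negative eigenvalues (non-Euclidean input) are kept in
    the diagnostics.  ``cailliez`` adds the smallest constant to
    off-diagonal dissimilarities that makes the configuration Euclidean.
    """
    labels = (
        D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(len(D))
    )
    arr = _check_distance(D)
    if cailliez:
        arr = _cailliez(arr)
    n = arr.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (arr**2) @ J
    # symmetrize against round-off before the symmetric eigensolver
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords,
            index=labels,
            columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eigvals,
        negative_eigenvalues=eigvals[eigvals < -tol],
        proportion_explained=prop,
    )


def _cailliez(arr: np.ndarray) -> np.ndarray:
    """Smallest additive constant making a dissimilarity Euclidean."""
    n = arr.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (arr**2) @ J
    d2 = -0.5 * J @ arr @ J
    top = np.hstack([np.zeros((n, n)), 2.0 * d1])
    bot = np.hstack([-np.eye(n), -4.0 * d2])
    c = np.max(np.real(np.linalg.eigvals(np.vstack([top, bot]))))
    out = arr + c
    np.fill_diagonal(out, 0.0)
    return out


def pca_presence(occ: pd.DataFrame, n_components: int | None = None):
    """PCA of a binary presence/absence matrix (column-centered SVD).

    Returns ``(scores, loadings, explained_variance_ratio)``; loadings rank
    the prey by their contribution to each axis, i.e. the species best
    explaining similarity among samples.
    """
    if occ.shape[0] < 2 or occ.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 prey")
    X = (occ > 0).astype(float).to_numpy()
    k = min(X.shape) if n_components is None else n_components
    k = min(k, min(X.shape[0] - 1, X.shape[1]))
    model = PCA(n_components=k)
    scores = model.fit_transform(X)
    axes = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=occ.index, columns=axes),
        pd.DataFrame(model.components_.T, index=occ.columns, columns=axes),
        model.explained_variance_ratio_,
    )


def permanova(
    D: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    SS_total = sum of squared distances / n; SS_within sums, per group, the
    squared within-group distances divided by the group size; pseudo-F =
    (SS_between / (g-1)) / (SS_within / (n-g)).  The p-value is the
    upper-tail fraction of label permutations (with the +1 correction)
    whose pseudo-F meets or exceeds the observed one.
    """
    arr = _check_distance(D)
    if isinstance(D, pd.DataFrame) and isinstance(labels, pd.Series):
        labels = labels.loc[D.index]
    lab = np.asarray(labels)
    if lab.shape[0] != arr.shape[0]:
        raise ValueError("labels do not match the distance matrix")
    groups, counts = np.unique(lab, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n, g = arr.shape[0], len(groups)
    d2 = arr**2

    def pseudo_f(assignment: np.ndarray) -> tuple[float, float]:
        ss_total = d2.sum() / (2.0 * n)
        ss_within = 0.0
        for grp, cnt in zip(groups, counts):
            idx = np.flatnonzero(assignment == grp)
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * cnt)
        ss_between = ss_total - ss_within
        with np.errstate(divide="ignore"):  # perfect separation -> F = inf
            f = (ss_between / (g - 1)) / (ss_within / (n - g))
        return f, ss_between / ss_total

    f_obs, r2 = pseudo_f(lab)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(lab[rng.permutation(n)])
        if f_perm >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_between=g - 1,
        df_within=n - g,
        R2=float(r2),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
    )
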