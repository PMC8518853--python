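"""RLQ ordination and fourth-corner tests linking predators, prey and traits.

Three tables are crossed: R (samples x predictors — predator-species
indicators and colony habitat composition), L (samples x prey detections,
the linking table) and Q (prey x ecological traits).  Habitat composition is
compositional, so it enters R through the additive log-ratio (ALR)
transform.

The fourth-corner statistic for a predictor x and a trait q is the
correlation through L: with cell weights p_ij = L_ij / L_++ and marginal
row/column weights r, c, both variables are weighted-standardized and

    r_xq = sum_ij p_ij * x_i~ * q_j~ ,

equal to the Pearson correlation on the table inflated to one record per
unit of L.  Significance combines two permutation models — permuting whole
samples (model 2, tests the link between R and L) and whole prey (model 4,
tests the link between Q and L) — as p6 = max(p2, p4), which controls type
I error when either link may be absent.  All p-values are two-sided with
the +1 correction and are adjusted jointly by Benjamini-Hochberg FDR.

RLQ generalizes this cell-by-cell view to an ordination: the correspondence
analysis of L supplies the weights under which R and Q are standardized, and
the crossed matrix of fourth-corner correlations is decomposed by SVD, each
eigenvalue being the squared co-inertia captured by an axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_model import SPECIES

__all__ = [
    "RlqResult",
    "FourthCornerResult",
    "alr_transform",
    "build_r_table",
    "fourth_corner_stat",
    "fourth_corner_test",
    "rlq",
    "bh_fdr",
]


@dataclass
class RlqResult:
    """Eigenvalues, scores and loadings of an RLQ ordination."""

    eigenvalues: np.ndarray
    sample_scores: pd.DataFrame
    prey_scores: pd.DataFrame
    env_loadings: pd.DataFrame
    trait_loadings: pd.DataFrame
    row_weights: pd.Series
    col_weights: pd.Series
    total_coinertia: float


@dataclass
class FourthCornerResult:
    """Trait x predictor fourth-corner grid with combined-model p-values.

    All frames are indexed by trait with one column per predictor.
    ``p_model6`` is the cell-wise max of the model-2 and model-4 p-values;
    ``p_adjusted`` applies BH-FDR across the whole grid jointly.
    """

    stat: pd.DataFrame
    p_model2: pd.DataFrame
    p_model4: pd.DataFrame
    p_model6: pd.DataFrame
    p_adjusted: pd.DataFrame
    alpha: float
    n_permutations: int
    seed: int | None

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_adjusted <= self.alpha

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (trait, predictor) cell."""
        rows = []
        for trait in self.stat.index:
            for pred in self.stat.columns:
                rows.append(
                    {
                        "trait": trait,
                        "predictor": pred,
                        "stat": self.stat.loc[trait, pred],
                        "p_model2": self.p_model2.loc[trait, pred],
                        "p_model4": self.p_model4.loc[trait, pred],
                        "p_model6": self.p_model6.loc[trait, pred],
                        "p_adjusted": self.p_adjusted.loc[trait, pred],
                        "significant": bool(
                            self.p_adjusted.loc[trait, pred] <= self.alpha
                        ),
                    }
                )
        return pd.DataFrame(rows)


def alr_transform(
    h: pd.DataFrame,
    ref: str = "farmland",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Additive log-ratio transform of compositional habitat rows.

    Each non-reference class j maps to ln((x_j + d) / (x_ref + d)); the
    reference column is dropped.  ``pseudocount`` d defaults to half the
    smallest non-zero proportion in the table (0 if no zeros are present),
    the usual multiplicative zero-replacement.  Scale-invariant: rescaling a
    row and renormalizing leaves the transform unchanged.
    """
    if ref not in h.columns:
        raise KeyError(f"reference column {ref!r} not in habitat table")
    vals = h.to_numpy(dtype=float)
    if pseudocount is None:
        nz = vals[vals > 0]
        pseudocount = 0.0 if (vals > 0).all() else float(nz.min()) / 2.0
    shifted = vals + pseudocount
    shifted = shifted / shifted.sum(axis=1, keepdims=True)
    refcol = shifted[:, h.columns.get_loc(ref)]
    if (refcol == 0).any():
        raise ValueError(
            f"reference column {ref!r} is zero even after the pseudocount"
        )
    out = np.log(shifted / refcol[:, None])
    frame = pd.DataFrame(out, index=h.index, columns=h.columns)
    return frame.drop(columns=ref)


def build_r_table(
    meta: pd.DataFrame,
    habitat: pd.DataFrame,
    use_alr: bool = True,
    ref: str = "farmland",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-sample predictor table R: species indicators + habitat predictors.

    Each sample gets one binary indicator per predator species and the
    habitat composition of its colony, ALR-transformed by default (5
    predictors for 6 classes) or raw proportions otherwise.
    """
    hab = alr_transform(habitat, ref=ref, pseudocount=pseudocount) if use_alr \
        else habitat
    present = [sp for sp in SPECIES if (meta["species"] == sp).any()]
    cols = {sp: (meta["species"] == sp).astype(float) for sp in present}
    r = pd.DataFrame(cols, index=meta.index)
    joined = hab.loc[meta["colony_id"]].set_axis(meta.index)
    return pd.concat([r, joined], axis=1)


def _weighted_standardize(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Center and scale columns to zero weighted mean and unit weighted
    variance; zero weighted variance is a degenerate variable."""
    mean = w @ X
    Xc = X - mean
    var = w @ Xc**2
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ValueError(f"degenerate variable (zero weighted variance) "
                         f"at column index {bad.tolist()}")
    return Xc / np.sqrt(var)


def _ca_weights(L: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    total = L.sum()
    if total <= 0:
        raise ValueError("linking table has no detections")
    P = L / total
    return P, P.sum(axis=1), P.sum(axis=0)


def fourth_corner_stat(
    L: pd.DataFrame | np.ndarray,
    x: pd.Series | np.ndarray,
    q: pd.Series | np.ndarray,
) -> float:
    """Fourth-corner correlation of one predictor with one trait through L.

    Equals the Pearson correlation of (x, q) on the inflated data table
    holding one record per unit of count in L.  Binary and ordinal
    variables are treated as quantitative scores.
    """
    Larr = np.asarray(L, dtype=float)
    xa = np.asarray(x, dtype=float)
    qa = np.asarray(q, dtype=float)
    if Larr.shape != (xa.size, qa.size):
        raise ValueError("dimension mismatch between L, x and q")
    if (Larr < 0).any():
        raise ValueError("L must be non-negative")
    P, r, c = _ca_weights(Larr)
    xs = _weighted_standardize(xa[:, None], r)[:, 0]
    qs = _weighted_standardize(qa[:, None], c)[:, 0]
    return float(xs @ P @ qs)


def _stat_grid(P: np.ndarray, r: np.ndarray, c: np.ndarray,
               X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Predictor x trait grid of fourth-corner correlations."""
    Xs = _weighted_standardize(X, r)
    Qs = _weighted_standardize(Q, c)
    return Xs.T @ P @ Qs


def fourth_corner_test(
    L: pd.DataFrame,
    R_table: pd.DataFrame,
    Q_table: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> FourthCornerResult:
    """Permutation fourth-corner tests for every (trait, predictor) pair.

    Model 2 permutes entire rows of L (equivalently, the sample rows of R);
    model 4 permutes entire columns of L (the prey rows of Q).  Per cell and
    model the two-sided p-value carries the +1 correction; the combined
    model-6 p is the max of the two, and BH-FDR is applied across the whole
    grid jointly.
    """
    if list(L.index) != list(R_table.index):
        raise ValueError("sample ids of L and R_table differ")
    if list(L.columns) != list(Q_table.index):
        raise ValueError("prey ids of L columns and Q_table rows differ")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    keep_rows = L.sum(axis=1) > 0
    keep_cols = L.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn(
            f"dropping {int((~keep_rows).sum())} empty sample row(s) and "
            f"{int((~keep_cols).sum())} empty prey column(s) of L",
            stacklevel=2,
        )
        L = L.loc[keep_rows, keep_cols]
        R_table = R_table.loc[keep_rows]
        Q_table = Q_table.loc[keep_cols]
    Larr = L.to_numpy(dtype=float)
    X = R_table.to_numpy(dtype=float)
    Q = Q_table.to_numpy(dtype=float)
    P, r, c = _ca_weights(Larr)

    obs = _stat_grid(P, r, c, X, Q)
    abs_obs = np.abs(obs)
    rng = np.random.default_rng(seed)

    PQ = P @ _weighted_standardize(Q, c)  # fixed part for model 2
    XP = _weighted_standardize(X, r).T @ P  # fixed part for model 4
    n, m = Larr.shape
    exceed2 = np.zeros_like(obs)
    exceed4 = np.zeros_like(obs)
    for _ in range(n_perm):
        Xp = _weighted_standardize(X[rng.permutation(n)], r)
        exceed2 += np.abs(Xp.T @ PQ) >= abs_obs - 1e-12
    for _ in range(n_perm):
        Qp = _weighted_standardize(Q[rng.permutation(m)], c)
        exceed4 += np.abs(XP @ Qp) >= abs_obs - 1e-12
    p2 = (1.0 + exceed2) / (1.0 + n_perm)
    p4 = (1.0 + exceed4) / (1.0 + n_perm)
    p6 = np.maximum(p2, p4)
    adj = bh_fdr(p6.ravel()).reshape(p6.shape)

    def frame(a: np.ndarray) -> pd.DataFrame:
        # grids are predictor x trait; Table-style output is trait x predictor
        return pd.DataFrame(
            a.T, index=Q_table.columns, columns=R_table.columns
        )

    return FourthCornerResult(
        stat=frame(obs),
        p_model2=frame(p2),
        p_model4=frame(p4),
        p_model6=frame(p6),
        p_adjusted=frame(adj),
        alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
    )


def rlq(
    R_table: pd.DataFrame,
    L: pd.DataFrame,
    Q_table: pd.DataFrame,
) -> RlqResult:
    """RLQ ordination of the predictor / linking / trait triplet.

    The correspondence analysis of L provides row weights D_r, column
    weights D_c and the chi-square residual matrix; R and Q columns are
    weighted-standardized under D_r and D_c.  The crossed matrix of
    fourth-corner correlations is decomposed by SVD; eigenvalues are
    squared singular values and sum to the total co-inertia.  Empty rows or
    columns of L are dropped with a warning before the analysis.
    """
    if list(L.index) != list(R_table.index):
        raise ValueError("sample ids of L and R_table differ")
    if list(L.columns) != list(Q_table.index):
        raise ValueError("prey ids of L columns and Q_table rows differ")
    keep_rows = L.sum(axis=1) > 0
    keep_cols = L.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn(
            f"dropping {int((~keep_rows).sum())} empty sample row(s) and "
            f"{int((~keep_cols).sum())} empty prey column(s) of L",
            stacklevel=2,
        )
        L = L.loc[keep_rows, keep_cols]
        R_table = R_table.loc[keep_rows]
        Q_table = Q_table.loc[keep_cols]
    Larr = L.to_numpy(dtype=float)
    X = R_table.to_numpy(dtype=float)
    Q = Q_table.to_numpy(dtype=float)
    P, r, c = _ca_weights(Larr)
    Xs = _weighted_standardize(X, r)
    Qs = _weighted_standardize(Q, c)
    M = Xs.T @ P @ Qs  # crossed fourth-corner matrix (predictors x traits)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    eig = S**2
    k = eig.size
    axes = [f"AxcR{i + 1}" for i in range(k)]
    return RlqResult(
        eigenvalues=eig,
        sample_scores=pd.DataFrame(Xs @ U, index=L.index, columns=axes),
        prey_scores=pd.DataFrame(Qs @ Vt.T, index=L.columns, columns=axes),
        env_loadings=pd.DataFrame(U, index=R_table.columns, columns=axes),
        trait_loadings=pd.DataFrame(Vt.T, index=Q_table.columns, columns=axes),
        row_weights=pd.Series(r, index=L.index),
        col_weights=pd.Series(c, index=L.columns),
        total_coinertia=float(np.sum(M**2)),
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
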