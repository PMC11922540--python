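"""Paired-method consistency: Spearman grids, BH-FDR, clustering, co-inertia.

The comparison layer between the microscopy and metabarcoding views of the
same community: rank correlations between every (microscopy feature, ASV
feature) pair over shared samples — with pairwise-complete handling of
masked cells — Benjamini–Hochberg control of the false discovery rate over
each grid, the critical |r| at a given alpha, heatmap leaf ordering by
complete-linkage clustering, and the RV coefficient / co-inertia
decomposition measuring the global co-structure of the two tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import rankdata, t as student_t
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationGrid",
    "CoinertiaResult",
    "spearman_grid",
    "spearman_pair",
    "critical_r",
    "count_correlations",
    "heatmap_order",
    "rv_coefficient",
    "coinertia",
]


@dataclass
class CorrelationGrid:
    """All-pairs Spearman correlations between two feature tables.

    ``r``, ``p``, ``q``, ``n`` are row-feature × column-feature DataFrames
    (NaN where fewer than ``min_n`` complete pairs or zero rank variance);
    ``q`` holds BH-adjusted p-values computed jointly over every defined
    cell of the grid; ``significant`` is the boolean mask q ≤ alpha.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame
    alpha: float
    significant: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.significant = (self.q <= self.alpha).fillna(False)

    def write(self, prefix) -> None:
        """Serialize as three TSV matrices plus a JSON summary."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        self.r.to_csv(f"{prefix}_r.tsv", sep="\t")
        self.p.to_csv(f"{prefix}_p.tsv", sep="\t")
        self.q.to_csv(f"{prefix}_q.tsv", sep="\t")
        neg, pos = count_correlations(self)
        summary = {
            "alpha": self.alpha,
            "n_cells": int(self.r.size),
            "n_defined": int(self.r.notna().values.sum()),
            "n_negative_significant": neg,
            "n_positive_significant": pos,
            "median_n_per_pair": float(np.nanmedian(self.n.values)),
        }
        with open(f"{prefix}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def spearman_pair(
    x: np.ndarray, y: np.ndarray, min_n: int = 4, exact: bool = False
) -> tuple[float, float, int]:
    """Spearman r and two-sided p for one pair, pairwise-complete.

    Masked (NaN) samples are dropped pairwise.  r is the Pearson
    correlation of average ranks; p comes from the t approximation
    t = r sqrt((n−2)/(1−r²)) on n−2 df, or from full enumeration of rank
    permutations when ``exact`` (only sensible for n ≤ 12 — the exact null
    is used instead of the t tail).  Returns (nan, nan, n) when fewer than
    ``min_n`` complete pairs remain or either variable has no rank
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_n:
        return float("nan"), float("nan"), n
    rx = rankdata(x[ok], method="average")
    ry = rankdata(y[ok], method="average")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan"), n
    r = float(np.clip(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy), -1, 1))
    if exact:
        if n > 12:
            raise ValueError("exact permutation p only supported for n <= 12")
        null = []
        base = np.argsort(np.argsort(x[ok]))
        for perm in itertools.permutations(range(n)):
            py = ry[list(perm)]
            null.append(((rx - rx.mean()) * (py - py.mean())).mean() / (sx * sy))
        null = np.abs(np.asarray(null))
        p = float((null >= abs(r) - 1e-12).mean())
        return r, p, n
    if abs(r) == 1.0:
        return r, 0.0, n
    t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * student_t.sf(abs(t_stat), df=n - 2))
    return r, p, n


def spearman_grid(
    X: pd.DataFrame, Y: pd.DataFrame, alpha: float = 0.05, min_n: int = 4
) -> CorrelationGrid:
    """Spearman correlation of every X column against every Y column.

    X and Y are sample × feature tables over a shared sample index (the
    intersection is used).  BH adjustment is applied once, jointly, over
    every defined cell of the grid — one family per grid.
    """
    samples = X.index.intersection(Y.index)
    if len(samples) < min_n:
        raise ValueError(
            f"only {len(samples)} shared samples; need at least {min_n}"
        )
    Xs, Ys = X.loc[samples], Y.loc[samples]
    r = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns, dtype=float)
    p = r.copy()
    nmat = pd.DataFrame(0, index=X.columns, columns=Y.columns, dtype=int)
    for xi in X.columns:
        xv = Xs[xi].to_numpy(dtype=float)
        for yj in Y.columns:
            rij, pij, nij = spearman_pair(xv, Ys[yj].to_numpy(dtype=float), min_n)
            r.loc[xi, yj] = rij
            p.loc[xi, yj] = pij
            nmat.loc[xi, yj] = nij
    q = p.copy()
    flat = p.values.ravel()
    defined = ~np.isnan(flat)
    if defined.any():
        _, q_adj, _, _ = multipletests(flat[defined], alpha=alpha, method="fdr_bh")
        qflat = np.full_like(flat, np.nan)
        qflat[defined] = q_adj
        q = pd.DataFrame(qflat.reshape(p.shape), index=p.index, columns=p.columns)
    return CorrelationGrid(r=r, p=p, q=q, n=nmat, alpha=alpha)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at two-sided ``alpha`` for n paired samples.

    Inverts the t approximation: r* = t / sqrt(n − 2 + t²) with t the
    (1 − alpha/2) Student-t quantile on n − 2 df.  For n = 27 at
    alpha = 0.05 this is 0.381 — the "r ≥ |0.38|" reliability threshold
    quoted for 27-sample monitoring designs.
    """
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t_crit = student_t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def count_correlations(grid: CorrelationGrid) -> tuple[int, int]:
    """(negative, positive) counts of significant cells of a grid."""
    sig = grid.significant.values
    r = grid.r.values
    neg = int((sig & (r < 0)).sum())
    pos = int((sig & (r > 0)).sum())
    return neg, pos


def heatmap_order(r_matrix: pd.DataFrame) -> tuple[list, list]:
    """Leaf orders for heatmap display of a correlation matrix.

    Rows and columns are clustered independently with complete-linkage
    agglomeration on Euclidean distances.  Undefined correlations are
    imputed as 0 for the distance computation only.  Labels are pre-sorted
    so equal profiles tie-break deterministically by label.
    """

    def order_axis(mat: pd.DataFrame) -> list:
        if mat.shape[0] <= 1:
            return list(mat.index)
        mat = mat.sort_index()
        values = mat.fillna(0.0).to_numpy(dtype=float)
        Z = linkage(values, method="complete", metric="euclidean")
        return [mat.index[i] for i in leaves_list(Z)]

    return order_axis(r_matrix), order_axis(r_matrix.T)


def _center(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    A = np.asarray(X, dtype=float)
    return A - A.mean(axis=0, keepdims=True)


def rv_coefficient(X, Y) -> float:
    """RV coefficient between two column-centered sample × feature tables.

    RV = tr(XᵀY YᵀX) / sqrt(tr((XᵀX)²) · tr((YᵀY)²)), a matrix
    generalization of squared correlation: 0 for unrelated configurations,
    1 when one configuration is a rotation/dilation of the other.
    """
    A, B = _center(X), _center(Y)
    if A.shape[0] != B.shape[0]:
        raise ValueError("tables must share the sample dimension")
    den_a = np.sum((A.T @ A) ** 2)
    den_b = np.sum((B.T @ B) ** 2)
    if den_a == 0 or den_b == 0:
        raise ValueError("zero total variance in one of the tables")
    num = np.sum((A.T @ B) ** 2)  # tr(XᵀY YᵀX) = ||XᵀY||_F²
    return float(num / np.sqrt(den_a * den_b))


@dataclass
class CoinertiaResult:
    """Co-inertia decomposition of two paired tables.

    ``rv``: the RV coefficient; ``axis_inertia``: squared singular values
    of the cross-covariance XᵀY/n (per-axis co-inertia); ``n_axes``: axes
    retained; ``row_axes`` / ``col_axes``: loading vectors of the retained
    axes for the X and Y features.
    """

    rv: float
    axis_inertia: np.ndarray
    n_axes: int
    row_axes: np.ndarray
    col_axes: np.ndarray

    @property
    def total_inertia(self) -> float:
        return float(self.axis_inertia.sum())


def coinertia(X, Y, n_axes: int = 2) -> CoinertiaResult:
    """Co-inertia analysis of two column-centered tables.

    The SVD of the cross-covariance matrix XᵀY/n yields co-inertia axes;
    each squared singular value is that axis's share of the total
    co-inertia.  The reported RV equals :func:`rv_coefficient`.
    """
    A, B = _center(X), _center(Y)
    n = A.shape[0]
    cross = A.T @ B / n
    U, s, Vt = np.linalg.svd(cross, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but cross-covariance rank is {rank}; "
            "truncating",
            stacklevel=2,
        )
        n_axes = rank
    return CoinertiaResult(
        rv=rv_coefficient(X, Y),
        axis_inertia=s**2,
        n_axes=n_axes,
        row_axes=U[:, :n_axes],
        col_axes=Vt[:n_axes].T,
    )
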