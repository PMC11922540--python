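"""Compositional transforms and diversity indices.

Relative abundances are compositional: they sum to 1, which induces
spurious negative correlation between components.  The centered log-ratio
(clr) transform, ln(x_i / g(x)) with g the row geometric mean, maps a
composition to an unconstrained space where correlation analysis is less
distorted.  A rank scaling to [0, 1] is provided as a robust alternative.
Alpha-diversity indices (richness, Chao1, Shannon, Simpson) and analytic
rarefaction round out the descriptive layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TransformedMatrix",
    "CLRTransformer",
    "Rank01Transformer",
    "clr_transform",
    "rank01_transform",
    "diversity_profile",
    "diversity_table",
    "rarefaction_curve",
]


@dataclass
class TransformedMatrix:
    """A transformed sample × feature matrix with its transform recorded."""

    values: pd.DataFrame
    transform: str  # "clr" | "rank01" | "none"
    zero_replacement: dict = field(default_factory=dict)


def _multiplicative_replace_row(row: np.ndarray) -> tuple[np.ndarray, float]:
    """Replace zeros in a closed composition, preserving ratios of the rest.

    delta = 0.5 × the smallest nonzero proportion of the row; nonzero
    entries are shrunk multiplicatively so the row still sums to 1.
    """
    zero = row == 0
    if not zero.any():
        return row, 0.0
    delta = 0.5 * row[~zero].min()
    out = row.copy()
    out[zero] = delta
    out[~zero] = row[~zero] * (1.0 - delta * zero.sum())
    return out, float(delta)


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Centered log-ratio transform of row compositions.

    clr(x)_i = ln(x_i / g(x)), g the geometric mean of the row; each output
    row sums to zero.  Rows are closed (divided by their sum) first, so the
    transform is invariant to the scale of the input row.  Zeros are
    replaced per ``zero_strategy``:

    * ``"multiplicative"`` (default): per-row delta of half the smallest
      nonzero proportion, remaining entries rescaled;
    * ``"error"``: any zero raises.

    The per-sample deltas used are recorded on the returned
    :class:`TransformedMatrix` so runs are reproducible.
    """

    def __init__(self, zero_strategy: str = "multiplicative"):
        self.zero_strategy = zero_strategy

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> TransformedMatrix:
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        values = df.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("clr input must be non-negative")
        row_sums = values.sum(axis=1)
        if (row_sums == 0).any():
            bad = list(df.index[row_sums == 0])
            raise ValueError(f"all-zero rows cannot be clr-transformed: {bad}")
        closed = values / row_sums[:, None]
        deltas: dict = {}
        if (closed == 0).any():
            if self.zero_strategy == "error":
                raise ValueError("zeros present and zero_strategy='error'")
            if self.zero_strategy != "multiplicative":
                raise ValueError(f"unknown zero_strategy {self.zero_strategy!r}")
            for k in range(closed.shape[0]):
                closed[k], delta = _multiplicative_replace_row(closed[k])
                if delta:
                    deltas[str(df.index[k])] = delta
        logs = np.log(closed)
        out = logs - logs.mean(axis=1, keepdims=True)
        return TransformedMatrix(
            pd.DataFrame(out, index=df.index, columns=df.columns),
            transform="clr",
            zero_replacement={"strategy": self.zero_strategy, "deltas": deltas},
        )


class Rank01Transformer(BaseEstimator, TransformerMixin):
    """Scale each feature to [0, 1] by its rank across samples.

    Per column, values are replaced by (rank − 1)/(n − 1) with average
    ranks for ties; a constant column maps to all 0.5.  Undefined for a
    single sample.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> TransformedMatrix:
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        n = df.shape[0]
        if n < 2:
            raise ValueError("rank scaling needs at least two samples")
        out = np.empty(df.shape, dtype=float)
        values = df.to_numpy(dtype=float)
        for j in range(df.shape[1]):
            col = values[:, j]
            if np.all(col == col[0]):
                out[:, j] = 0.5
            else:
                out[:, j] = (rankdata(col, method="average") - 1.0) / (n - 1.0)
        return TransformedMatrix(
            pd.DataFrame(out, index=df.index, columns=df.columns),
            transform="rank01",
        )


def clr_transform(rel: pd.DataFrame, zero_strategy: str = "multiplicative") -> TransformedMatrix:
    return CLRTransformer(zero_strategy=zero_strategy).fit(rel).transform(rel)


def rank01_transform(matrix: pd.DataFrame) -> TransformedMatrix:
    return Rank01Transformer().fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# diversity

def diversity_profile(values, chao1: bool | str = True) -> dict[str, float]:
    """Richness, Chao1, Shannon (nats) and Gini–Simpson for one sample.

    ``values`` may be integer read counts or real abundances.  Chao1 needs
    integer counts (singletons/doubletons are meaningless otherwise):
    with ``chao1=True`` (default) non-integer input raises; ``chao1="auto"``
    reports NaN instead; ``chao1=False`` skips it.  Shannon H = −Σ p ln p;
    Simpson reported as 1 − Σ p² (probability two random cells differ);
    Chao1 is the bias-corrected estimator S + F1(F1−1)/(2(F2+1)).
    """
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("negative values in diversity input")
    x = x[x > 0]
    richness = int(x.size)
    out: dict[str, float] = {"richness": richness}
    if richness == 0:
        out.update({"shannon": 0.0, "simpson": 0.0})
        if chao1:
            out["chao1"] = 0.0
        return out
    p = x / x.sum()
    out["shannon"] = float(-(p * np.log(p)).sum())
    out["simpson"] = float(1.0 - (p**2).sum())
    if chao1:
        if not np.allclose(x, np.round(x)):
            if chao1 == "auto":
                out["chao1"] = float("nan")
                return out
            raise ValueError("Chao1 requires integer counts")
        f1 = int((np.round(x) == 1).sum())
        f2 = int((np.round(x) == 2).sum())
        out["chao1"] = richness + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return out


def diversity_table(matrix: pd.DataFrame, chao1: bool | str = "auto") -> pd.DataFrame:
    """Per-sample diversity indices for a sample × feature matrix."""
    rows = {
        s: diversity_profile(matrix.loc[s].fillna(0).values, chao1=chao1)
        for s in matrix.index
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(counts, depths) -> pd.Series:
    """Expected richness at each rarefaction depth (analytic).

    For a sample with N reads over features with counts N_i, the expected
    number of features seen in a uniform subsample of d reads is
    E[S_d] = Σ_i [1 − C(N−N_i, d)/C(N, d)] — the hypergeometric
    expectation, computed in log space for stability.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("rarefaction requires non-negative integer counts")
    x = np.round(x[x > 0])
    total = int(x.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths > total).any():
        raise ValueError(f"rarefaction depth exceeds sample total ({total})")
    if (depths < 0).any():
        raise ValueError("negative rarefaction depth")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = []
    for d in depths:
        # P(feature i absent from subsample) = C(N - N_i, d) / C(N, d)
        keep = (total - x) >= d
        p_absent = np.zeros_like(x)
        p_absent[keep] = np.exp(
            log_choose(total - x[keep], d) - log_choose(total, d)
        )
        out.append(float(np.sum(1.0 - p_absent)))
    return pd.Series(out, index=depths, name="expected_richness")
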