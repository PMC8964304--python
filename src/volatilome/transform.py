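"""Preprocessing chain and principal component analysis.

The phenotype matrix is prepared for multivariate analysis per volatile:
median imputation of missing cells, a zero-shift by the column's minimum
non-zero value when zeros are present (so the logarithm is defined), natural
log, and a Z-score. Clamping of Z-scores to [-3, 3] is applied for
clustering/heatmap inputs but not for PCA. The applied parameters are
recorded so the transform can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TransformedMatrix", "PcaResult", "preprocess", "pca", "select_extreme_loadings"]


@dataclass
class TransformedMatrix:
    """Z-scored log matrix plus the per-volatile replay parameters
    (shift constant, log base, centering mean, scaling SD)."""

    values: pd.DataFrame
    params: pd.DataFrame
    clamped: bool = False


def preprocess(
    matrix: pd.DataFrame, impute: bool = True, clamp: bool = False
) -> TransformedMatrix:
    """Impute, zero-shift, log, Z-score (and optionally clamp) per volatile.

    Order per column: missing cells replaced by the column median of the
    observed values (if ``impute``); if any zero remains, the column's
    minimum non-zero value is added to every entry; natural log; Z-score
    using the sample SD (n-1). With ``clamp``, values outside [-3, 3] are
    collapsed to the bounds after scaling.

    Raises if a volatile is constant after the log (its Z-score is
    undefined) or has no observed values.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.astype(float).copy()
    params = pd.DataFrame(
        index=X.columns, columns=["shift", "log_base", "mean", "sd"], dtype=object
    )
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        if obs.size == 0:
            raise ValueError(f"volatile {col!r} has no observed values")
        if np.any(obs < 0):
            raise ValueError(f"volatile {col!r} has negative concentrations")
        if impute:
            v = np.where(np.isnan(v), np.median(obs), v)
        elif np.isnan(v).any():
            raise ValueError(
                f"volatile {col!r} has missing values; pass impute=True or impute upstream"
            )
        shift = 0.0
        if np.any(v == 0):
            nonzero = v[v > 0]
            if nonzero.size == 0:
                raise ValueError(f"volatile {col!r} is all zeros")
            shift = float(nonzero.min())
            v = v + shift
        v = np.log(v)
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        if sd == 0:
            raise ValueError(f"volatile {col!r} is constant after log transform")
        v = (v - mean) / sd
        X[col] = v
        params.loc[col] = [shift, "e", mean, sd]
    if clamp:
        X = X.clip(lower=-3.0, upper=3.0)
    return TransformedMatrix(values=X, params=params, clamped=clamp)


@dataclass
class PcaResult:
    """Scores (samples x components), loadings (volatiles x components) and
    the fraction of total variance carried by each component."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: TransformedMatrix | pd.DataFrame) -> PcaResult:
    """PCA of the preprocessed (centred and scaled) matrix.

    Computed by singular value decomposition of the column-centred matrix,
    equivalent to an eigendecomposition of its covariance — which, after the
    Z-score step, is the correlation structure of the raw matrix. The sign
    of each component is fixed by making its largest-magnitude loading
    positive. Retains min(n_samples - 1, n_volatiles) components; variance
    fractions sum to 1 over them.
    """
    X = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    if X.isna().to_numpy().any():
        raise ValueError("matrix has missing values; preprocess/impute first")
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 samples and 2 volatiles")
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    k = min(n - 1, p)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest |loading| positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U * s
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comps),
        explained_variance_ratio=pd.Series(ratio, index=comps, name="explained_variance_ratio"),
    )


def select_extreme_loadings(
    result: PcaResult, k: int = 15, axes: tuple[int, ...] = (1, 2)
) -> list[str]:
    """Union over ``axes`` of the k volatiles with most extreme (largest
    absolute) loadings per axis; ties broken by larger |loading| then
    lexicographic volatile id. Returns sorted volatile ids (size <= k*len(axes)).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return []
    if k > result.loadings.shape[0]:
        raise ValueError("k exceeds the number of volatiles")
    selected: set[str] = set()
    for axis in axes:
        col = f"PC{axis}"
        if col not in result.loadings.columns:
            raise ValueError(f"component {col} not present")
        load = result.loadings[col]
        order = sorted(load.index, key=lambda vid: (-abs(load[vid]), str(vid)))
        selected.update(order[:k])
    return sorted(selected)
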