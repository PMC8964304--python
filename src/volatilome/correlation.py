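"""Spearman correlation networks over volatiles and covariate traits.

Pairwise rank correlations (average-rank tie handling) with two-sided
p-values from the t approximation on n - 2 degrees of freedom, Bonferroni
classification at a family level alpha over the tested pairs, agglomerative
clustering of volatiles on the correlation distance 1 - rho with plain
bootstrap (BP) node support, and trait-versus-volatile/PC correlation scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, t as t_dist

__all__ = [
    "CorrelationResult",
    "Dendrogram",
    "spearman_matrix",
    "bonferroni_classify",
    "cluster_volatiles",
    "trait_correlations",
]


@dataclass
class CorrelationResult:
    """Volatile x volatile Spearman matrix with testing metadata.

    ``rho`` is symmetric with unit diagonal (NaN marks untestable pairs),
    ``n_obs`` the pairwise-complete sample sizes; after
    :func:`bonferroni_classify`, ``significant`` and ``sign`` ("+", "-", "")
    are populated and ``alpha`` records the family level.
    """

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    n_obs: pd.DataFrame
    m_tested: int
    alpha: float | None = None
    significant: pd.DataFrame | None = None
    sign: pd.DataFrame | None = None

    @property
    def n_significant(self) -> int:
        if self.significant is None:
            raise ValueError("run bonferroni_classify first")
        return int(np.triu(self.significant.to_numpy(), k=1).sum())

    def counts(self) -> dict[str, int]:
        """Significant pair counts partitioned by correlation sign."""
        if self.significant is None or self.sign is None:
            raise ValueError("run bonferroni_classify first")
        iu = np.triu_indices(self.rho.shape[0], k=1)
        sig = self.significant.to_numpy()[iu]
        sgn = self.sign.to_numpy()[iu]
        pos = int(np.sum(sig & (sgn == "+")))
        neg = int(np.sum(sig & (sgn == "-")))
        return {"total": pos + neg, "positive": pos, "negative": neg, "tested": self.m_tested}

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per unordered volatile pair."""
        cols = list(self.rho.columns)
        iu = np.triu_indices(len(cols), k=1)
        out = pd.DataFrame(
            {
                "volatile_a": [cols[i] for i in iu[0]],
                "volatile_b": [cols[j] for j in iu[1]],
                "rho": self.rho.to_numpy()[iu],
                "p": self.pvalues.to_numpy()[iu],
                "n": self.n_obs.to_numpy()[iu],
            }
        )
        if self.significant is not None:
            out["significant"] = self.significant.to_numpy()[iu]
            out["sign"] = self.sign.to_numpy()[iu]
        return out


def _spearman_pvalues(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t approximation with n - 2 df."""
    with np.errstate(divide="ignore", invalid="ignore"):
        df = n - 2.0
        denom = 1.0 - rho**2
        tval = rho * np.sqrt(np.where(denom > 0, df / np.where(denom > 0, denom, 1.0), np.inf))
        p = np.where(
            df > 0,
            np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * t_dist.sf(np.abs(tval), np.maximum(df, 1))),
            np.nan,
        )
    return p


def spearman_matrix(matrix, min_pairs: int = 10) -> CorrelationResult:
    """All-pairs Spearman correlation of a samples x volatiles matrix.

    Complete matrices take a fast path (rank every column once, then a
    product-moment correlation of the ranks — exactly the tie-corrected
    average-rank statistic). With missing cells each pair is computed on its
    pairwise-complete observations; pairs with fewer than ``min_pairs``
    complete rows, or with a constant column on that subset, are untestable
    (rho = NaN) and excluded from the tested-pair count.
    """
    from .transform import TransformedMatrix

    X = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    cols = list(X.columns)
    if not np.isnan(A).any():
        ranks = rankdata(A, axis=0)
        sd = ranks.std(axis=0)
        constant = sd == 0
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
        np.fill_diagonal(rho, 1.0)
        n_obs = np.full((p, p), n, dtype=float)
    else:
        rho = np.full((p, p), np.nan)
        n_obs = np.zeros((p, p))
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(n_obs, (~np.isnan(A)).sum(axis=0))
        for i in range(p):
            for j in range(i + 1, p):
                ok = ~np.isnan(A[:, i]) & ~np.isnan(A[:, j])
                n_ij = int(ok.sum())
                n_obs[i, j] = n_obs[j, i] = n_ij
                if n_ij < max(min_pairs, 3):
                    continue
                xi = rankdata(A[ok, i])
                yj = rankdata(A[ok, j])
                if xi.std() == 0 or yj.std() == 0:
                    continue
                rho[i, j] = rho[j, i] = np.corrcoef(xi, yj)[0, 1]
    pvals = _spearman_pvalues(rho, n_obs)
    np.fill_diagonal(pvals, 0.0)
    iu = np.triu_indices(p, k=1)
    m_tested = int(np.sum(~np.isnan(rho[iu]) & (n_obs[iu] >= min_pairs)))
    idx = pd.Index(cols)
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        pvalues=pd.DataFrame(pvals, index=idx, columns=idx),
        n_obs=pd.DataFrame(n_obs, index=idx, columns=idx),
        m_tested=m_tested,
    )


def bonferroni_classify(result: CorrelationResult, alpha: float = 0.05) -> CorrelationResult:
    """Flag pairs significant at the Bonferroni-corrected level alpha / m,
    where m is the number of tested pairs, and label them by the sign of
    rho. Untestable pairs are never significant."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if result.m_tested == 0:
        raise ValueError("no tested pairs to classify")
    threshold = alpha / result.m_tested
    p = result.pvalues.to_numpy()
    rho = result.rho.to_numpy()
    sig = np.where(np.isnan(p) | np.isnan(rho), False, p < threshold)
    np.fill_diagonal(sig, False)
    sign = np.where(~sig, "", np.where(rho > 0, "+", "-"))
    idx = result.rho.index
    return replace(
        result,
        alpha=alpha,
        significant=pd.DataFrame(sig.astype(bool), index=idx, columns=idx),
        sign=pd.DataFrame(sign, index=idx, columns=idx),
    )


def _node_leafsets(Z: np.ndarray, n_leaves: int) -> list[frozenset[int]]:
    """Leaf-index set of each internal node, in linkage-row order."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for row_i, (a, b) in enumerate(Z[:, :2].astype(int)):
        merged = members[a] | members[b]
        members[n_leaves + row_i] = merged
        out.append(merged)
    return out


@dataclass
class Dendrogram:
    """Volatile dendrogram on correlation distance with bootstrap support.

    ``support`` holds, per internal node (linkage-row order), the percent of
    bootstrap replicates whose tree contains an identical leaf set — plain
    bootstrap probability (BP), not the multiscale AU correction.
    """

    linkage: np.ndarray
    labels: list[str]
    support: np.ndarray
    method: str
    n_boot: int

    def node_supports(self) -> dict[frozenset[str], float]:
        sets = _node_leafsets(self.linkage, len(self.labels))
        return {
            frozenset(self.labels[i] for i in s): float(bp)
            for s, bp in zip(sets, self.support)
        }

    def to_newick(self) -> str:
        """Newick string with BP support as internal-node labels."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        by_leafset = self.node_supports()
        for node in tree.non_tips(include_self=True):
            leafset = frozenset(tip.name for tip in node.tips())
            if leafset in by_leafset:
                node.name = f"{by_leafset[leafset]:g}"
        return str(tree)


def _spearman_rho_complete(A: np.ndarray) -> np.ndarray:
    ranks = rankdata(A, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    # a column constant in a bootstrap resample carries no rank signal
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def cluster_volatiles(
    matrix,
    n_boot: int = 1000,
    method: str = "average",
    seed: int = 0,
) -> Dendrogram:
    """Hierarchical clustering of volatiles on 1 - Spearman's rho.

    The input samples x volatiles matrix must be complete (impute upstream).
    Node support is estimated by resampling samples with replacement
    ``n_boot`` times, recomputing the correlation, distance and tree, and
    counting the fraction of replicate trees containing each original
    node's exact leaf set. Deterministic given ``seed``.
    """
    from .transform import TransformedMatrix

    X = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    if X.isna().to_numpy().any():
        raise ValueError("matrix has missing values; impute before clustering")
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    labels = [str(c) for c in X.columns]

    def tree_of(data: np.ndarray) -> np.ndarray:
        rho = _spearman_rho_complete(data)
        D = np.clip(1.0 - rho, 0.0, None)
        np.fill_diagonal(D, 0.0)
        return scipy_linkage(squareform(D, checks=False), method=method)

    Z = tree_of(A)
    ref_sets = _node_leafsets(Z, p)
    hits = np.zeros(len(ref_sets))
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        boot_sets = set(_node_leafsets(tree_of(A[rows]), p))
        for k, s in enumerate(ref_sets):
            if s in boot_sets:
                hits[k] += 1
    support = hits / n_boot * 100.0 if n_boot > 0 else np.full(len(ref_sets), np.nan)
    return Dendrogram(linkage=Z, labels=labels, support=support, method=method, n_boot=n_boot)


def trait_correlations(
    traits: pd.DataFrame,
    targets: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of each covariate trait against each target
    column (volatile concentrations or PC scores), Bonferroni-corrected over
    the whole tested family.

    Categorical traits (e.g. fruit color class) are rank-transformed via
    their category codes and flagged ``categorical``; shared samples are
    matched on index. Returns a tidy frame (trait, target, rho, p, n,
    significant, categorical).
    """
    shared = traits.index.intersection(targets.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    T = traits.loc[shared]
    Y = targets.loc[shared]
    rows = []
    for trait in T.columns:
        tv = T[trait]
        categorical = not pd.api.types.is_numeric_dtype(tv)
        if categorical:
            tv = pd.Series(pd.Categorical(tv).codes, index=tv.index).replace(-1, np.nan)
        tv = tv.astype(float)
        for target in Y.columns:
            yv = Y[target].astype(float)
            ok = tv.notna() & yv.notna()
            n_ok = int(ok.sum())
            if n_ok < max(min_pairs, 3) or tv[ok].nunique() < 2 or yv[ok].nunique() < 2:
                rows.append((trait, target, np.nan, np.nan, n_ok, categorical))
                continue
            r = float(np.corrcoef(rankdata(tv[ok]), rankdata(yv[ok]))[0, 1])
            pv = float(_spearman_pvalues(np.array(r), np.array(float(n_ok))))
            rows.append((trait, target, r, pv, n_ok, categorical))
    out = pd.DataFrame(rows, columns=["trait", "target", "rho", "p", "n", "categorical"])
    m = int(out["p"].notna().sum())
    out["significant"] = out["p"] < (alpha / m if m else np.nan)
    return out
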