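"""Clone detection from SNP genotypes and clonal analysis of phenotypes.

Vegetatively propagated varieties yield genetically identical trees
("clones") whose expected kinship coefficient is 0.5; unrelated varieties
have kinship near 0. Kinship is estimated with an allele-frequency-weighted
method-of-moments estimator

    phi(i, j) = sum_m (g_im - 2 p_m)(g_jm - 2 p_m) / (2 sum_m 2 p_m (1 - p_m))

over SNPs non-missing in both samples, with p_m the sample alternate-allele
frequency; monomorphic SNPs are excluded. Clone groups are the connected
components of pairs whose kinship falls in a window around 0.5.

Clone pairs are then exploited in two ways: a randomization test asking
whether clone-mates have closer volatile profiles (mean pairwise Euclidean
distance) than random pseudo-pairs, and broad-sense heritability per
volatile as the k = 2 intraclass correlation from a one-way ANOVA with
clone group as the factor,

    H2 = (MSB - MSW) / (MSB + MSW),

which can be negative when within-group variance exceeds between-group
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "CloneSet",
    "RandomizationResult",
    "H2Results",
    "CloneDistanceTest",
    "CloneHeritability",
    "estimate_kinship",
    "identify_clones",
    "clone_randomization_test",
    "estimate_h2",
    "compare_h2_sets",
]


def estimate_kinship(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise kinship matrix from a samples x SNPs dosage frame.

    Dosages are 0/1/2 with NaN for missing calls. Sums run over the SNPs
    non-missing in both members of a pair; the estimator is symmetric and
    invariant to SNP order. Raises if no polymorphic SNP remains.
    """
    G = genotypes.to_numpy(dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    ok = ~np.isnan(G)
    n_obs = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(G, axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    poly = (n_obs > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    Gp, pp, okp = G[:, poly], p[poly], ok[:, poly]
    Z = np.where(okp, Gp - 2.0 * pp, 0.0)
    w = 2.0 * pp * (1.0 - pp)
    num = Z @ Z.T
    denom = 2.0 * (okp * w) @ okp.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, num / denom, np.nan)
    K = (K + K.T) / 2.0
    return pd.DataFrame(K, index=genotypes.index, columns=genotypes.index)


@dataclass
class CloneSet:
    """Disjoint clone groups (size >= 2) of sample ids, with a per-group flag
    recording whether all members share a variety name (when names given)."""

    groups: list[tuple[str, ...]]
    name_agreement: list[bool | None] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return sum(len(g) for g in self.groups)

    def pairs(self, decompose: bool = True) -> list[tuple[str, str]]:
        """Within-group sample pairs. Groups larger than 2 contribute all
        their member pairs when ``decompose`` is set, else only exact pairs."""
        out: list[tuple[str, str]] = []
        for g in self.groups:
            if len(g) == 2:
                out.append((g[0], g[1]))
            elif decompose:
                out.extend((g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g)))
        return out


def identify_clones(
    kinship: pd.DataFrame,
    window: tuple[float, float] = (0.4, 0.6),
    names: pd.Series | None = None,
) -> CloneSet:
    """Clone groups as connected components of pairs with kinship inside
    ``window``; groups of size >= 2 are returned, ordered by first member."""
    lo, hi = window
    K = kinship.to_numpy()
    ids = list(kinship.index)
    adj = np.triu((K >= lo) & (K <= hi), k=1)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: list[tuple[str, ...]] = []
    for c in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(labels == c)]
        if len(members) >= 2:
            groups.append(tuple(members))
    groups.sort(key=lambda g: ids.index(g[0]))
    flags: list[bool | None] = [
        None if names is None else bool(names.loc[list(g)].nunique() == 1) for g in groups
    ]
    return CloneSet(groups=groups, name_agreement=flags)


@dataclass
class RandomizationResult:
    """Outcome of the clonal randomization test."""

    observed: float
    pvalue: float
    n_replicates: int
    n_pairs: int
    null_mean: float
    null_quantiles: dict[float, float]
    seed: int

    def summary(self) -> str:
        lines = [
            "Clonal randomization test (mean pairwise Euclidean distance)",
            f"  clone pairs:        {self.n_pairs}",
            f"  observed mean dist: {self.observed:.4f}",
            f"  null mean dist:     {self.null_mean:.4f} "
            f"[2.5%: {self.null_quantiles[0.025]:.4f}, 97.5%: {self.null_quantiles[0.975]:.4f}]",
            f"  replicates:         {self.n_replicates} (seed {self.seed})",
            f"  P (null < observed): {self.pvalue:.4g}",
        ]
        return "\n".join(lines)


def clone_randomization_test(
    matrix,
    pairs: list[tuple[str, str]],
    n_replicates: int = 10_000,
    seed: int = 0,
    disjoint: bool = True,
) -> RandomizationResult:
    """Test whether clone pairs have closer volatile profiles than chance.

    The observed statistic is the mean Euclidean distance between the
    profiles of the clone pairs. Each null replicate draws n pseudo-pairs
    from all samples — by default 2n distinct samples paired off (mirroring
    the disjointness of real clone pairs; ``disjoint=False`` instead draws
    each pair independently) — and records their mean distance. The P-value
    is the proportion of replicates whose null mean is strictly less than
    the observed mean.
    """
    from .transform import TransformedMatrix

    X = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    if X.isna().to_numpy().any():
        raise ValueError("matrix has missing values; preprocess first")
    if len(pairs) < 1:
        raise ValueError("need at least one clone pair")
    n_pairs, n_samples = len(pairs), X.shape[0]
    if disjoint and 2 * n_pairs > n_samples:
        raise ValueError("2 * n_pairs exceeds the number of samples")
    index = {s: i for i, s in enumerate(X.index)}
    D = squareform(pdist(X.to_numpy(dtype=float)))
    pair_idx = np.array([(index[a], index[b]) for a, b in pairs])
    observed = float(D[pair_idx[:, 0], pair_idx[:, 1]].mean())

    rng = np.random.default_rng(seed)
    if disjoint:
        keys = rng.random((n_replicates, n_samples))
        idx = np.argsort(keys, axis=1)[:, : 2 * n_pairs]
        a, b = idx[:, 0::2], idx[:, 1::2]
    else:
        a = rng.integers(0, n_samples, size=(n_replicates, n_pairs))
        off = rng.integers(1, n_samples, size=(n_replicates, n_pairs))
        b = (a + off) % n_samples
    null_means = D[a, b].mean(axis=1)
    pvalue = float((null_means < observed).sum() / n_replicates)
    qs = {q: float(np.quantile(null_means, q)) for q in (0.025, 0.5, 0.975)}
    return RandomizationResult(
        observed=observed,
        pvalue=pvalue,
        n_replicates=n_replicates,
        n_pairs=n_pairs,
        null_mean=float(null_means.mean()),
        null_quantiles=qs,
        seed=seed,
    )


def estimate_h2(matrix, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Broad-sense heritability per volatile from clone pairs.

    One-way ANOVA with clone group as factor and 2 replicates per group:
    MSB the between-group and MSW the within-group mean square, and
    H2 = (MSB - MSW)/(MSB + MSW). For each volatile only pairs with both
    members observed enter; fewer than 2 usable pairs, or zero total
    variance, yields a flagged NaN. Negative estimates are reported as
    computed. Returns a frame indexed by volatile with columns msb, msw,
    n_groups, h2, note.
    """
    from .transform import TransformedMatrix

    X = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    if len(pairs) < 2:
        raise ValueError("need at least 2 clone pairs")
    rows = []
    for vol in X.columns:
        col = X[vol]
        vals = np.array(
            [[col.get(a, np.nan), col.get(b, np.nan)] for a, b in pairs], dtype=float
        )
        usable = vals[~np.isnan(vals).any(axis=1)]
        g = usable.shape[0]
        if g < 2:
            rows.append((vol, np.nan, np.nan, g, np.nan, "insufficient_pairs"))
            continue
        group_means = usable.mean(axis=1)
        grand = usable.mean()
        msb = 2.0 * np.sum((group_means - grand) ** 2) / (g - 1)
        msw = np.sum((usable - group_means[:, None]) ** 2) / g
        if msb + msw == 0:
            rows.append((vol, msb, msw, g, np.nan, "zero_variance"))
            continue
        h2 = (msb - msw) / (msb + msw)
        rows.append((vol, msb, msw, g, h2, ""))
    out = pd.DataFrame(rows, columns=["volatile", "msb", "msw", "n_groups", "h2", "note"])
    return out.set_index("volatile")


def compare_h2_sets(
    h2_a: pd.DataFrame, h2_b: pd.DataFrame, outlier_threshold: float = 0.5
) -> dict:
    """Concordance between two heritability tables (e.g. the same-name and
    the all-clones pair sets): Spearman correlation over shared volatiles
    plus the volatiles whose estimates differ by more than the cutoff."""
    shared = h2_a.index.intersection(h2_b.index)
    a = h2_a.loc[shared, "h2"]
    b = h2_b.loc[shared, "h2"]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared volatiles with estimates")
    rho = float(spearmanr(a[ok], b[ok]).statistic)
    diff = (a - b).abs()
    outliers = sorted(diff.index[diff > outlier_threshold])
    return {"rho": rho, "n_shared": int(ok.sum()), "outliers": outliers}


class CloneDistanceTest:
    """Model-style wrapper: clonal randomization test on a profile matrix.

    ``CloneDistanceTest(matrix, pairs).fit()`` returns a
    :class:`RandomizationResult` with a ``summary()`` table.
    """

    def __init__(self, matrix, pairs: list[tuple[str, str]]):
        self.matrix = matrix
        self.pairs = list(pairs)

    def fit(
        self, n_replicates: int = 10_000, seed: int = 0, disjoint: bool = True
    ) -> RandomizationResult:
        return clone_randomization_test(
            self.matrix, self.pairs, n_replicates=n_replicates, seed=seed, disjoint=disjoint
        )


@dataclass
class H2Results:
    """Per-volatile broad-sense heritability estimates."""

    table: pd.DataFrame

    def summary(self) -> str:
        est = self.table["h2"].dropna()
        lines = [
            "Broad-sense heritability from clone pairs (k = 2 intraclass correlation)",
            f"  volatiles estimated: {len(est)} / {len(self.table)}",
        ]
        if len(est):
            lines += [
                f"  negative estimates:  {(est < 0).sum()}",
                f"  positive range:      "
                f"[{est[est > 0].min():.3f}, {est.max():.3f}]" if (est > 0).any() else "",
                f"  median H2:           {est.median():.3f}",
            ]
        return "\n".join(line for line in lines if line)


class CloneHeritability:
    """Model-style wrapper: per-volatile H2 from clone pairs.

    ``CloneHeritability(matrix, pairs).fit()`` returns :class:`H2Results`.
    """

    def __init__(self, matrix, pairs: list[tuple[str, str]]):
        self.matrix = matrix
        self.pairs = list(pairs)

    def fit(self) -> H2Results:
        return H2Results(table=estimate_h2(self.matrix, self.pairs))
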