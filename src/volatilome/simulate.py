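"""Synthetic panels with planted genetic structure.

Emulates a fruit-volatile survey of vegetatively propagated palms: a set of
varieties (distinct genotypes) sampled across two farms, some varieties
present as clone pairs or triples, phenotyped by GC-MS in three technical
replicates and genotyped at biallelic SNPs.

The genetic model is additive on the log-concentration scale: for sample
``s`` of variety ``g`` and volatile ``v``,

    log c_{s,v} = baseline_v + G_{g,v} + farm_s + E_{s,v}

with ``G ~ N(0, sigma2_G_v)`` shared by clone-mates, ``E ~ N(0, sigma2_E_v)``
independent per sample, and an optional farm effect. Broad-sense
heritability is planted exactly as ``H2_v = sigma2_G_v / (sigma2_G_v +
sigma2_E_v)``. Concentrations are ``exp(log c)``, hence lognormal and
strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PanelDesign",
    "TruePanel",
    "default_design",
    "simulate_panel",
    "simulate_replicates",
    "simulate_genotypes",
    "simulate_covariates",
]

#: Internal-standard peak area emitted for every simulated run.
DEFAULT_AREA_ISTD = 1.0e6
#: Internal-standard quantity (ug) and powder quantity (g) per run.
DEFAULT_MASS_ISTD = 5.0
DEFAULT_MASS_POWDER = 0.5


@dataclass(frozen=True)
class PanelDesign:
    """Design of a synthetic panel.

    Parameters
    ----------
    n_varieties
        Number of distinct genotypes. Each clone group occupies one variety;
        total samples = ``n_varieties + sum(size - 1 for size in clone_groups)``.
    n_volatiles
        Number of volatile compounds.
    clone_groups
        Sizes of the clone groups (e.g. sixteen pairs and one triple).
    baseline_log_mean, var_genetic, var_env
        Per-volatile baseline log-concentration and log-scale genotypic /
        environmental variances. ``H2 = var_genetic / (var_genetic + var_env)``
        holds exactly for the planted values.
    farm_effect_sd
        Log-scale SD of the additive farm effect (two farms). The study design
        spans two farms but fits no farm model, so the default is 0.
    seed
        Seed for the panel-level random stream.
    """

    n_varieties: int
    n_volatiles: int
    clone_groups: tuple[int, ...]
    baseline_log_mean: np.ndarray
    var_genetic: np.ndarray
    var_env: np.ndarray
    farm_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_log_mean", "var_genetic", "var_env"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_volatiles,):
                raise ValueError(f"{name} must have shape ({self.n_volatiles},)")
            object.__setattr__(self, name, arr)
        if np.any(self.var_genetic < 0) or np.any(self.var_env < 0):
            raise ValueError("variances must be non-negative")
        if self.farm_effect_sd < 0:
            raise ValueError("farm_effect_sd must be non-negative")
        if any(size < 2 for size in self.clone_groups):
            raise ValueError("clone groups must have size >= 2")
        if len(self.clone_groups) > self.n_varieties:
            raise ValueError("more clone groups than varieties")
        if self.n_samples < sum(self.clone_groups):
            raise ValueError("clone-group sizes exceed total samples")

    @property
    def n_samples(self) -> int:
        return self.n_varieties + sum(size - 1 for size in self.clone_groups)

    @property
    def h2(self) -> np.ndarray:
        """Planted per-volatile broad-sense heritability."""
        total = self.var_genetic + self.var_env
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, self.var_genetic / total, 0.0)
        return out


def default_design(
    seed: int = 0,
    n_varieties: int = 130,
    n_volatiles: int = 80,
    clone_groups: tuple[int, ...] = (2,) * 16 + (3,),
    total_log_var: float = 0.64,
    farm_effect_sd: float = 0.0,
) -> PanelDesign:
    """Design mirroring the default survey: 148 samples from 130 genotypes
    (16 clone pairs + 1 triple = 35 clonal samples), 80 volatiles.

    Per-volatile baselines are drawn Uniform(log 1, log 400) on the
    log(ug/100 g) scale and heritabilities Uniform(0.05, 0.85); the total
    log-scale variance defaults to 0.64 (SD 0.8, a typical sample-to-sample
    spread for fruit volatiles).
    """
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(np.log(1.0), np.log(400.0), size=n_volatiles)
    h2 = rng.uniform(0.05, 0.85, size=n_volatiles)
    return PanelDesign(
        n_varieties=n_varieties,
        n_volatiles=n_volatiles,
        clone_groups=tuple(clone_groups),
        baseline_log_mean=baseline,
        var_genetic=h2 * total_log_var,
        var_env=(1.0 - h2) * total_log_var,
        farm_effect_sd=farm_effect_sd,
        seed=seed,
    )


@dataclass
class TruePanel:
    """Ground truth for one simulated panel.

    Attributes
    ----------
    expected
        samples x volatiles expected concentrations (linear scale, > 0).
    variety, clone_group, farm
        Per-sample labels; ``clone_group`` is None for singleton varieties.
    genetic_value
        samples x volatiles log-scale genotypic values (clone-mates identical).
    """

    expected: pd.DataFrame
    variety: pd.Series
    clone_group: pd.Series
    farm: pd.Series
    genetic_value: pd.DataFrame
    design: PanelDesign = field(repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expected.index)

    @property
    def volatile_ids(self) -> list[str]:
        return list(self.expected.columns)

    def clone_groups(self) -> dict[str, list[str]]:
        """Mapping clone-group label -> member sample ids."""
        mask = self.clone_group.notna()
        out: dict[str, list[str]] = {}
        for sample, group in self.clone_group[mask].items():
            out.setdefault(group, []).append(sample)
        return out


def simulate_panel(design: PanelDesign) -> TruePanel:
    """Draw latent genotypic and environmental effects for one panel.

    Clone-mates share the genotypic value for every volatile and are spread
    across the two farms (alternating assignment), mimicking replicate trees
    of elite varieties grown on both farms. Deterministic given
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n_var, n_vol = design.n_varieties, design.n_volatiles
    variety_ids = [f"V{i + 1:03d}" for i in range(n_var)]
    # First len(clone_groups) varieties are the clonal ones.
    sample_variety: list[str] = []
    sample_group: list[str | None] = []
    for g, size in enumerate(design.clone_groups):
        sample_variety += [variety_ids[g]] * size
        sample_group += [f"CG{g + 1:02d}"] * size
    for v in range(len(design.clone_groups), n_var):
        sample_variety.append(variety_ids[v])
        sample_group.append(None)
    n_samples = len(sample_variety)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    volatile_ids = [f"vol{j + 1:02d}" for j in range(n_vol)]

    G_variety = rng.normal(0.0, np.sqrt(design.var_genetic), size=(n_var, n_vol))
    E = rng.normal(0.0, np.sqrt(design.var_env), size=(n_samples, n_vol))
    farm_effects = rng.normal(0.0, design.farm_effect_sd, size=2)

    var_index = {v: i for i, v in enumerate(variety_ids)}
    G = G_variety[[var_index[v] for v in sample_variety]]
    # Alternate farms within each clone group so clone-mates sit on
    # different farms; singletons alternate panel-wide.
    farms = []
    group_counts: dict[str, int] = {}
    for i, grp in enumerate(sample_group):
        if grp is None:
            farms.append("farm_A" if i % 2 == 0 else "farm_B")
        else:
            k = group_counts.get(grp, 0)
            group_counts[grp] = k + 1
            farms.append("farm_A" if k % 2 == 0 else "farm_B")
    farm_term = np.where(np.asarray(farms) == "farm_A", farm_effects[0], farm_effects[1])

    log_conc = design.baseline_log_mean[None, :] + G + farm_term[:, None] + E
    expected = pd.DataFrame(np.exp(log_conc), index=sample_ids, columns=volatile_ids)
    return TruePanel(
        expected=expected,
        variety=pd.Series(sample_variety, index=sample_ids, name="variety"),
        clone_group=pd.Series(sample_group, index=sample_ids, name="clone_group", dtype=object),
        farm=pd.Series(farms, index=sample_ids, name="farm"),
        genetic_value=pd.DataFrame(G, index=sample_ids, columns=volatile_ids),
        design=design,
    )


def simulate_replicates(
    panel: TruePanel,
    cv_tech: float = 0.15,
    outlier_rate: float = 0.02,
    outlier_factor_range: tuple[float, float] = (3.0, 6.0),
    missing_rate: float = 0.03,
    seed: int = 0,
    n_runs: int = 3,
) -> pd.DataFrame:
    """Emit a tidy technical-replicate peak-area table for a panel.

    Each run's analyte peak area is the expected concentration times
    multiplicative lognormal noise with coefficient of variation ``cv_tech``
    (mean 1, so replicate means are unbiased on the linear scale). With
    probability ``outlier_rate`` an entire run of one sample is scaled by a
    factor drawn Uniform over ``outlier_factor_range`` — the "one bad run"
    failure mode the replicate QC is designed to catch. With probability
    ``missing_rate`` a (sample, volatile) is undetected and all of its runs
    are missing; this puts the missing fraction of both the replicate table
    and the assembled matrix at ``missing_rate``.

    Returns a DataFrame with columns sample, volatile, run, area, area_istd,
    mass_istd, mass_powder; ``area`` is NaN for missing cells. Peak areas are
    scaled so the semi-quantification formula recovers the concentration.
    """
    for name, rate in (("cv_tech", cv_tech), ("outlier_rate", outlier_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    conc = panel.expected.to_numpy()
    if conc.size == 0:
        raise ValueError("empty panel")
    n_samples, n_vol = conc.shape
    rng = np.random.default_rng(seed)

    if cv_tech > 0:
        sigma2 = np.log1p(cv_tech**2)
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=(n_samples, n_vol, n_runs))
    else:
        noise = np.ones((n_samples, n_vol, n_runs))
    # with probability outlier_rate a sample has one aberrant run: that
    # whole run's values are scaled by a factor from outlier_factor_range
    run_factor = np.ones((n_samples, n_runs))
    has_outlier = rng.random(n_samples) < outlier_rate
    which_run = rng.integers(0, n_runs, size=n_samples)
    lo, hi = outlier_factor_range
    factors = rng.uniform(lo, hi, size=n_samples)
    run_factor[np.flatnonzero(has_outlier), which_run[has_outlier]] = factors[has_outlier]
    missing = rng.random((n_samples, n_vol)) < missing_rate

    values = conc[:, :, None] * noise * run_factor[:, None, :]
    # area scaling inverts m = (A/A_EI)(m_EI/m_p)*100
    area = values * DEFAULT_AREA_ISTD * DEFAULT_MASS_POWDER / (DEFAULT_MASS_ISTD * 100.0)
    area[missing] = np.nan

    samples = np.repeat(panel.sample_ids, n_vol * n_runs)
    volatiles = np.tile(np.repeat(panel.volatile_ids, n_runs), n_samples)
    runs = np.tile(np.arange(1, n_runs + 1), n_samples * n_vol)
    return pd.DataFrame(
        {
            "sample": samples,
            "volatile": volatiles,
            "run": runs,
            "area": area.reshape(-1),
            "area_istd": DEFAULT_AREA_ISTD,
            "mass_istd": DEFAULT_MASS_ISTD,
            "mass_powder": DEFAULT_MASS_POWDER,
        }
    )


def simulate_genotypes(
    panel: TruePanel,
    n_snps: int = 5000,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    genotyping_error: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Biallelic SNP dosages (samples x SNPs) with clone structure.

    SNP alternate-allele frequencies are Uniform(maf_low, maf_high). Each
    variety receives an independent Hardy-Weinberg genotype vector; samples
    inherit their variety's vector, so clone-mates are identical up to the
    genotyping error, under which each call is independently redrawn from
    Hardy-Weinberg with probability ``genotyping_error``. Frequencies are
    stored in ``df.attrs["alt_freq"]``.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not 0.0 <= genotyping_error <= 1.0:
        raise ValueError("genotyping_error must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    freq = rng.uniform(maf_low, maf_high, size=n_snps)
    varieties = sorted(set(panel.variety))
    founders = rng.binomial(2, freq, size=(len(varieties), n_snps))
    var_index = {v: i for i, v in enumerate(varieties)}
    dosage = founders[[var_index[v] for v in panel.variety]].astype(float)
    if genotyping_error > 0:
        flip = rng.random(dosage.shape) < genotyping_error
        redrawn = rng.binomial(2, np.broadcast_to(freq, dosage.shape)[flip])
        dosage[flip] = redrawn
    snp_ids = [f"snp{j + 1:05d}" for j in range(n_snps)]
    out = pd.DataFrame(dosage, index=panel.sample_ids, columns=snp_ids)
    out.attrs["alt_freq"] = freq
    return out


def simulate_covariates(
    panel: TruePanel,
    loadings: dict[str, float] | None = None,
    noise_sd: float | dict[str, float] = 0.5,
    seed: int = 0,
    factor: str | None = None,
) -> pd.DataFrame:
    """Covariate traits (moisture, sugars, color class) tied to a latent
    volatile factor.

    The factor is the z-scored mean log expected concentration across
    volatiles (a global metabolic level), or a single volatile's z-scored
    log concentration when ``factor`` names one. Each quantitative trait is
    ``weight * factor + Normal(0, noise_sd)`` mapped onto a realistic scale;
    sucrose is constructed as total sugars minus glucose minus fructose, so
    its correlation with the invert sugars is negative by construction.
    The color class is an independent 3-level categorical.
    """
    if factor is None:
        latent = np.log(panel.expected.to_numpy()).mean(axis=1)
    elif factor in panel.expected.columns:
        latent = np.log(panel.expected[factor].to_numpy())
    else:
        raise KeyError(f"unknown latent factor reference: {factor!r}")
    sd = latent.std(ddof=1)
    latent = (latent - latent.mean()) / sd if sd > 0 else latent - latent.mean()

    if loadings is None:
        loadings = {"moisture": -0.5, "glucose": 0.4, "fructose": 0.35}
    if not all(np.isfinite(list(loadings.values()))):
        raise ValueError("loadings must be finite")
    rng = np.random.default_rng(seed)
    n = len(latent)

    def trait_noise(name: str) -> np.ndarray:
        s = noise_sd[name] if isinstance(noise_sd, dict) else noise_sd
        return rng.normal(0.0, s, size=n) if s > 0 else np.zeros(n)

    scores = {name: w * latent + trait_noise(name) for name, w in loadings.items()}
    out = pd.DataFrame(index=pd.Index(panel.sample_ids, name="sample"))
    # map latent scores to plausible composition scales, floored at zero
    out["moisture"] = np.clip(20.0 + 5.0 * scores.pop("moisture", np.zeros(n)), 0.0, 100.0)
    glucose = np.clip(32.0 + 6.0 * scores.pop("glucose", np.zeros(n)), 0.0, None)
    fructose = np.clip(30.0 + 6.0 * scores.pop("fructose", np.zeros(n)), 0.0, None)
    total = np.clip(70.0 + rng.normal(0.0, 2.0, size=n), 0.0, None)
    out["glucose"] = glucose
    out["fructose"] = fructose
    out["sucrose"] = np.clip(total - glucose - fructose, 0.0, None)
    out["total_sugars"] = out[["glucose", "fructose", "sucrose"]].sum(axis=1)
    for name, vals in scores.items():  # any extra user-specified traits, raw scale
        out[name] = vals
    out["color_class"] = rng.choice(["yellow", "red", "brown"], size=n)
    return out
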