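"""Run configuration: one flat record of every pipeline tunable.

Defaults are the analysis' published operating points: CV threshold 50%,
deviation bounds 35%/55%, clone-kinship window around 0.5, 10,000
randomization replicates, 1,000 bootstrap replicates, family alpha 0.05,
15 extreme loadings on each of PC1/PC2. The config round-trips losslessly
through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "volatilome_out"

    # inputs; when replicates_path is None the synthetic generator runs
    replicates_path: str | None = None
    vcf_path: str | None = None
    traits_path: str | None = None

    # synthetic panel
    n_varieties: int = 130
    n_volatiles: int = 80
    clone_groups: list[int] = field(default_factory=lambda: [2] * 16 + [3])
    total_log_var: float = 0.64
    farm_effect_sd: float = 0.0
    cv_tech: float = 0.15
    outlier_rate: float = 0.02
    outlier_factor_low: float = 3.0
    outlier_factor_high: float = 6.0
    missing_rate: float = 0.03
    n_snps: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.5
    genotyping_error: float = 0.0

    # QC (documentation of the fixed thresholds; see quantify module)
    cv_threshold: float = 50.0
    deviation_low: float = 35.0
    deviation_high: float = 55.0

    # transforms / PCA
    clamp_for_clustering: bool = True
    n_extreme: int = 15
    axes: list[int] = field(default_factory=lambda: [1, 2])

    # clonal
    clone_window_low: float = 0.4
    clone_window_high: float = 0.6
    n_permutations: int = 10_000
    disjoint_pairs: bool = True

    # correlation
    alpha: float = 0.05
    min_pairs: int = 10
    n_bootstrap: int = 1000
    linkage: str = "average"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{Path(path)}: unknown config keys {sorted(unknown)}")
        return cls(**data)
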