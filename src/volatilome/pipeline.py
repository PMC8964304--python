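"""End-to-end pipeline: simulate (optional) -> quantify -> transform/PCA ->
clones -> clone test -> heritability -> correlation network -> clustering.

Every stage writes plain-text artifacts (TSV/Newick/JSON-like log) into the
output directory; all randomness is seeded from the config so two runs with
identical configs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clonal, correlation, io, quantify, simulate, transform
from .config import RunConfig

logger = logging.getLogger("volatilome")

__all__ = ["run_pipeline"]

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the artifact directory.

    With no ``replicates_path`` the synthetic generator produces the inputs
    (replicate table, VCF, traits) first. Any stage failure propagates with
    the stage named.
    """
    for attr in ("replicates_path", "vcf_path", "traits_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr} does not exist: {p}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"volatilome {__version__}", f"seed {config.seed}"]
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    stage = "setup"
    try:
        panel = None
        if config.replicates_path is None:
            stage = "simulate"
            design = simulate.default_design(
                seed=int(seeds[0]),
                n_varieties=config.n_varieties,
                n_volatiles=config.n_volatiles,
                clone_groups=tuple(config.clone_groups),
                total_log_var=config.total_log_var,
                farm_effect_sd=config.farm_effect_sd,
            )
            panel = simulate.simulate_panel(design)
            replicates = simulate.simulate_replicates(
                panel,
                cv_tech=config.cv_tech,
                outlier_rate=config.outlier_rate,
                outlier_factor_range=(config.outlier_factor_low, config.outlier_factor_high),
                missing_rate=config.missing_rate,
                seed=int(seeds[1]),
            )
            genotypes = simulate.simulate_genotypes(
                panel,
                n_snps=config.n_snps,
                maf_low=config.maf_low,
                maf_high=config.maf_high,
                genotyping_error=config.genotyping_error,
                seed=int(seeds[2]),
            )
            traits = simulate.simulate_covariates(panel, seed=int(seeds[3]))
            io.write_replicates(replicates, outdir / "replicates.tsv")
            io.write_genotypes(genotypes, outdir / "genotypes.vcf")
            traits.to_csv(outdir / "traits.tsv", sep="\t", float_format=_FLOAT_FMT)
            log_lines.append(
                f"simulate: n_samples={design.n_samples} n_volatiles={design.n_volatiles} "
                f"clone_groups={list(design.clone_groups)} seeds={[int(s) for s in seeds[:4]]}"
            )
        else:
            replicates = io.read_replicates(config.replicates_path)
            genotypes = io.read_genotypes(config.vcf_path) if config.vcf_path else None
            traits = (
                pd.read_csv(config.traits_path, sep="\t", index_col=0)
                if config.traits_path
                else None
            )

        stage = "quantify"
        conc, decisions = quantify.apply_qc(replicates)
        matrix, missing_fraction = quantify.assemble_matrix(replicates, decisions)
        _write(quantify.decisions_frame(decisions), outdir / "qc_decisions.tsv", index=False)
        io.write_matrix(matrix, outdir / "volatile_matrix.tsv")
        log_lines.append(
            f"quantify: {matrix.shape[0]}x{matrix.shape[1]} matrix, "
            f"missing fraction {missing_fraction:.4%}"
        )

        stage = "preprocess"
        tm_pca = transform.preprocess(matrix, impute=True, clamp=False)
        tm_clust = transform.preprocess(
            matrix, impute=True, clamp=config.clamp_for_clustering
        )
        _write(tm_pca.params, outdir / "transform_params.tsv")

        stage = "pca"
        pca_res = transform.pca(tm_pca)
        _write(pca_res.scores, outdir / "pca_scores.tsv")
        _write(pca_res.loadings, outdir / "pca_loadings.tsv")
        _write(pca_res.explained_variance_ratio.to_frame(), outdir / "pca_variance.tsv")
        extreme = transform.select_extreme_loadings(
            pca_res,
            k=min(config.n_extreme, pca_res.loadings.shape[0]),
            axes=tuple(config.axes),
        )
        (outdir / "extreme_loading_volatiles.txt").write_text("\n".join(extreme) + "\n")
        evr = pca_res.explained_variance_ratio
        log_lines.append(
            f"pca: PC1 {evr.iloc[0]:.1%}, PC2 {evr.iloc[1]:.1%}; "
            f"{len(extreme)} extreme-loading volatiles"
        )

        stage = "clones"
        clones = None
        if genotypes is not None:
            kinship = clonal.estimate_kinship(genotypes)
            _write(kinship, outdir / "kinship.tsv")
            clones = clonal.identify_clones(
                kinship, window=(config.clone_window_low, config.clone_window_high)
            )
            rows = [
                {"group": f"CG{g + 1:02d}", "sample": s}
                for g, grp in enumerate(clones.groups)
                for s in grp
            ]
            _write(pd.DataFrame(rows, columns=["group", "sample"]),
                   outdir / "clone_groups.tsv", index=False)
            log_lines.append(
                f"clones: {len(clones.groups)} groups, {clones.n_members} member samples"
            )

        if clones is not None and clones.pairs():
            stage = "clone-test"
            rand = clonal.CloneDistanceTest(tm_clust, clones.pairs()).fit(
                n_replicates=config.n_permutations,
                seed=int(seeds[4]),
                disjoint=config.disjoint_pairs,
            )
            (outdir / "clone_test.json").write_text(
                json.dumps(
                    {
                        "observed": rand.observed,
                        "pvalue": rand.pvalue,
                        "n_replicates": rand.n_replicates,
                        "n_pairs": rand.n_pairs,
                        "null_mean": rand.null_mean,
                        "seed": rand.seed,
                    },
                    indent=1,
                )
                + "\n"
            )
            log_lines.append(f"clone-test: P = {rand.pvalue:.4g} ({rand.n_replicates} replicates)")

            stage = "h2"
            if len(clones.pairs()) >= 2:
                h2 = clonal.CloneHeritability(matrix, clones.pairs()).fit()
                _write(h2.table, outdir / "heritability.tsv")
                est = h2.table["h2"].dropna()
                log_lines.append(
                    f"h2: {len(est)} volatiles, {(est < 0).sum()} negative estimates"
                )

        stage = "corr"
        corr = correlation.bonferroni_classify(
            correlation.spearman_matrix(matrix, min_pairs=config.min_pairs),
            alpha=config.alpha,
        )
        _write(corr.to_long(), outdir / "correlations.tsv", index=False)
        counts = corr.counts()
        log_lines.append(
            f"corr: {counts['tested']} pairs tested, {counts['total']} significant "
            f"({counts['positive']} positive, {counts['negative']} negative)"
        )

        stage = "cluster"
        dendro = correlation.cluster_volatiles(
            tm_clust,
            n_boot=config.n_bootstrap,
            method=config.linkage,
            seed=int(seeds[5]),
        )
        (outdir / "volatile_dendrogram.nwk").write_text(dendro.to_newick())

        stage = "traits"
        if traits is not None:
            tc = correlation.trait_correlations(
                traits, pca_res.scores[["PC1", "PC2"]], alpha=config.alpha
            )
            _write(tc, outdir / "trait_pc_correlations.tsv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(outdir / "config.yaml")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return outdir
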