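"""End-to-end runs: CSS scan, quantitative GWAS, regional allelic test.

Each run takes a :class:`RunConfig`, writes TSV/BED tables, a Manhattan
plot and a JSON manifest (config echo + package versions + seed) into the
output directory, and returns the main tables for programmatic use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import bonferroni_thresholds, effective_tests_li_ji, gwas_linear, pca, allelic_association
from .constituent import compute_constituents
from .css import compute_css
from .panel import GenotypePanel, apply_qc, write_results_table
from .regions import call_regions, read_genes, regions_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters shared by the pipeline commands."""

    selected: str = "selected"
    reference: str = "reference"
    snp_call_min: float = 0.95
    ind_call_min: float = 0.95
    maf_min: float = 0.01
    half_width_bp: int = 500_000
    top_fraction: float = 0.01
    sig_fraction: float = 0.001
    min_top1: int = 5
    window_bp: int = 1_000_000
    mode: str = "strict"  # strict | relaxed
    dsaf_orientation: str = "ref_minor"
    truncate_at: float = 0.05
    gap_cap_bp: int = 200_000
    flank_bp: int = 500_000
    gwas_alpha: float = 0.05
    region: tuple | None = None  # (chrom, start_bp, end_bp) for region-assoc
    assoc_maf_min: float = 0.05
    assoc_call_min: float = 0.95
    seed: int = 0
    outdir: str = "cssig_out"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed"):
            raise ValueError("mode must be 'strict' or 'relaxed'")


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "cssig_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_css_scan(
    panel: GenotypePanel, config: RunConfig, genes: pd.DataFrame | None = None
):
    """QC -> constituents -> CSS -> smoothing -> region calling -> outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label in (config.selected, config.reference):
        if label not in set(panel.individuals["cohort"].dropna()):
            raise ValueError(f"cohort {label!r} absent from panel")
    qc_panel, report = apply_qc(
        panel, snp_call_min=config.snp_call_min,
        ind_call_min=config.ind_call_min, maf_min=config.maf_min,
    )
    logger.info("QC kept %d/%d SNPs", report.n_snps_out, report.n_snps_in)
    scores = compute_constituents(
        qc_panel, config.selected, config.reference,
        dsaf_orientation=config.dsaf_orientation,
        truncate_at=config.truncate_at, gap_cap_bp=config.gap_cap_bp,
    )
    stats_matrix, valid_matrix = scores.as_matrix()
    result = compute_css(
        stats_matrix, valid_matrix,
        qc_panel.snps["pos_bp"].to_numpy(), qc_panel.snps["chrom"].to_numpy(),
        half_width_bp=config.half_width_bp,
    )
    table = pd.DataFrame(
        {
            "snp_id": qc_panel.snps["id"],
            "chrom": qc_panel.snps["chrom"],
            "pos_bp": qc_panel.snps["pos_bp"],
            "fst": scores.fst,
            "dsaf": scores.dsaf,
            "xpehh": scores.xpehh_std,
            "css": result.css,
            "css_smooth": result.css_smooth,
        }
    )
    write_results_table(table, outdir / "css_snps.tsv", "tsv")
    regions = call_regions(
        qc_panel.snps, result.css_smooth, result.valid,
        top_fraction=config.top_fraction, sig_fraction=config.sig_fraction,
        window_bp=config.window_bp, min_top1=config.min_top1,
        mode=config.mode, genes=genes, flank_bp=config.flank_bp,
    )
    rframe = regions_to_frame(regions)
    if len(rframe):
        write_results_table(rframe, outdir / "regions.tsv", "tsv")
        write_results_table(rframe, outdir / "regions.bed", "bed")
    else:
        logger.warning("no regions satisfied the %s-mode rule", config.mode)
    if config.make_plots:
        from .plotting import manhattan

        manhattan(table, ["css", "css_smooth"], outdir / "css_manhattan.png")
    _write_manifest(outdir, config, {
        "n_snps_qc": report.n_snps_out, "n_regions": len(rframe),
    })
    return table, regions, report


def run_gwas(
    panel: GenotypePanel,
    config: RunConfig,
    phenotype: np.ndarray | None = None,
    speed_indices: pd.DataFrame | None = None,
    covariates: np.ndarray | None = None,
):
    """(PCA phenotype ->) per-SNP OLS -> Li-Ji Me -> Bonferroni thresholds."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pca_result = None
    if phenotype is None:
        if speed_indices is None:
            raise ValueError("supply either a phenotype vector or raw speed indices")
        index_cols = [c for c in speed_indices.columns if c not in ("id", "sex")]
        pca_result = pca(speed_indices[index_cols].to_numpy(), standardize=True)
        phenotype = pca_result.scores[:, 0]
        if covariates is None and "sex" in speed_indices.columns:
            covariates = (speed_indices["sex"].to_numpy() == "M").astype(float)
    assoc = gwas_linear(panel, phenotype, covariates)
    me = effective_tests_li_ji(panel)
    thresholds = bonferroni_thresholds(me, alpha=config.gwas_alpha)
    assoc["p_adjusted"] = np.minimum(assoc["p_unadj"] * thresholds.me, 1.0)
    write_results_table(assoc, outdir / "gwas.tsv", "tsv")
    if config.make_plots:
        from .plotting import manhattan

        plot_df = assoc.assign(neglogp=-np.log10(assoc["p_unadj"]))
        manhattan(
            plot_df, ["neglogp"], outdir / "gwas_manhattan.png",
            hlines={
                "genome-wide": -np.log10(thresholds.genomewide_p),
                "suggestive": -np.log10(thresholds.suggestive_p),
            },
        )
    _write_manifest(outdir, config, {
        "me": thresholds.me,
        "genomewide_p": thresholds.genomewide_p,
        "suggestive_p": thresholds.suggestive_p,
        "pc1_variance_fraction": (
            float(pca_result.variance_fractions[0]) if pca_result else None
        ),
    })
    return assoc, thresholds, pca_result


def run_region_assoc(panel: GenotypePanel, config: RunConfig, case_label: str, control_label: str):
    """Regional case-control allelic scan with region-wide Bonferroni."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        assoc = allelic_association(
            panel, case_label, control_label, region=config.region,
            maf_min=config.assoc_maf_min, call_min=config.assoc_call_min,
        )
    except Exception as err:  # 0 surviving SNPs is a warning, not a failure
        logger.warning("regional association produced no testable SNPs: %s", err)
        assoc = pd.DataFrame(
            columns=["snp_id", "chrom", "pos_bp", "odds_ratio", "statistic",
                     "p_unadj", "p_adjusted", "test_kind"]
        )
    if len(assoc):
        write_results_table(assoc, outdir / "region_assoc.tsv", "tsv")
    _write_manifest(outdir, config, {"n_region_snps": len(assoc)})
    return assoc
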