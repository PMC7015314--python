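"""Downstream association stages.

Covers the quantitative-phenotype arm (PCA of speed indices, per-SNP
ordinary-least-squares GWAS with covariates, Li-Ji effective number of
independent tests and the derived Bonferroni thresholds), the regional
allelic case-control test (2x2 Pearson chi-square with Haldane-corrected
odds ratios), and an identity-by-state permutation test for cohort
differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, apply_qc

__all__ = [
    "PCAResult",
    "ThresholdSet",
    "pca",
    "gwas_linear",
    "effective_tests_li_ji",
    "li_ji_me_from_correlation",
    "bonferroni_thresholds",
    "allelic_association",
    "ibs_matrix",
    "ibs_permutation_test",
]


@dataclass
class PCAResult:
    """Eigen-decomposition of a correlation or covariance matrix.

    ``loadings`` has one column per component (orthonormal); ``scores`` are
    the centred (and scaled, if standardised) data projected onto them;
    ``variance_fractions`` sum to 1 and are non-increasing.
    """

    loadings: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    standardized: bool


@dataclass
class ThresholdSet:
    """Bonferroni thresholds from an effective number of independent loci."""

    me: float
    genomewide_p: float
    suggestive_p: float


def pca(data: np.ndarray, standardize: bool = True) -> PCAResult:
    """Principal components of a (samples x variables) matrix.

    Decomposes the correlation matrix when ``standardize`` else the
    covariance matrix. Components are ordered by decreasing variance and
    signed so the largest-magnitude loading of each is positive.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 samples and >=2 variables")
    if np.isnan(X).any():
        raise ValueError("PCA input must not contain missing values")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant variable; cannot standardise")
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest |loading| positive per component
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    return PCAResult(
        loadings=eigvec,
        scores=Xc @ eigvec,
        variance_fractions=eigval / eigval.sum(),
        standardized=standardize,
    )


def gwas_linear(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of phenotype on additive alt-allele dosage plus covariates.

    Fits ``y ~ 1 + dosage + covariates`` separately at each SNP, dropping
    individuals with a missing genotype there; reports the genotype-term
    estimate, its standard error, t statistic and two-sided p-value.
    Monomorphic SNPs come back invalid (NaN row). Collinear covariates
    raise an explicit error.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != panel.n_individuals:
        raise ValueError("phenotype length does not match individuals")
    if covariates is None:
        C = np.empty((y.shape[0], 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.shape[0]:
            C = C.T
    base = np.column_stack([np.ones_like(y), C])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError("collinear covariates")
    G = panel.genotypes()
    n_snps = panel.n_snps
    beta = np.full(n_snps, np.nan)
    se = np.full(n_snps, np.nan)
    tval = np.full(n_snps, np.nan)
    pval = np.full(n_snps, np.nan)
    for j in range(n_snps):
        g = G[:, j]
        ok = ~(np.isnan(g) | np.isnan(y))
        gj, yj, Xj = g[ok], y[ok], base[ok]
        if gj.size == 0 or np.all(gj == gj[0]):
            continue  # monomorphic among called -> invalid
        X = np.column_stack([Xj, gj])
        df = X.shape[0] - X.shape[1]
        if df <= 0:
            continue
        xtx = X.T @ X
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            continue
        b = xtx_inv @ (X.T @ yj)
        resid = yj - X @ b
        sigma2 = float(resid @ resid) / df
        se_j = np.sqrt(sigma2 * xtx_inv[-1, -1])
        beta[j] = b[-1]
        se[j] = se_j
        if se_j > 0:
            tval[j] = b[-1] / se_j
            pval[j] = 2 * stats.t.sf(abs(tval[j]), df)
    return pd.DataFrame(
        {
            "snp_id": panel.snps["id"],
            "chrom": panel.snps["chrom"],
            "pos_bp": panel.snps["pos_bp"],
            "beta": beta,
            "se": se,
            "statistic": tval,
            "p_unadj": pval,
            "test_kind": "linear",
        }
    )


def li_ji_me_from_correlation(corr: np.ndarray) -> float:
    """Li & Ji (2005) effective test count from one correlation matrix:
    each eigenvalue lambda contributes I(lambda >= 1) + (lambda - floor(lambda))."""
    eigval = np.linalg.eigvalsh(corr)
    eigval = np.clip(eigval, 0.0, None)
    return float(np.sum((eigval >= 1).astype(float) + (eigval - np.floor(eigval))))


def effective_tests_li_ji(
    panel: GenotypePanel, block: str = "chrom", block_size: int | None = None
) -> float:
    """Effective number of independent loci Me by the Li-Ji eigenvalue method.

    Per block (chromosome by default, optionally fixed-size SNP blocks
    within chromosome), the eigenvalues lambda of the genotype correlation
    matrix contribute f(lambda) = I(lambda >= 1) + (lambda - floor(lambda));
    block totals are summed. Monomorphic SNPs carry no information and
    count zero.
    """
    G = panel.genotypes()
    if G.shape[1] < 2:
        raise ValueError("need >=2 SNPs")
    chroms = panel.snps["chrom"].to_numpy()
    me = 0.0
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        sub = G[:, cols]
        sd = np.nanstd(sub, axis=0)
        sub = sub[:, sd > 0]
        if sub.shape[1] == 0:
            continue
        if sub.shape[1] == 1:
            me += 1.0
            continue
        chunks = (
            [sub]
            if block_size is None
            else [sub[:, i : i + block_size] for i in range(0, sub.shape[1], block_size)]
        )
        for chunk in chunks:
            if chunk.shape[1] == 1:
                me += 1.0
                continue
            corr = pd.DataFrame(chunk).corr().to_numpy()  # pairwise-complete
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            me += li_ji_me_from_correlation(corr)
    return me


def bonferroni_thresholds(me: float, alpha: float = 0.05) -> ThresholdSet:
    """Genome-wide (alpha/Me) and suggestive (1/Me) p-value thresholds."""
    if me < 1:
        raise ValueError("Me must be >= 1")
    return ThresholdSet(me=me, genomewide_p=alpha / me, suggestive_p=1.0 / me)


def allelic_association(
    panel: GenotypePanel,
    case_label: str,
    control_label: str,
    region: tuple[str, int, int] | None = None,
    maf_min: float = 0.05,
    call_min: float = 0.95,
) -> pd.DataFrame:
    """Case-control allelic test over a (regional) SNP set.

    After restricting to ``region`` (chrom, start_bp, end_bp) and applying
    the QC filters (MAF > maf_min, SNP and individual call rate >=
    call_min), each SNP's 2x2 case/control x allele count table is tested
    with a 1-df Pearson chi-square. The odds ratio uses the Haldane
    correction (+0.5 in every cell) when any cell is zero. p_adjusted is
    Bonferroni over the surviving regional SNP count, capped at 1.
    """
    sub = panel if region is None else panel.subset_region(*region)
    labels = sub.individuals["cohort"]
    keep = labels.isin([case_label, control_label]).to_numpy()
    sub = sub.take_individuals(keep)
    sub, _ = apply_qc(sub, snp_call_min=call_min, ind_call_min=call_min, maf_min=maf_min)
    ac_case, an_case = sub.allele_counts(case_label)
    ac_ctrl, an_ctrl = sub.allele_counts(control_label)
    n = sub.n_snps
    chi2 = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    oratio = np.full(n, np.nan)
    for j in range(n):
        table = np.array(
            [
                [ac_case[j], an_case[j] - ac_case[j]],
                [ac_ctrl[j], an_ctrl[j] - ac_ctrl[j]],
            ],
            dtype=float,
        )
        if table.sum() == 0 or (table.sum(axis=1) == 0).any():
            continue
        if (table.sum(axis=0) == 0).any():
            chi2[j], pval[j] = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            chi2[j], pval[j] = stat, p
        t = table + 0.5 if (table == 0).any() else table
        oratio[j] = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    p_adj = np.minimum(pval * n, 1.0)
    return pd.DataFrame(
        {
            "snp_id": sub.snps["id"],
            "chrom": sub.snps["chrom"],
            "pos_bp": sub.snps["pos_bp"],
            "odds_ratio": oratio,
            "statistic": chi2,
            "p_unadj": pval,
            "p_adjusted": p_adj,
            "test_kind": "allelic_chisq",
        }
    )


def ibs_matrix(panel: GenotypePanel) -> np.ndarray:
    """Pairwise identity-by-state similarity between individuals.

    IBS between two individuals at a SNP is the shared-allele fraction of
    their genotypes (1 - |g_i - g_j| / 2 on dosage), averaged over SNPs
    called in both.
    """
    G = panel.genotypes()
    n = G.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        diff = np.abs(G[i] - G[i + 1 :])
        sim = 1.0 - diff / 2.0
        means = np.nanmean(sim, axis=1)
        out[i, i + 1 :] = means
        out[i + 1 :, i] = means
    return out


def ibs_permutation_test(
    panel: GenotypePanel, labels: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Permutation test for cohort differentiation on IBS similarity.

    Observed statistic: mean between-group IBS minus mean within-group IBS
    (negative when groups are differentiated). p-value is the add-one
    lower-tail estimate (1 + #{permuted <= observed}) / (n_perm + 1) over
    seeded label permutations.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("need exactly two groups")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sim = ibs_matrix(panel)
    iu = np.triu_indices(sim.shape[0], k=1)

    def statistic(lab: np.ndarray) -> float:
        between = lab[iu[0]] != lab[iu[1]]
        vals = sim[iu]
        return float(vals[between].mean() - vals[~between].mean())

    obs = statistic(labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if statistic(lab) <= obs:
            count += 1
    return obs, (1 + count) / (n_perm + 1)
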