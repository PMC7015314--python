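"""Synthetic two-cohort genotype panels with drift, LD, sweeps and phenotypes.

The generator emulates the statistical structure a two-population selection
scan assumes: two cohorts of 50 diploids drawn from Balding-Nichols
allele-frequency drift around a shared ancestral frequency (F = 0.05 by
default, matching the modest differentiation expected between connected
breeding populations), haplotypes built as founder mosaics whose switch
rate sets linkage disequilibrium decaying over roughly 0.4 Mb, an optional
planted sweep (one donor haplotype copied into a fraction of the selected
cohort around a core SNP), and optional QTL-driven quantitative phenotypes
and latent-factor speed indices.

Default scale is one 10 Mb chromosome with 10 kb SNP spacing (1,001 SNPs),
which keeps haplotype scans fast while leaving room for 1 Mb windows.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "SweepConfig",
    "QTLConfig",
    "SimulationConfig",
    "simulate_two_pop_panel",
    "plant_sweep",
    "simulate_quantitative_phenotype",
    "simulate_speed_indices",
]

SELECTED = "selected"
REFERENCE = "reference"


@dataclass
class SweepConfig:
    core_index: int = 500  # middle of the default 1,001-SNP chromosome
    f_sweep: float = 0.8  # fraction of selected-cohort haplotypes replaced
    span_bp: int = 1_000_000  # total span (+- span/2 around the core)
    mutation_rate: float = 0.005  # per-SNP flip rate on each copied haplotype


@dataclass
class QTLConfig:
    snp_index: int = 500
    beta: float = 0.5  # phenotype units per alt-allele copy
    residual_sd: float = 1.0
    sex_effect: float = 0.0


@dataclass
class SimulationConfig:
    n_snps: int = 1_001
    n_per_cohort: int = 50
    spacing_bp: int = 10_000
    chrom: str = "1"
    f_drift: float = 0.05  # Balding-Nichols differentiation per cohort
    n_founders: int = 20
    mosaic_switch_rate: float = 0.02  # per-SNP founder-switch probability
    sweep: SweepConfig | None = None
    qtl: QTLConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_drift < 1:
            raise ValueError("f_drift must be in (0, 1)")
        if not 0 <= self.mosaic_switch_rate <= 1:
            raise ValueError("mosaic_switch_rate must be in [0, 1]")
        if self.sweep is not None and not 0 <= self.sweep.f_sweep <= 1:
            raise ValueError("f_sweep must be in [0, 1]")


def _mosaic_haplotypes(
    rng: np.random.Generator, founders: np.ndarray, n_haps: int, switch_rate: float
) -> np.ndarray:
    """Each haplotype copies one founder, switching to a random founder with
    probability ``switch_rate`` at each SNP (geometric segment lengths)."""
    k, n_snps = founders.shape
    switches = rng.random((n_haps, n_snps)) < switch_rate
    switches[:, 0] = True
    choice = rng.integers(0, k, size=(n_haps, n_snps))
    seg = np.maximum.accumulate(np.where(switches, np.arange(n_snps), -1), axis=1)
    donor = np.take_along_axis(choice, seg, axis=1)
    return founders[donor, np.arange(n_snps)[None, :]]


def _founder_pool(rng: np.random.Generator, p_pop: np.ndarray, k: int) -> np.ndarray:
    """Founder haplotypes whose pooled allele frequency tracks p_pop exactly.

    The alt-allele count per SNP is k*p rounded stochastically on the
    remainder, assigned to founders in random order. This prevents the
    finite founder pool from adding founder-effect drift on top of the
    Balding-Nichols differentiation, so the generator's F means what it
    says; a mosaic-sampled allele is still marginally Bernoulli(p_pop).
    """
    m = p_pop.size
    exact = k * p_pop
    n_alt = np.floor(exact).astype(int) + (rng.random(m) < (exact - np.floor(exact)))
    ranks = rng.random((k, m)).argsort(axis=0)
    return (ranks < n_alt[None, :]).astype(np.int8)


def simulate_two_pop_panel(config: SimulationConfig) -> GenotypePanel:
    """Two-cohort phased panel under Balding-Nichols drift with mosaic LD.

    Ancestral frequencies are Uniform(0.05, 0.95); each cohort's frequency
    is Beta(p(1-F)/F, (1-p)(1-F)/F); founder haplotypes are independent
    Bernoulli draws from the cohort frequencies and sampled haplotypes are
    founder mosaics. Fully phased, no missingness; byte-reproducible for a
    given config (the seed is part of the config).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_per_cohort, config.n_snps
    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = config.f_drift
    haps = []
    for _ in range(2):  # selected, reference
        p_pop = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
        founders = _founder_pool(rng, p_pop, config.n_founders)
        haps.append(_mosaic_haplotypes(rng, founders, 2 * n, config.mosaic_switch_rate))
    hap = np.vstack(haps).astype(np.int8)
    pos = (1 + np.arange(m)) * config.spacing_bp
    snps = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(m)],
            "chrom": config.chrom,
            "pos_bp": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"sel{i + 1}" for i in range(n)] + [f"ref{i + 1}" for i in range(n)],
            "sex": (["M", "F"] * n)[:n] + (["M", "F"] * n)[:n],
            "cohort": [SELECTED] * n + [REFERENCE] * n,
        }
    )
    panel = GenotypePanel(snps, hap, individuals, phased=True)
    if config.sweep is not None:
        panel = plant_sweep(panel, config.sweep, seed=config.seed + 1)
    return panel


def plant_sweep(
    panel: GenotypePanel,
    sweep: SweepConfig,
    cohort: str = SELECTED,
    seed: int = 0,
) -> GenotypePanel:
    """Copy one donor haplotype into a fraction of the cohort around a core.

    A fraction ``f_sweep`` of the cohort's haplotypes is replaced, over the
    +- span_bp/2 window around the core SNP, by copies of a single donor
    haplotype; each copy is perturbed by independent per-SNP flips at
    ``mutation_rate`` (the core column itself is never flipped, so the core
    allele frequency in the cohort ends up >= f_sweep).
    """
    if sweep.f_sweep == 0:
        return panel
    if not 0 <= sweep.core_index < panel.n_snps:
        raise ValueError("sweep core index outside panel")
    rng = np.random.default_rng(seed)
    rows = panel.haplotype_rows(cohort)
    pos = panel.snps["pos_bp"].to_numpy()
    core_pos = pos[sweep.core_index]
    span = (pos >= core_pos - sweep.span_bp // 2) & (pos <= core_pos + sweep.span_bp // 2)
    span_idx = np.flatnonzero(span)
    hap = panel.haplotypes.copy()
    donor = hap[rows[0], span_idx].copy()
    n_carriers = int(round(sweep.f_sweep * rows.size))
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    for r in carriers:
        copy = donor.copy()
        flips = rng.random(copy.size) < sweep.mutation_rate
        flips[span_idx == sweep.core_index] = False
        copy[flips] = 1 - copy[flips]
        hap[r, span_idx] = copy
    return replace(panel, haplotypes=hap)


def simulate_quantitative_phenotype(
    panel: GenotypePanel, qtl: QTLConfig, seed: int = 0
) -> pd.DataFrame:
    """Additive single-QTL phenotype with a sex effect and Gaussian noise.

    y = beta * dosage + sex_effect * 1(male) + N(0, residual_sd); sexes are
    assigned alternately M/F for balance. Returns a table (id, sex,
    phenotype) aligned to the panel's individuals.
    """
    g = panel.genotypes()[:, qtl.snp_index]
    if np.nanstd(g) == 0:
        raise ValueError("QTL SNP is monomorphic")
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    sex = np.array(["M", "F"] * ((n + 1) // 2))[:n]
    y = (
        qtl.beta * np.nan_to_num(g, nan=np.nanmean(g))
        + qtl.sex_effect * (sex == "M")
        + rng.normal(0.0, qtl.residual_sd, size=n)
    )
    return pd.DataFrame({"id": panel.individuals["id"], "sex": sex, "phenotype": y})


# Loadings solving (1 + 5 a^2) / 6 = 0.647 for the default PC1 share of the
# six GPS sprint indices (peak velocity, acceleration time, average sprint
# velocity, and the three 6-second distance measures).
DEFAULT_SPEED_LOADINGS = (0.759,) * 6
SPEED_INDEX_NAMES = ["v_peak", "acc", "ave_spr", "dist6a", "dist6b", "dist6"]
# plausible physical units: means and scales per index (m/s, s, m/s, m, m, m)
_SPEED_SHIFT = np.array([16.0, 18.0, 13.5, 90.0, 95.0, 185.0])
_SPEED_SCALE = np.array([1.0, 3.0, 0.9, 6.0, 6.0, 11.0])


def simulate_speed_indices(
    n: int,
    loadings: tuple[float, ...] = DEFAULT_SPEED_LOADINGS,
    noise_sd: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Six sprint-speed indices from a single latent speed factor.

    Each standardised index is loading * latent + sqrt(1 - loading^2) * noise
    (rank-1 plus diagonal correlation), then shifted and scaled to plausible
    units. ``noise_sd`` overrides the unit-variance-preserving noise scale.
    Returns a table (id, sex, v_peak, acc, ave_spr, dist6a, dist6b, dist6).
    """
    lam = np.asarray(loadings, dtype=float)
    if lam.size != 6:
        raise ValueError("need 6 loadings")
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(n, 1))
    noise_scale = np.sqrt(np.clip(1 - lam**2, 0, None)) if noise_sd is None else noise_sd
    Z = latent * lam + rng.normal(size=(n, 6)) * noise_scale
    values = Z * _SPEED_SCALE + _SPEED_SHIFT
    out = pd.DataFrame(values, columns=SPEED_INDEX_NAMES)
    out.insert(0, "sex", np.array(["M", "F"] * ((n + 1) // 2))[:n])
    out.insert(0, "id", [f"horse{i + 1}" for i in range(n)])
    return out
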