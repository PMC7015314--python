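"""Per-SNP constituent selection statistics contrasting two cohorts.

Three statistics feed the composite score:

* ``weir_cockerham_fst`` — the Weir & Cockerham (1984) two-population
  single-locus theta estimate computed from allele counts (the haploid /
  allele-level analysis-of-variance form). Negative estimates are retained
  because the composite uses ranks.
* ``delta_saf`` — signed difference in the frequency of a candidate
  "selected" allele between the selected and reference cohorts. The
  candidate allele defaults to the allele that is minor in the reference
  cohort, a derived-allele proxy when the ancestral state is unknown.
* ``xpehh`` — cross-population extended haplotype homozygosity: the log
  ratio of integrated EHH (iHH) between the two cohorts, where EHH at a
  distance is the probability that two random haplotypes from the cohort
  are identical over the whole span from the core SNP out to that distance
  (the two core-allele curves enter weighted by their pair frequencies).
  Raw scores are standardised genome-wide to mean 0, sd 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, allele_frequencies

__all__ = [
    "ConstituentScores",
    "EHHCurve",
    "weir_cockerham_fst",
    "delta_saf",
    "ehh",
    "xpehh_scan",
    "standardize_xpehh",
    "compute_constituents",
]


@dataclass
class EHHCurve:
    """EHH decay away from a core SNP for one core-allele carrier group."""

    core: int
    allele: int
    offsets: list  # [(pos_bp, ehh)] ordered outward from the core
    truncation_reason: str  # "threshold" | "chromosome_end"

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.offsets])


@dataclass
class ConstituentScores:
    """Index-aligned per-SNP statistics with validity masks."""

    fst: np.ndarray
    dsaf: np.ndarray
    xpehh_raw: np.ndarray
    xpehh_std: np.ndarray
    valid_fst: np.ndarray
    valid_dsaf: np.ndarray
    valid_xpehh: np.ndarray

    def as_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(3 x n) statistic matrix and matching validity mask."""
        stats = np.vstack([self.fst, self.dsaf, self.xpehh_std])
        valid = np.vstack([self.valid_fst, self.valid_dsaf, self.valid_xpehh])
        return stats, valid


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def weir_cockerham_fst(
    ac_sel: np.ndarray, an_sel: np.ndarray, ac_ref: np.ndarray, an_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham theta per SNP from (allele count, allele total) pairs.

    Uses the allele-level ANOVA estimator for r = 2 populations:
    MSP = sum_i n_i (p_i - pbar)^2 / (r - 1),
    MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1),
    n_c = (N - sum n_i^2 / N) / (r - 1),
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG).

    Returns (theta, valid). SNPs monomorphic in both cohorts for the same
    allele (zero denominator) or with fewer than two observed alleles in
    either cohort are flagged invalid.
    """
    ac_sel = np.asarray(ac_sel, dtype=float)
    an_sel = np.asarray(an_sel, dtype=float)
    ac_ref = np.asarray(ac_ref, dtype=float)
    an_ref = np.asarray(an_ref, dtype=float)
    valid = (an_sel >= 2) & (an_ref >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ac_sel / an_sel
        p2 = ac_ref / an_ref
        n = an_sel + an_ref
        pbar = (ac_sel + ac_ref) / n
        msp = an_sel * (p1 - pbar) ** 2 + an_ref * (p2 - pbar) ** 2
        msg = (an_sel * p1 * (1 - p1) + an_ref * p2 * (1 - p2)) / (n - 2)
        nc = n - (an_sel**2 + an_ref**2) / n
        denom = msp + (nc - 1) * msg
        theta = msp - msg
        theta = np.where(denom != 0, theta / np.where(denom == 0, 1, denom), np.nan)
    valid &= ~np.isnan(theta)
    theta = np.where(valid, theta, np.nan)
    return theta, valid


# ---------------------------------------------------------------------------
# Delta-SAF
# ---------------------------------------------------------------------------


def delta_saf(
    freq_sel: np.ndarray, freq_ref: np.ndarray, orientation: str = "ref_minor"
) -> tuple[np.ndarray, np.ndarray]:
    """Signed change in selected-candidate allele frequency.

    ``orientation='ref_minor'`` orients each SNP on the allele that is minor
    in the reference cohort (ties go to the alt allele), so a positive value
    means the candidate allele rose in the selected cohort.
    ``orientation='alt_allele'`` uses the alt allele everywhere.
    """
    f_sel = np.asarray(freq_sel, dtype=float)
    f_ref = np.asarray(freq_ref, dtype=float)
    valid = ~(np.isnan(f_sel) | np.isnan(f_ref))
    if orientation == "alt_allele":
        d = f_sel - f_ref
    elif orientation == "ref_minor":
        flip = f_ref > 0.5
        d = np.where(flip, (1 - f_sel) - (1 - f_ref), f_sel - f_ref)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return np.where(valid, d, np.nan), valid


# ---------------------------------------------------------------------------
# EHH / XP-EHH
# ---------------------------------------------------------------------------


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    allele: int,
    direction: str,
    truncate_at: float = 0.05,
) -> EHHCurve:
    """EHH decay curve for carriers of ``allele`` at the ``core`` SNP.

    At offset SNP j, EHH is the fraction of carrier-haplotype pairs that are
    identical over every SNP from the core through j. Extension stops when
    EHH drops below ``truncate_at`` or the chromosome ends. Haplotypes must
    be complete (no missing alleles) over the scanned span.
    """
    hap = np.asarray(haplotypes)
    positions = np.asarray(positions)
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    carriers = np.flatnonzero(hap[:, core] == allele)
    if carriers.size < 2:
        raise ValueError(f"need >=2 carrier haplotypes at core {core}, got {carriers.size}")
    sub = hap[carriers]
    if (sub == MISSING).any():
        raise ValueError("EHH requires complete haplotypes over the scanned span")
    n_pairs = carriers.size * (carriers.size - 1) // 2
    step = 1 if direction == "right" else -1
    group = np.zeros(carriers.size, dtype=np.int64)
    offsets: list[tuple[int, float]] = []
    reason = "chromosome_end"
    j = core
    while True:
        j += step
        if j < 0 or j >= hap.shape[1]:
            break
        group = _extend_groups(group, sub[:, j])
        value = _pair_homozygosity(group, n_pairs)
        offsets.append((int(positions[j]), value))
        if value < truncate_at:
            reason = "threshold"
            break
    return EHHCurve(core=core, allele=allele, offsets=offsets, truncation_reason=reason)


def _extend_groups(group: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Refine haplotype identity classes by one more SNP, relabelling compactly."""
    key = group * 2 + alleles
    _, new = np.unique(key, return_inverse=True)
    return new


def _pair_homozygosity(group: np.ndarray, n_pairs: int) -> float:
    counts = np.bincount(group)
    return float((counts * (counts - 1) // 2).sum() / n_pairs)


def _ihh_one_side(
    hap: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    truncate_at: float,
    gap_cap_bp: int,
) -> tuple[float, bool]:
    """Integrated pooled EHH on one side of the core (trapezoid over bp).

    The pooled curve counts pairs identical over the full span *including*
    the core SNP, i.e. the frequency-weighted combination of the two
    core-allele EHH curves. Starts at the core homozygosity and integrates
    until the curve falls below ``truncate_at``, the chromosome ends, or an
    inter-SNP gap exceeds ``gap_cap_bp`` (flagged).
    """
    n = hap.shape[0]
    n_pairs = n * (n - 1) // 2
    group = _extend_groups(np.zeros(n, dtype=np.int64), hap[:, core])
    prev_val = _pair_homozygosity(group, n_pairs)
    prev_pos = positions[core]
    area = 0.0
    gap_truncated = False
    j = core
    while prev_val >= truncate_at:
        j += step
        if j < 0 or j >= hap.shape[1]:
            break
        gap = abs(int(positions[j]) - int(prev_pos))
        if gap > gap_cap_bp:
            gap_truncated = True
            break
        group = _extend_groups(group, hap[:, j])
        value = _pair_homozygosity(group, n_pairs)
        area += 0.5 * (prev_val + value) * gap
        prev_val, prev_pos = value, positions[j]
    return area, gap_truncated


def xpehh_scan(
    panel: GenotypePanel,
    selected: str,
    reference: str,
    truncate_at: float = 0.05,
    gap_cap_bp: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (unstandardised) XP-EHH = ln(iHH_sel / iHH_ref) at every SNP.

    SNP columns with any missing allele are excluded from the scan entirely
    (EHH needs complete haplotypes); cores at such columns, or where either
    cohort's iHH is zero/undefined, are flagged invalid. Physical distance
    (bp) stands in for genetic distance.

    Returns (raw, valid) aligned to the panel SNP order.
    """
    hap_sel = panel.cohort_haplotypes(selected)
    hap_ref = panel.cohort_haplotypes(reference)
    n_snps = panel.n_snps
    raw = np.full(n_snps, np.nan)
    valid = np.zeros(n_snps, dtype=bool)
    complete = ~(
        (hap_sel == MISSING).any(axis=0) | (hap_ref == MISSING).any(axis=0)
    )
    chroms = panel.snps["chrom"].to_numpy()
    pos_all = panel.snps["pos_bp"].to_numpy()
    for chrom in pd.unique(chroms):
        on_chrom = np.flatnonzero((chroms == chrom) & complete)
        if on_chrom.size < 2:
            continue
        pos = pos_all[on_chrom]
        hs = np.ascontiguousarray(hap_sel[:, on_chrom])
        hr = np.ascontiguousarray(hap_ref[:, on_chrom])
        for k in range(on_chrom.size):
            il, gl = _ihh_one_side(hs, pos, k, -1, truncate_at, gap_cap_bp)
            ir, _ = _ihh_one_side(hs, pos, k, +1, truncate_at, gap_cap_bp)
            jl, _ = _ihh_one_side(hr, pos, k, -1, truncate_at, gap_cap_bp)
            jr, _ = _ihh_one_side(hr, pos, k, +1, truncate_at, gap_cap_bp)
            ihh_s = il + ir
            ihh_r = jl + jr
            if ihh_s > 0 and ihh_r > 0:
                raw[on_chrom[k]] = np.log(ihh_s / ihh_r)
                valid[on_chrom[k]] = True
    return raw, valid


def standardize_xpehh(raw: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Z-standardise raw XP-EHH over valid entries (genome-wide mean/sd)."""
    raw = np.asarray(raw, dtype=float)
    if valid is None:
        valid = ~np.isnan(raw)
    vals = raw[valid]
    if vals.size < 2:
        raise ValueError("need >=2 valid XP-EHH values to standardise")
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValueError("XP-EHH values are constant; cannot standardise")
    out = np.full(raw.shape, np.nan)
    out[valid] = (raw[valid] - vals.mean()) / sd
    return out


def compute_constituents(
    panel: GenotypePanel,
    selected: str,
    reference: str,
    dsaf_orientation: str = "ref_minor",
    truncate_at: float = 0.05,
    gap_cap_bp: int = 200_000,
) -> ConstituentScores:
    """All three constituent statistics for selected vs reference cohorts."""
    ac_s, an_s = panel.allele_counts(selected)
    ac_r, an_r = panel.allele_counts(reference)
    fst, v_fst = weir_cockerham_fst(ac_s, an_s, ac_r, an_r)
    f_sel = allele_frequencies(panel, selected, "alt")
    f_ref = allele_frequencies(panel, reference, "alt")
    dsaf, v_dsaf = delta_saf(f_sel, f_ref, orientation=dsaf_orientation)
    raw, v_xp = xpehh_scan(panel, selected, reference, truncate_at=truncate_at, gap_cap_bp=gap_cap_bp)
    std = standardize_xpehh(raw, v_xp)
    return ConstituentScores(
        fst=fst, dsaf=dsaf, xpehh_raw=raw, xpehh_std=std,
        valid_fst=v_fst, valid_dsaf=v_dsaf, valid_xpehh=v_xp,
    )
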