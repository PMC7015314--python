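"""Composite selection signal (CSS) scoring.

The composite takes each constituent statistic through six steps: rank
genome-wide, convert ranks to fractional ranks r' = rank/(n+1) in (0,1),
transform to z-values via the standard-normal quantile function, average
the z-values across the m contributing tests at each SNP, obtain an
upper-tail p-value for the mean under N(0, 1/m), and declare
CSS = -log10(p). Finally the score is smoothed within 1 Mb windows
centred on each SNP, never averaging across chromosomes.

Ranks are averaged over ties, which keeps the mean fractional rank at 0.5
and preserves the null calibration. SNPs missing some constituents are
combined with m equal to the number of tests that are available there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CSSResult",
    "fractional_ranks",
    "rank_to_z",
    "css_combine",
    "smooth_by_window",
    "compute_css",
]

_LN10 = np.log(10.0)


@dataclass
class CSSResult:
    """Per-SNP composite scores aligned to the panel SNP order."""

    fractional: np.ndarray  # (m_tests x n) fractional ranks, NaN where invalid
    z: np.ndarray  # (m_tests x n) z-values
    mean_z: np.ndarray
    m: np.ndarray  # tests contributing per SNP
    p: np.ndarray  # upper-tail under N(0, 1/m)
    css: np.ndarray  # -log10 p
    css_smooth: np.ndarray
    valid: np.ndarray  # m >= 1


def fractional_ranks(values: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Ascending fractional ranks r' = rank/(n+1), ties averaged.

    Invalid (masked or NaN) entries propagate as NaN. Output lies strictly
    inside (0, 1).
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = ~np.isnan(values)
    else:
        valid = np.asarray(valid, dtype=bool) & ~np.isnan(values)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("need >=2 valid values to rank")
    out = np.full(values.shape, np.nan)
    ranks = stats.rankdata(values[valid], method="average")
    out[valid] = ranks / (n + 1)
    return out


def rank_to_z(r: np.ndarray) -> np.ndarray:
    """Standard-normal quantile of each fractional rank (NaN passes through)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((r <= 0) | (r >= 1)):
            raise ValueError("fractional ranks must lie strictly in (0, 1)")
    return stats.norm.ppf(r)


def css_combine(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Combine an (m_tests x n) z matrix into (mean_z, m, p, css) per SNP.

    p is the upper-tail probability of the mean under N(0, 1/m) with m the
    per-SNP count of non-NaN tests; css = -log10 p (computed in log space
    so extreme scores do not underflow). SNPs with m = 0 come out NaN.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    m = (~np.isnan(z)).sum(axis=0).astype(float)
    ok = m >= 1
    with np.errstate(invalid="ignore"):
        mean_z = np.where(ok, np.nansum(np.nan_to_num(z, nan=0.0), axis=0) / np.maximum(m, 1), np.nan)
    p = np.full(z.shape[1], np.nan)
    css = np.full(z.shape[1], np.nan)
    # mean ~ N(0, 1/m)  =>  sqrt(m) * mean ~ N(0, 1)
    logp = stats.norm.logsf(mean_z[ok] * np.sqrt(m[ok]))
    p[ok] = np.exp(logp)
    css[ok] = -logp / _LN10
    return mean_z, m.astype(int), p, css


def smooth_by_window(
    css: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    half_width_bp: int = 500_000,
) -> np.ndarray:
    """Mean of css over SNPs within +-half_width_bp on the same chromosome.

    The window is centred on each SNP (total span 1 Mb at the default) and
    NaN scores are ignored; a SNP whose window holds no valid score stays
    NaN. Positions must be sorted within chromosome (panel convention).
    """
    css = np.asarray(css, dtype=float)
    positions = np.asarray(positions)
    chroms = np.asarray(chroms)
    out = np.full(css.shape, np.nan)
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        vals = css[idx]
        ok = ~np.isnan(vals)
        filled = np.where(ok, vals, 0.0)
        csum = np.concatenate([[0.0], np.cumsum(filled)])
        ccount = np.concatenate([[0], np.cumsum(ok.astype(int))])
        lo = np.searchsorted(pos, pos - half_width_bp, side="left")
        hi = np.searchsorted(pos, pos + half_width_bp, side="right")
        total = csum[hi] - csum[lo]
        count = ccount[hi] - ccount[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[idx] = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out


def compute_css(
    stats_matrix: np.ndarray,
    valid_matrix: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    half_width_bp: int = 500_000,
) -> CSSResult:
    """Full composite pipeline from an (m_tests x n) statistic matrix."""
    stats_matrix = np.atleast_2d(np.asarray(stats_matrix, dtype=float))
    valid_matrix = np.atleast_2d(np.asarray(valid_matrix, dtype=bool))
    frac = np.full(stats_matrix.shape, np.nan)
    for t in range(stats_matrix.shape[0]):
        frac[t] = fractional_ranks(stats_matrix[t], valid_matrix[t])
    z = np.where(np.isnan(frac), np.nan, stats.norm.ppf(np.clip(frac, 1e-300, 1 - 1e-16)))
    mean_z, m, p, css = css_combine(z)
    smooth = smooth_by_window(css, positions, chroms, half_width_bp=half_width_bp)
    return CSSResult(
        fractional=frac, z=z, mean_z=mean_z, m=m, p=p, css=css,
        css_smooth=smooth, valid=m >= 1,
    )
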