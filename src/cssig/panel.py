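"""Genotype panels: reading, writing, QC and allele frequencies.

A :class:`GenotypePanel` holds a SNP map (pandas DataFrame), a phased
haplotype matrix of shape ``(2 * n_individuals, n_snps)`` with entries in
``{0, 1, MISSING}``, and an individual table carrying sex and cohort labels.
Positions are 1-based inclusive (VCF convention) throughout; BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing haplotype allele.
MISSING = np.int8(-1)

SNP_COLUMNS = ["id", "chrom", "pos_bp", "ref", "alt"]
RESULT_COLUMNS = ["snp_id", "chrom", "pos_bp", "fst", "dsaf", "xpehh", "css", "css_smooth"]


class PanelError(ValueError):
    """Raised on malformed genotype input or an empty panel after filtering."""


@dataclass
class QCReport:
    """Bookkeeping for :func:`apply_qc`; counts reconcile in - removed = out."""

    n_snps_in: int
    n_snps_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed_snps: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["id", "reason"]))
    removed_individuals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["id", "reason"]))

    def __post_init__(self) -> None:
        assert self.n_snps_in - len(self.removed_snps) == self.n_snps_out
        assert self.n_individuals_in - len(self.removed_individuals) == self.n_individuals_out


@dataclass
class GenotypePanel:
    """Phased SNP genotypes for a set of individuals split into cohorts.

    Parameters
    ----------
    snps : DataFrame with columns id, chrom, pos_bp, ref, alt, sorted by
        (chrom, pos_bp).
    haplotypes : int8 array (2n x m); row 2i and 2i+1 are the two haplotypes
        of individual i; entries 0 (ref), 1 (alt) or -1 (missing).
    individuals : DataFrame with columns id, sex, cohort.
    phased : whether haplotype phase is meaningful (required for EHH).
    """

    snps: pd.DataFrame
    haplotypes: np.ndarray
    individuals: pd.DataFrame
    phased: bool = True

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.individuals), len(self.snps)):
            raise PanelError(
                f"haplotype matrix {self.haplotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        order = self.snps.sort_values(["chrom", "pos_bp"], kind="stable").index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.haplotypes = self.haplotypes[:, order]

    # -- basic views ---------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.individuals["cohort"].dropna().unique())

    def haplotype_rows(self, cohort: str | None = None) -> np.ndarray:
        """Row indices into ``haplotypes`` for a cohort (or all)."""
        if cohort is None:
            idx = np.arange(self.n_individuals)
        else:
            idx = np.flatnonzero((self.individuals["cohort"] == cohort).to_numpy())
            if idx.size == 0:
                raise PanelError(f"no individuals in cohort {cohort!r}")
        return np.repeat(2 * idx, 2) + np.tile([0, 1], idx.size)

    def cohort_haplotypes(self, cohort: str) -> np.ndarray:
        return self.haplotypes[self.haplotype_rows(cohort)]

    def genotypes(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_individuals x n_snps), NaN if either
        haplotype is missing."""
        h = self.haplotypes.astype(float)
        h[h == MISSING] = np.nan
        return h[0::2] + h[1::2]

    # -- subsetting ----------------------------------------------------

    def take_snps(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(self, snps=self.snps.iloc[index], haplotypes=self.haplotypes[:, index])

    def take_individuals(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        rows = np.repeat(2 * index, 2) + np.tile([0, 1], index.size)
        return replace(self, individuals=self.individuals.iloc[index], haplotypes=self.haplotypes[rows])

    def subset_region(self, chrom: str, start_bp: int, end_bp: int) -> "GenotypePanel":
        """SNPs with start_bp <= pos_bp <= end_bp on ``chrom`` (1-based inclusive)."""
        m = (
            (self.snps["chrom"].astype(str) == str(chrom))
            & (self.snps["pos_bp"] >= start_bp)
            & (self.snps["pos_bp"] <= end_bp)
        ).to_numpy()
        return self.take_snps(m)

    # -- per-SNP summaries ---------------------------------------------

    def allele_counts(self, cohort: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, non-missing allele total) per SNP."""
        h = self.haplotypes if cohort is None else self.cohort_haplotypes(cohort)
        called = h != MISSING
        return (h == 1).sum(axis=0), called.sum(axis=0)

    def snp_call_rate(self) -> np.ndarray:
        g = self.haplotypes != MISSING
        called = g[0::2] & g[1::2]
        return called.mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        g = self.haplotypes != MISSING
        called = g[0::2] & g[1::2]
        return called.mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over the whole panel (NaN if no calls)."""
        ac, an = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return np.fmin(p, 1.0 - p)


def allele_frequencies(panel: GenotypePanel, cohort: str, allele: str = "alt") -> np.ndarray:
    """Per-SNP frequency of ``allele`` ('ref' or 'alt') within a cohort.

    Missing alleles are excluded from the denominator; a SNP with no called
    alleles in the cohort yields NaN, never 0.
    """
    if allele not in ("ref", "alt"):
        raise ValueError("allele must be 'ref' or 'alt'")
    ac, an = panel.allele_counts(cohort)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    return f if allele == "alt" else np.where(np.isnan(f), np.nan, 1.0 - f)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_vcf(path, cohorts: dict[str, str] | None = None, require_phased: bool = True) -> GenotypePanel:
    """Read a VCF into a panel, keeping biallelic SNPs only.

    Multi-allelic and indel records are dropped with a logged count.
    ``cohorts`` maps sample id -> cohort label (samples absent from the map
    get cohort NaN). Unphased heterozygous genotypes raise unless
    ``require_phased=False``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    any_unphased = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        gt = np.asarray(var.genotype.array())  # (n_samples, 3): a1, a2, phased
        col = np.empty(2 * len(samples), dtype=np.int8)
        col[0::2] = gt[:, 0]
        col[1::2] = gt[:, 1]
        col[col < 0] = MISSING
        het_unphased = (gt[:, 2] == 0) & (gt[:, 0] >= 0) & (gt[:, 0] != gt[:, 1])
        if het_unphased.any():
            any_unphased = True
        vid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        rows.append((vid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        columns.append(col)
    vcf.close()
    if any_unphased and require_phased:
        raise PanelError(f"{path}: unphased heterozygous genotypes but phased data required")
    if not rows:
        raise PanelError(f"{path}: no biallelic SNP records")
    if n_dropped:
        logger.info("%s: dropped %d non-biallelic-SNP records", path, n_dropped)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    hap = np.column_stack(columns)
    cohorts = cohorts or {}
    individuals = pd.DataFrame(
        {"id": samples, "sex": pd.NA, "cohort": [cohorts.get(s) for s in samples]}
    )
    return GenotypePanel(snps, hap, individuals, phased=not any_unphased)


def read_plink_text(
    ped_path,
    map_path,
    cohorts: dict[str, str] | None = None,
    alleles: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Read PLINK text .ped/.map files.

    ``alleles`` may supply the ref/alt coding as a DataFrame with columns
    (id, ref, alt); otherwise ref is the major allele observed in the file
    (ties broken alphabetically) and alt the minor.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos_bp"], dtype={"chrom": str}
    )
    n_snps = len(mp)
    ids, sexes, hap_rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PanelError(f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}")
            ids.append(parts[1])
            sexes.append({"1": "M", "2": "F"}.get(parts[4], pd.NA))
            hap_rows.append(parts[6:])
    alle = np.asarray(hap_rows, dtype="U8")
    a1 = alle[:, 0::2]
    a2 = alle[:, 1::2]
    if alleles is not None:
        coding = alleles.set_index("id").loc[mp["id"], ["ref", "alt"]]
        ref = coding["ref"].to_numpy(dtype="U8")
        alt = coding["alt"].to_numpy(dtype="U8")
    else:
        ref = np.empty(n_snps, dtype="U8")
        alt = np.empty(n_snps, dtype="U8")
        for j in range(n_snps):
            obs = np.concatenate([a1[:, j], a2[:, j]])
            obs = obs[obs != "0"]
            uniq, counts = np.unique(obs, return_counts=True)
            if uniq.size == 0:
                ref[j], alt[j] = "N", "N"
            elif uniq.size == 1:
                ref[j], alt[j] = uniq[0], "."
            elif uniq.size == 2:
                # major allele -> ref; alphabetical tie-break for determinism
                order = np.lexsort((uniq, -counts))
                ref[j], alt[j] = uniq[order[0]], uniq[order[1]]
            else:
                raise PanelError(f"{ped_path}: SNP {mp['id'][j]} has >2 alleles")

    def code(a: np.ndarray) -> np.ndarray:
        out = np.full(a.shape, MISSING, dtype=np.int8)
        out[a == ref[None, :]] = 0
        out[a == alt[None, :]] = 1
        return out

    hap = np.empty((2 * len(ids), n_snps), dtype=np.int8)
    hap[0::2] = code(a1)
    hap[1::2] = code(a2)
    snps = pd.DataFrame(
        {"id": mp["id"], "chrom": mp["chrom"].astype(str), "pos_bp": mp["pos_bp"].astype(int), "ref": ref, "alt": alt}
    )
    cohorts = cohorts or {}
    individuals = pd.DataFrame({"id": ids, "sex": sexes, "cohort": [cohorts.get(s) for s in ids]})
    # .ped carries no phase information
    return GenotypePanel(snps, hap, individuals, phased=False)


def read_genotypes(path, format: str, map_path=None, cohorts=None, **kw) -> GenotypePanel:
    """Dispatch to :func:`read_vcf` or :func:`read_plink_text`."""
    if format == "vcf":
        return read_vcf(path, cohorts=cohorts, **kw)
    if format == "plink_text":
        if map_path is None:
            raise ValueError("plink_text format requires map_path")
        return read_plink_text(path, map_path, cohorts=cohorts, **kw)
    raise ValueError(f"unknown format {format!r}")


def read_cohort_file(path) -> dict[str, str]:
    """Two-column id -> cohort label TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "cohort"], dtype=str)
    return dict(zip(df["id"], df["cohort"]))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a minimal phased VCF 4.2 text file."""
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.individuals["id"]) + "\n")
        hap = panel.haplotypes
        for j, snp in panel.snps.iterrows():
            a = hap[0::2, j]
            b = hap[1::2, j]
            gts = [
                f"{'.' if x == MISSING else x}{sep}{'.' if y == MISSING else y}"
                for x, y in zip(a, b)
            ]
            fh.write(
                f"{snp.chrom}\t{snp.pos_bp}\t{snp.id}\t{snp.ref}\t{snp.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_results_table(records: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write scored SNPs or regions as TSV, or regions as BED.

    BED output converts 1-based inclusive (start_bp, end_bp) intervals to
    0-based half-open. Refuses to write an empty table.
    """
    if len(records) == 0:
        raise ValueError("refusing to write an empty results table")
    if format == "tsv":
        records.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        required = {"chrom", "start_bp", "end_bp"}
        if not required.issubset(records.columns):
            raise ValueError(f"BED output needs columns {sorted(required)}")
        bed = pd.DataFrame(
            {
                "chrom": records["chrom"],
                "start": records["start_bp"].astype(int) - 1,
                "end": records["end_bp"].astype(int),
            }
        )
        extra = [c for c in records.columns if c not in required]
        for c in extra:
            bed[c] = records[c].to_numpy()
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def apply_qc(
    panel: GenotypePanel,
    snp_call_min: float = 0.95,
    ind_call_min: float = 0.95,
    maf_min: float = 0.01,
) -> tuple[GenotypePanel, QCReport]:
    """Filter SNPs and individuals on call rate, and SNPs on MAF.

    Surviving SNPs have call rate >= ``snp_call_min`` and MAF strictly
    greater than ``maf_min``; individuals have call rate >= ``ind_call_min``.
    Filters are iterated to a fixed point, which makes the operation
    idempotent. Raises :class:`PanelError` if nothing survives.
    """
    for thr in (snp_call_min, ind_call_min, maf_min):
        if not 0 <= thr <= 1:
            raise ValueError("QC thresholds must be in [0, 1]")
    removed_snps: list[tuple[str, str]] = []
    removed_inds: list[tuple[str, str]] = []
    n_snps_in, n_inds_in = panel.n_snps, panel.n_individuals
    out = panel
    while True:
        changed = False
        if out.n_snps == 0 or out.n_individuals == 0:
            break
        cr = out.snp_call_rate()
        keep = cr >= snp_call_min
        if not keep.all():
            removed_snps += [(sid, "low_call_rate") for sid in out.snps.loc[~keep, "id"]]
            out = out.take_snps(keep)
            changed = True
        if out.n_snps:
            icr = out.individual_call_rate()
            ikeep = icr >= ind_call_min
            if not ikeep.all():
                removed_inds += [(iid, "low_call_rate") for iid in out.individuals.loc[~ikeep, "id"]]
                out = out.take_individuals(ikeep)
                changed = True
        if out.n_snps and out.n_individuals:
            maf = out.maf()
            with np.errstate(invalid="ignore"):
                mkeep = maf > maf_min
            mkeep &= ~np.isnan(maf)
            if not mkeep.all():
                mono = np.nan_to_num(maf, nan=0.0) == 0
                for sid, is_mono in zip(out.snps.loc[~mkeep, "id"], mono[~mkeep]):
                    removed_snps.append((sid, "monomorphic" if is_mono else "low_maf"))
                out = out.take_snps(mkeep)
                changed = True
        if not changed:
            break
    if out.n_snps == 0:
        raise PanelError("QC removed every SNP")
    report = QCReport(
        n_snps_in=n_snps_in,
        n_snps_out=out.n_snps,
        n_individuals_in=n_inds_in,
        n_individuals_out=out.n_individuals,
        removed_snps=pd.DataFrame(removed_snps, columns=["id", "reason"]),
        removed_individuals=pd.DataFrame(removed_inds, columns=["id", "reason"]),
    )
    logger.info(
        "QC: %d/%d SNPs, %d/%d individuals retained",
        report.n_snps_out, n_snps_in, report.n_individuals_out, n_inds_in,
    )
    return out, report
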