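"""Pooled variant data: containers, VCF / count-table I/O, and post-calling filters.

Pooled sequencing (Pool-seq) yields per-pool read depths for the reference and
alternate allele at each SNP rather than individual genotypes.  This module
houses the :class:`PoolCounts` container used by every downstream scan, reads
it from a VCF with per-sample ``AD`` fields or from a tab-separated count
table, and applies the standard post-calling variant filters (per-pool depth
bounds, site missingness, minor-allele-frequency support).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PoolCounts",
    "FilterConfig",
    "read_pool_vcf",
    "write_pool_vcf",
    "read_count_table",
    "write_count_table",
    "apply_variant_filters",
    "major_minor_counts",
]


@dataclass
class PoolCounts:
    """Per-SNP, per-pool read counts for biallelic SNPs.

    Attributes
    ----------
    chrom : ndarray of str, shape (n_snps,)
    pos : ndarray of int, shape (n_snps,)
        1-based physical positions, strictly increasing within a chromosome.
    ref_allele, alt_allele : ndarray of str, shape (n_snps,)
    ref_reads, alt_reads : ndarray of int, shape (n_snps, n_pools)
        Read depth supporting each allele; a depth of 0 encodes a missing
        observation for that pool.
    pool_names : list of str
    pool_haploid_sizes : ndarray of int, shape (n_pools,)
        Number of chromosomes per pool (2 x diploid individuals); must be
        >= 2 for within-pool identity-by-state to be defined.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    pool_names: list[str]
    pool_haploid_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int64)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
        if self.pool_haploid_sizes is None:
            raise ValueError("pool_haploid_sizes is required")
        self.pool_haploid_sizes = np.asarray(self.pool_haploid_sizes, dtype=np.int64)
        if self.ref_reads.shape != self.alt_reads.shape:
            raise ValueError("ref_reads and alt_reads shapes differ")
        if self.ref_reads.ndim != 2:
            raise ValueError("read matrices must be 2-D (snp x pool)")
        if self.ref_reads.shape[1] != len(self.pool_names):
            raise ValueError("pool dimension does not match pool_names")
        if len(self.pool_haploid_sizes) != len(self.pool_names):
            raise ValueError("pool_haploid_sizes does not match pool_names")
        if (self.ref_reads < 0).any() or (self.alt_reads < 0).any():
            raise ValueError("negative read counts")
        if (self.pool_haploid_sizes < 2).any():
            raise ValueError("pool_haploid_sizes must be >= 2")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic derived quantities -------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.ref_reads.shape[0]

    @property
    def n_pools(self) -> int:
        return self.ref_reads.shape[1]

    def depth(self) -> np.ndarray:
        """Total read depth per SNP per pool (snp x pool)."""
        return self.ref_reads + self.alt_reads

    def alt_frequency(self) -> np.ndarray:
        """Read-based alternate-allele frequency; NaN where depth is 0."""
        d = self.depth().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.alt_reads / d, np.nan)

    def pool_index(self, pool: int | str) -> int:
        if isinstance(pool, str):
            try:
                return self.pool_names.index(pool)
            except ValueError:
                raise KeyError(f"unknown pool {pool!r}") from None
        if not 0 <= pool < self.n_pools:
            raise KeyError(f"pool index {pool} out of range")
        return int(pool)

    def take(self, snp_mask: np.ndarray) -> "PoolCounts":
        """Row-subset (SNP axis) preserving order."""
        return PoolCounts(
            chrom=self.chrom[snp_mask],
            pos=self.pos[snp_mask],
            ref_allele=np.asarray(self.ref_allele, dtype=object)[snp_mask],
            alt_allele=np.asarray(self.alt_allele, dtype=object)[snp_mask],
            ref_reads=self.ref_reads[snp_mask],
            alt_reads=self.alt_reads[snp_mask],
            pool_names=list(self.pool_names),
            pool_haploid_sizes=self.pool_haploid_sizes.copy(),
        )


@dataclass(frozen=True)
class FilterConfig:
    """Post-calling variant filter thresholds.

    ``min_depth``/``max_depth`` define per-pool missingness (an observation
    outside the depth bounds counts as missing); a SNP is removed when the
    missing fraction across pools exceeds ``max_missing_fraction``, and then
    retained only if its minor-allele read frequency is >= ``maf_threshold``
    in at least ``min_pools_at_maf`` non-missing pools.
    """

    min_depth: int = 10
    max_depth: int = 400
    maf_threshold: float = 0.02
    min_pools_at_maf: int = 2
    max_missing_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth > max_depth")


# -- I/O ---------------------------------------------------------------------------


def read_pool_vcf(path: str, pool_sizes: dict[str, int]) -> PoolCounts:
    """Read biallelic SNP records with per-sample AD into a :class:`PoolCounts`.

    Multiallelic and non-SNP records are skipped (count logged).  ``pool_sizes``
    maps every VCF sample name to its haploid pool size.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in pool_sizes:
            raise ValueError(f"sample {s!r} missing from pool_sizes")
    chroms, poss, refs, alts = [], [], [], []
    ref_rows, alt_rows = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks AD")
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes '.' as negative sentinel
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ref_rows.append(ad[:, 0])
        alt_rows.append(ad[:, 1])
    vcf.close()
    if skipped:
        logger.info("read_pool_vcf: skipped %d multiallelic/non-SNP records", skipped)
    if not chroms:
        raise ValueError(f"no biallelic SNP records in {path}")
    return PoolCounts(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        ref_reads=np.vstack(ref_rows),
        alt_reads=np.vstack(alt_rows),
        pool_names=samples,
        pool_haploid_sizes=np.array([pool_sizes[s] for s in samples]),
    )


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_pool_vcf(counts: PoolCounts, path: str) -> None:
    """Write a minimal VCF 4.2 with one sample column per pool and AD=ref,alt."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for c in pd.unique(counts.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(counts.pool_names)
            + "\n"
        )
        for i in range(counts.n_snps):
            cols = [
                str(counts.chrom[i]),
                str(int(counts.pos[i])),
                ".",
                str(counts.ref_allele[i]),
                str(counts.alt_allele[i]),
                ".",
                "PASS",
                ".",
                "AD",
            ]
            cols += [
                f"{counts.ref_reads[i, j]},{counts.alt_reads[i, j]}"
                for j in range(counts.n_pools)
            ]
            fh.write("\t".join(cols) + "\n")


def write_count_table(counts: PoolCounts, path: str) -> None:
    """Tab-separated dialect: chrom, pos, ref, alt, then one ref:alt column per pool."""
    with _open_text(path, "wt") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(counts.pool_names) + "\n")
        for i in range(counts.n_snps):
            cells = [
                f"{counts.ref_reads[i, j]}:{counts.alt_reads[i, j]}"
                for j in range(counts.n_pools)
            ]
            fh.write(
                f"{counts.chrom[i]}\t{counts.pos[i]}\t{counts.ref_allele[i]}\t"
                f"{counts.alt_allele[i]}\t" + "\t".join(cells) + "\n"
            )


def read_count_table(path: str, pool_sizes: dict[str, int]) -> PoolCounts:
    """Read the tab-separated dialect written by :func:`write_count_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pool_names = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    for s in pool_names:
        if s not in pool_sizes:
            raise ValueError(f"pool {s!r} missing from pool_sizes")
    split = [df[c].str.split(":", expand=True).astype(np.int64) for c in pool_names]
    ref = np.column_stack([s[0].to_numpy() for s in split])
    alt = np.column_stack([s[1].to_numpy() for s in split])
    return PoolCounts(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(),
        ref_allele=df["ref"].to_numpy(dtype=object),
        alt_allele=df["alt"].to_numpy(dtype=object),
        ref_reads=ref,
        alt_reads=alt,
        pool_names=pool_names,
        pool_haploid_sizes=np.array([pool_sizes[s] for s in pool_names]),
    )


# -- filtering ---------------------------------------------------------------------


def missing_mask(counts: PoolCounts, cfg: FilterConfig) -> np.ndarray:
    """Boolean (snp x pool): observation missing under the depth bounds."""
    d = counts.depth()
    return (d < cfg.min_depth) | (d > cfg.max_depth)


def apply_variant_filters(
    counts: PoolCounts, cfg: FilterConfig | None = None
) -> tuple[PoolCounts, dict[str, int]]:
    """Apply depth-based missingness and MAF-support filters.

    Returns the surviving :class:`PoolCounts` (order preserved) and removal
    counts per rule in application order: ``missingness`` first, then ``maf``.
    """
    cfg = cfg or FilterConfig()
    miss = missing_mask(counts, cfg)
    frac_missing = miss.mean(axis=1)
    keep_missing = frac_missing <= cfg.max_missing_fraction

    freq = counts.alt_frequency()
    freq = np.where(miss, np.nan, freq)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
        n_support = np.nansum(maf >= cfg.maf_threshold, axis=1)
    keep_maf = n_support >= cfg.min_pools_at_maf

    removed_missing = int((~keep_missing).sum())
    removed_maf = int((keep_missing & ~keep_maf).sum())
    out = counts.take(keep_missing & keep_maf)
    report = {"missingness": removed_missing, "maf": removed_maf}
    logger.info(
        "apply_variant_filters: %d in, %d removed (missingness), %d removed (maf), %d out",
        counts.n_snps, removed_missing, removed_maf, out.n_snps,
    )
    return out, report


def major_minor_counts(counts: PoolCounts, pool: int | str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP major/minor read counts within one pool.

    The major allele is the one with more reads in this pool; ties assign
    ref as major.  Depth-0 SNPs yield (0, 0).
    """
    j = counts.pool_index(pool)
    r = counts.ref_reads[:, j]
    a = counts.alt_reads[:, j]
    n_maj = np.where(r >= a, r, a)
    n_min = np.where(r >= a, a, r)
    return n_maj, n_min
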