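"""Windowed pooled FST and pooled-heterozygosity (Hp / ZHp) genome scans.

FST between pools is estimated from identity-by-state (IBS) probabilities:
``Q1`` for two distinct chromosomes within a pool and ``Q2`` for chromosomes
from two different pools, combined as ``FST = (Q1 - Q2) / (1 - Q2)``
(the Weir–Cockerham-style convention of the pooled ANOVA estimator family).
Both are estimated from read counts with explicit corrections for the two
stages of pooled sequencing — chromosomes sampled into the pool, then reads
sampled with replacement from the pool — so that the estimators are unbiased
at the population level.

The within-population scan uses the pooled heterozygosity

    Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))^2

over sliding windows of SNPs (major/minor read counts summed across the
window), Z-transformed genome-wide into ZHp; strongly negative ZHp flags
putative selective sweeps.

Windows are defined over SNP indices (default 625 SNPs, step 312), never span
chromosome boundaries, and trailing partial windows are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .poolio import PoolCounts, major_minor_counts

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "estimate_q1",
    "estimate_q2",
    "iis_estimates",
    "pairwise_fst_windows",
    "genomewide_fst",
    "hp_windows",
    "zhp_transform",
]

#: minimum read depth for within-pool IBS (needs two distinct reads)
MIN_DEPTH_Q1 = 2


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry over SNP indices."""

    window_snps: int = 625
    step_snps: int = 312

    def __post_init__(self) -> None:
        if not 1 <= self.step_snps <= self.window_snps:
            raise ValueError("require 1 <= step_snps <= window_snps")

    def starts(self, n: int) -> np.ndarray:
        """Window start indices for a chromosome with n usable SNPs."""
        if n < self.window_snps:
            return np.empty(0, dtype=np.int64)
        n_win = (n - self.window_snps) // self.step_snps + 1
        return np.arange(n_win, dtype=np.int64) * self.step_snps


def estimate_q1(
    ref_reads: np.ndarray, alt_reads: np.ndarray, pool_haploid_size: int
) -> np.ndarray:
    """Unbiased within-pool IBS probability from read counts.

    With read alt-frequency ``p = alt / c`` at depth ``c`` and haploid pool
    size ``n``::

        Q1_hat = 1 - (n/(n-1)) * (c/(c-1)) * 2*p*(1-p)

    The ``c/(c-1)`` factor undoes the with-replacement read sampling, the
    ``n/(n-1)`` factor undoes the chance of reading the same chromosome
    twice; the expectation equals the IBS probability of two distinct
    chromosomes.  May be slightly negative (unbiasedness correction).
    Depth < 2 yields NaN (missing).
    """
    n = float(pool_haploid_size)
    r = np.asarray(ref_reads, dtype=float)
    a = np.asarray(alt_reads, dtype=float)
    c = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(c > 0, a / c, np.nan)
        het = 2.0 * p * (1.0 - p)
        q1 = 1.0 - (n / (n - 1.0)) * (c / (c - 1.0)) * het
    return np.where(c >= MIN_DEPTH_Q1, q1, np.nan)


def estimate_q2(p_i: np.ndarray, p_j: np.ndarray) -> np.ndarray:
    """Between-pool IBS probability from read frequencies.

    Reads are independent across pools, so the plug-in
    ``p_i*p_j + (1-p_i)*(1-p_j)`` is unbiased.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    return p_i * p_j + (1.0 - p_i) * (1.0 - p_j)


def iis_estimates(counts: PoolCounts) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray]]:
    """Per-SNP Q1_hat per pool and Q2_hat per unordered pool pair."""
    q1 = np.column_stack(
        [
            estimate_q1(
                counts.ref_reads[:, j],
                counts.alt_reads[:, j],
                counts.pool_haploid_sizes[j],
            )
            for j in range(counts.n_pools)
        ]
    )
    freq = counts.alt_frequency()
    q2 = {
        (i, j): estimate_q2(freq[:, i], freq[:, j])
        for i in range(counts.n_pools)
        for j in range(i + 1, counts.n_pools)
    }
    return q1, q2


def _window_frame(
    counts: PoolCounts,
    spec: WindowSpec,
    num: np.ndarray,
    den: np.ndarray,
    stat: str,
    usable: np.ndarray,
) -> pd.DataFrame:
    """Aggregate per-SNP numerator/denominator into ratio-of-sums windows.

    ``usable`` marks SNPs entering the sums; unusable SNPs contribute 0 to
    both.  Windows whose denominator is 0 (or with no usable SNP) are dropped
    with a warning.
    """
    rows = []
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    n_dropped = 0
    for c in pd.unique(counts.chrom):
        idx = np.flatnonzero(counts.chrom == c)
        pos_c = counts.pos[idx]
        num_c = np.concatenate([[0.0], np.cumsum(num[idx])])
        den_c = np.concatenate([[0.0], np.cumsum(den[idx])])
        use_c = np.concatenate([[0], np.cumsum(usable[idx].astype(int))])
        for s in spec.starts(len(idx)):
            e = s + spec.window_snps
            d = den_c[e] - den_c[s]
            n_use = use_c[e] - use_c[s]
            if n_use == 0 or d == 0:
                n_dropped += 1
                continue
            start_pos, end_pos = int(pos_c[s]), int(pos_c[e - 1])
            rows.append(
                {
                    "chrom": c,
                    "start_pos": start_pos,
                    "end_pos": end_pos,
                    "mid_pos": (start_pos + end_pos) // 2,
                    "n_snps": spec.window_snps,
                    "stat": stat,
                    "value": (num_c[e] - num_c[s]) / d,
                }
            )
    if n_dropped:
        logger.warning("%s: dropped %d undefined windows", stat, n_dropped)
    if not rows:
        raise ValueError(f"no complete {spec.window_snps}-SNP window on any chromosome")
    return pd.DataFrame(rows)


def pairwise_fst_windows(
    counts: PoolCounts,
    pool_i: int | str,
    pool_j: int | str,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Sliding-window pairwise FST between two pools (ratio-of-sums).

    Per window, ``FST = sum(Q1bar - Q2) / sum(1 - Q2)`` over SNPs non-missing
    in both pools, where ``Q1bar`` averages the two pools' Q1_hat.
    """
    spec = spec or WindowSpec()
    i = counts.pool_index(pool_i)
    j = counts.pool_index(pool_j)
    q1_all, q2_all = iis_estimates(counts)
    q1bar = (q1_all[:, i] + q1_all[:, j]) / 2.0
    q2 = q2_all[(min(i, j), max(i, j))]
    usable = ~np.isnan(q1bar) & ~np.isnan(q2)
    num = q1bar - q2
    den = 1.0 - q2
    return _window_frame(counts, spec, num, den, "fst", usable)


def genomewide_fst(counts: PoolCounts, pools: list | None = None) -> float:
    """Genome-wide multi-pool FST: ratio of sums over all usable SNPs.

    Q1_hat is averaged (unweighted) over the selected pools and Q2_hat over
    unordered pool pairs; SNPs missing in any selected pool are excluded.
    """
    idx = (
        list(range(counts.n_pools))
        if pools is None
        else [counts.pool_index(p) for p in pools]
    )
    if len(idx) < 2:
        raise ValueError("genomewide_fst requires at least 2 pools")
    q1_all, q2_all = iis_estimates(counts)
    q1bar = q1_all[:, idx].mean(axis=1)
    pairs = [(min(a, b), max(a, b)) for k, a in enumerate(idx) for b in idx[k + 1 :]]
    q2bar = np.mean([q2_all[p] for p in pairs], axis=0)
    usable = ~np.isnan(q1bar) & ~np.isnan(q2bar)
    if not usable.any():
        raise ValueError("no usable SNPs")
    num = (q1bar - q2bar)[usable].sum()
    den = (1.0 - q2bar)[usable].sum()
    return float(num / den)


def hp_windows(
    counts: PoolCounts, pool: int | str, spec: WindowSpec | None = None
) -> pd.DataFrame:
    """Sliding-window pooled heterozygosity Hp for one pool.

    Major/minor read counts are summed across the window (missing SNPs
    contribute 0, 0); ``Hp = 2*S_maj*S_min/(S_maj+S_min)^2`` lies in [0, 0.5].
    """
    spec = spec or WindowSpec()
    n_maj, n_min = major_minor_counts(counts, pool)
    rows = []
    n_dropped = 0
    for c in pd.unique(counts.chrom):
        idx = np.flatnonzero(counts.chrom == c)
        pos_c = counts.pos[idx]
        maj_c = np.concatenate([[0], np.cumsum(n_maj[idx])])
        min_c = np.concatenate([[0], np.cumsum(n_min[idx])])
        for s in spec.starts(len(idx)):
            e = s + spec.window_snps
            s_maj = float(maj_c[e] - maj_c[s])
            s_min = float(min_c[e] - min_c[s])
            tot = s_maj + s_min
            if tot == 0:
                n_dropped += 1
                continue
            start_pos, end_pos = int(pos_c[s]), int(pos_c[e - 1])
            rows.append(
                {
                    "chrom": c,
                    "start_pos": start_pos,
                    "end_pos": end_pos,
                    "mid_pos": (start_pos + end_pos) // 2,
                    "n_snps": spec.window_snps,
                    "stat": "hp",
                    "value": 2.0 * s_maj * s_min / tot**2,
                }
            )
    if n_dropped:
        logger.warning("hp_windows: dropped %d zero-read windows", n_dropped)
    if not rows:
        raise ValueError("no complete window on any chromosome")
    return pd.DataFrame(rows)


def zhp_transform(track: pd.DataFrame) -> pd.DataFrame:
    """Z-transform an Hp track genome-wide: ZHp = (Hp - mean) / sample SD.

    Mean and SD are computed over all retained windows jointly across
    chromosomes (SD with n-1 denominator).
    """
    if len(track) < 2:
        raise ValueError("need at least 2 windows to standardize")
    values = track["value"].to_numpy(dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across windows; ZHp undefined")
    out = track.copy()
    out["value"] = (values - values.mean()) / sd
    out["stat"] = "zhp"
    return out


def write_track(track: pd.DataFrame, path: str) -> None:
    """Window track as TSV: chrom, start, end, mid, n_snps, stat, value."""
    track.rename(
        columns={"start_pos": "start", "end_pos": "end", "mid_pos": "mid"}
    ).to_csv(path, sep="\t", index=False)


def read_track(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.rename(columns={"start": "start_pos", "end": "end_pos", "mid": "mid_pos"})
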