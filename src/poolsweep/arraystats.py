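"""SNP-array genotype QC, diversity statistics and PCA.

Covers the individual-genotype side of the study design: Hardy–Weinberg
exact testing, the standard array QC cascade (sample call rate, per-population
MAF / missingness / HWE, duplicate removal by IBS, SNP intersection across
populations), per-individual inbreeding coefficients F from observed vs
expected homozygosity (with the small-sample 2n/(2n-1) correction used by the
usual tooling), and genotype / pool-frequency PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "ArrayQcConfig",
    "hwe_exact_test",
    "apply_array_qc",
    "het_and_f",
    "genotype_pca",
    "pool_frequency_pca",
    "ibs_identity_matrix",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alt-allele dosage calls over {0, 1, 2, -1=missing}."""

    calls: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.calls.shape
        if len(self.individual_ids) != n or len(self.populations) != n:
            raise ValueError("individual metadata does not match call matrix")
        if len(self.snp_ids) != m or len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("SNP metadata does not match call matrix")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypeMatrix":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else ind_mask
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            calls=self.calls[np.ix_(ind_mask, snp_mask)],
            individual_ids=[x for x, k in zip(self.individual_ids, ind_mask) if k],
            snp_ids=[x for x, k in zip(self.snp_ids, snp_mask) if k],
            chrom=self.chrom[snp_mask],
            pos=self.pos[snp_mask],
            populations=[x for x, k in zip(self.populations, ind_mask) if k],
        )


@dataclass(frozen=True)
class ArrayQcConfig:
    min_maf: float = 0.01
    max_snp_missing: float = 0.10
    hwe_alpha: float = 1e-6
    min_sample_call_rate: float = 0.95
    max_ibs_identity: float = 0.99

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_snp_missing", "hwe_alpha",
                     "min_sample_call_rate", "max_ibs_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the sample size n and the minor-allele count; the
    probability of a table with ``h`` heterozygotes is proportional to
    ``2**h * n! / (n_AA! h! n_aa!)``.  The p-value sums the probabilities of
    all tables no more probable than the observed one.  Monomorphic SNPs
    return 1.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype counts")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty table")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    h_max = min(rare, 2 * n - rare)
    hets = np.arange(rare % 2, h_max + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logw = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _snp_stats(calls: np.ndarray):
    """Per-SNP (freq, missing fraction, genotype counts) from a call block."""
    miss = calls == MISSING
    n_obs = (~miss).sum(axis=0)
    n0 = ((calls == 0)).sum(axis=0)
    n1 = ((calls == 1)).sum(axis=0)
    n2 = ((calls == 2)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, (n1 + 2 * n2) / (2 * n_obs), np.nan)
    return freq, miss.mean(axis=0), n0, n1, n2, n_obs


def ibs_identity_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise identity-by-state fraction over SNPs non-missing in both.

    IBS per SNP is ``1 - |g_i - g_j| / 2``; duplicated samples score 1.
    """
    n = calls.shape[0]
    out = np.ones((n, n))
    valid = calls != MISSING
    g = calls.astype(np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if not both.any():
                out[i, j] = out[j, i] = 0.0
                continue
            ibs = 1.0 - np.abs(g[i, both] - g[j, both]) / 2.0
            out[i, j] = out[j, i] = ibs.mean()
    return out


def apply_array_qc(
    g: GenotypeMatrix, cfg: ArrayQcConfig | None = None, per_population: bool = True
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Array QC cascade; returns the filtered matrix and a removal report.

    Order: (1) drop individuals with call rate < ``min_sample_call_rate``;
    (2) within each population, fail SNPs on MAF, missingness or HWE;
    (3) drop one of each individual pair with IBS identity >
    ``max_ibs_identity`` (first by id order kept); (4) retain the SNP
    intersection across populations.
    """
    cfg = cfg or ArrayQcConfig()
    call_rate = (g.calls != MISSING).mean(axis=1)
    keep_ind = call_rate >= cfg.min_sample_call_rate
    removed_call_rate = int((~keep_ind).sum())
    g1 = g.subset(ind_mask=keep_ind)
    if g1.n_individuals == 0:
        raise ValueError("all individuals removed by call-rate filter")

    pop_arr = np.array(g1.populations, dtype=object)
    fail_maf = np.zeros(g1.n_snps, bool)
    fail_miss = np.zeros(g1.n_snps, bool)
    fail_hwe = np.zeros(g1.n_snps, bool)
    blocks = (
        [(p, g1.calls[pop_arr == p]) for p in sorted(set(g1.populations))]
        if per_population
        else [("all", g1.calls)]
    )
    for pname, block in blocks:
        if block.shape[0] == 0:
            raise ValueError(f"empty population {pname!r} after sample QC")
        freq, missing, n0, n1, n2, n_obs = _snp_stats(block)
        with np.errstate(invalid="ignore"):
            maf = np.fmin(freq, 1 - freq)
        fail_maf |= np.isnan(maf) | (maf < cfg.min_maf)
        fail_miss |= missing > cfg.max_snp_missing
        for j in np.flatnonzero(n_obs > 0):
            if not (fail_maf[j] or fail_miss[j]):
                if hwe_exact_test(n0[j], n1[j], n2[j]) < cfg.hwe_alpha:
                    fail_hwe[j] = True
    keep_snp = ~(fail_maf | fail_miss | fail_hwe)
    g2 = g1.subset(snp_mask=keep_snp)
    if g2.n_snps == 0:
        raise ValueError("all SNPs removed by QC")

    ibs = ibs_identity_matrix(g2.calls)
    drop = np.zeros(g2.n_individuals, bool)
    order = np.argsort(np.array(g2.individual_ids, dtype=object))
    rank = {int(k): r for r, k in enumerate(order)}
    for i in range(g2.n_individuals):
        for j in range(i + 1, g2.n_individuals):
            if ibs[i, j] > cfg.max_ibs_identity and not (drop[i] or drop[j]):
                drop[j if rank[i] < rank[j] else i] = True
    removed_ibs = int(drop.sum())
    g3 = g2.subset(ind_mask=~drop)

    report = {
        "individuals_in": g.n_individuals,
        "removed_call_rate": removed_call_rate,
        "removed_ibs": removed_ibs,
        "individuals_out": g3.n_individuals,
        "snps_in": g.n_snps,
        "removed_maf": int(fail_maf.sum()),
        "removed_missingness": int((fail_miss & ~fail_maf).sum()),
        "removed_hwe": int((fail_hwe & ~fail_maf & ~fail_miss).sum()),
        "snps_out": g3.n_snps,
    }
    logger.info("apply_array_qc: %s", report)
    return g3, report


def het_and_f(g: GenotypeMatrix, population: str | None = None):
    """Per-individual homozygosity/F and population heterozygosity means.

    Per SNP j with allele frequency p_j from the n_j non-missing calls, the
    expected homozygosity contribution is ``1 - 2 p_j (1-p_j) * 2n_j/(2n_j-1)``
    (small-sample corrected).  Per individual over its L non-missing SNPs::

        F = (obs_hom - exp_hom) / (L - exp_hom)

    The population observed/expected heterozygosities are means over SNPs of
    the observed heterozygote fraction and the corrected 2pq.
    Returns ``(per_individual DataFrame, summary dict)``.
    """
    if population is not None:
        mask = np.array([p == population for p in g.populations])
        if not mask.any():
            raise ValueError(f"no individuals in population {population!r}")
        g = g.subset(ind_mask=mask)
    if g.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    calls = g.calls
    valid = calls != MISSING
    freq, _, n0, n1, n2, n_obs = _snp_stats(calls)
    usable = n_obs > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = 2.0 * n_obs / (2.0 * n_obs - 1.0)
        exp_het_snp = 2.0 * freq * (1.0 - freq) * corr
    exp_het_snp = np.where(usable, exp_het_snp, np.nan)

    v = valid & usable[None, :]
    obs_hom = ((calls == 0) | (calls == 2))[:, :] & v
    obs_hom_n = obs_hom.sum(axis=1).astype(float)
    L = v.sum(axis=1).astype(float)
    exp_hom_n = np.where(v, 1.0 - np.nan_to_num(exp_het_snp)[None, :], 0.0).sum(axis=1)
    denom = L - exp_hom_n
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hat = np.where(denom != 0, (obs_hom_n - exp_hom_n) / denom, np.nan)

    per_ind = pd.DataFrame(
        {
            "individual": g.individual_ids,
            "population": g.populations,
            "obs_hom": obs_hom_n,
            "exp_hom": exp_hom_n,
            "n_snps": L.astype(int),
            "F": f_hat,
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_het_snp = np.where(n_obs > 0, n1 / n_obs, np.nan)
    summary = {
        "obs_het": float(np.nanmean(np.where(usable, obs_het_snp, np.nan))),
        "exp_het": float(np.nanmean(exp_het_snp)),
        "F_mean": float(np.nanmean(f_hat)),
    }
    return per_ind, summary


def genotype_pca(g: GenotypeMatrix, n_components: int = 10):
    """PCA of the genotype matrix with HWE-variance scaling.

    Missing calls are mean-imputed per SNP; each SNP is centered by 2p and
    scaled by sqrt(2p(1-p)).  Returns (coordinates n_ind x k, variance
    fractions over the full spectrum).
    """
    calls = g.calls.astype(float)
    calls[g.calls == MISSING] = np.nan
    mean = np.nanmean(calls, axis=0)
    if np.isnan(mean).any():
        raise ValueError("SNP with all calls missing")
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0
    x = (calls[:, keep] - mean[keep]) / scale[keep]
    u, s, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(n_components, len(s))
    if k < n_components:
        logger.warning("genotype_pca: truncated to rank %d", k)
    return u[:, :k] * s[:k], frac[:k]


def pooled_maf_mask(counts, maf_min: float = 0.40) -> np.ndarray:
    """SNPs whose minor-allele frequency over pooled read totals exceeds ``maf_min``."""
    total_alt = counts.alt_reads.sum(axis=1)
    total = counts.depth().sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(total > 0, total_alt / total, np.nan)
    maf = np.fmin(pooled, 1 - pooled)
    return maf > maf_min


def pool_frequency_pca(counts, maf_min: float = 0.40, n_components: int = 5):
    """PCA of pools on their read-frequency matrix at highly polymorphic SNPs.

    SNPs are kept when the pooled (read-total) MAF exceeds ``maf_min``; the
    pool x SNP frequency matrix is centered per SNP.  A simple stand-in for
    covariance-model approaches: it recovers broad pool structure only.
    """
    if counts.n_pools < 3:
        raise ValueError("pool_frequency_pca requires >= 3 pools")
    keep = pooled_maf_mask(counts, maf_min)
    if not keep.any():
        raise ValueError("no SNPs pass the pooled MAF filter")
    freq = counts.alt_frequency()[keep].T  # pools x snps
    col_mean = np.nanmean(freq, axis=0)
    inds = np.where(np.isnan(freq))
    freq[inds] = np.take(col_mean, inds[1])
    x = freq - freq.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    k = min(n_components, len(s))
    return u[:, :k] * s[:k], frac[:k]
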