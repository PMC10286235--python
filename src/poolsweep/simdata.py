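"""Synthetic pooled-count, haplotype and genotype data with known truth.

The downstream scans are validated on data whose generative parameters are
known exactly:

* pooled read counts under a Balding–Nichols differentiation model whose
  single parameter ``fst_target`` equals the expected FST, with two-stage
  sampling (chromosomes drawn binomially from the population, reads drawn
  binomially from the pool sample) at Poisson depth, and optional injected
  high-differentiation ("sweep") and monomorphic ("low-het") spans;
* phased haplotype panels carrying a partial hard sweep: a fraction of
  haplotypes are decayed copies of one founder around a core site, the rest
  are neutral background;
* individual 0/1/2 genotype matrices with a controllable inbreeding
  coefficient F and missing-call rate.

All draws flow from a single seed; identical parameters and seed reproduce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arraystats import GenotypeMatrix
from .hapscan import HaplotypePanel
from .poolio import PoolCounts

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_pools",
    "simulate_sweep_haplotypes",
    "simulate_neutral_haplotypes",
    "simulate_genotypes",
    "write_truth",
]

# mean inter-SNP spacing (bp); ~10 SNPs per kb so a 625-SNP window spans ~100 kb
_MEAN_SPACING = 100


@dataclass(frozen=True)
class SimParams:
    """Parameters of the pooled-count simulation.

    ``sweep_regions`` is a list of ``(pool_index, (start_snp, stop_snp), freq)``
    tuples (stop exclusive): the named pool's population allele frequency is
    overwritten by ``freq`` over the span, emulating a (near-)fixed sweep that
    differentiates it from the other pools.  ``low_het_regions`` is a list of
    ``(pool_index, (start_snp, stop_snp))``: the pool's sampled frequency is
    rounded to 0 or 1 over the span, removing within-pool heterozygosity.
    """

    n_pools: int = 2
    pool_haploid_sizes: int | tuple[int, ...] = 100
    n_snps: int = 20_000
    mean_depth: float = 95.0
    fst_target: float = 0.10
    sweep_regions: tuple = ()
    low_het_regions: tuple = ()
    ancestral_freq_dist: tuple[float, float] = (0.8, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_target <= 0.99:
            raise ValueError("fst_target must be in [0, 0.99]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_pools < 1 or self.n_snps < 1:
            raise ValueError("n_pools and n_snps must be positive")
        sizes = self.sizes()
        if (sizes < 2).any():
            raise ValueError("pool_haploid_sizes must be >= 2")
        for region in list(self.sweep_regions) + list(self.low_het_regions):
            pool, span = region[0], region[1]
            if not 0 <= pool < self.n_pools:
                raise ValueError(f"region pool index {pool} out of range")
            if not (0 <= span[0] <= span[1] <= self.n_snps):
                raise ValueError(f"region span {span} outside [0, n_snps)")

    def sizes(self) -> np.ndarray:
        if np.isscalar(self.pool_haploid_sizes):
            return np.full(self.n_pools, int(self.pool_haploid_sizes), dtype=np.int64)
        return np.asarray(self.pool_haploid_sizes, dtype=np.int64)


@dataclass
class SimTruth:
    """Generative truth accompanying a simulated :class:`~poolsweep.poolio.PoolCounts`."""

    pool_freqs: np.ndarray  # population allele frequency, snp x pool
    sweep_regions: tuple
    low_het_regions: tuple
    fst_per_snp: np.ndarray = field(default=None)  # type: ignore[assignment]


def _population_fst(pool_freqs: np.ndarray) -> np.ndarray:
    """Analytic per-SNP FST = (Q1-Q2)/(1-Q2) of the drawn population frequencies."""
    p = pool_freqs
    q1 = np.mean(p**2 + (1 - p) ** 2, axis=1)
    k = p.shape[1]
    s1, s1c = p.sum(axis=1), (1 - p).sum(axis=1)
    # mean over unordered pairs of p_i p_j + (1-p_i)(1-p_j)
    cross = (s1**2 - (p**2).sum(axis=1) + s1c**2 - ((1 - p) ** 2).sum(axis=1)) / 2
    q2 = cross / (k * (k - 1) / 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(1 - q2 > 0, (q1 - q2) / (1 - q2), np.nan)


def simulate_pools(params: SimParams) -> tuple[PoolCounts, SimTruth]:
    """Draw pooled read counts under the Balding–Nichols model.

    Per SNP: ancestral frequency ``p ~ Beta(ancestral_freq_dist)``; each pool's
    population frequency ``pi ~ Beta(p(1-c)/c, (1-p)(1-c)/c)`` with
    ``c = fst_target`` (c = 0 collapses to ``pi = p``); pool allele counts
    ``~ Binomial(n_i, pi)``; depth ``~ Poisson(mean_depth)``; alt reads
    ``~ Binomial(depth, within-pool sample frequency)``.
    """
    rng = np.random.default_rng(params.seed)
    S, K = params.n_snps, params.n_pools
    sizes = params.sizes()
    a, b = params.ancestral_freq_dist
    c = params.fst_target

    anc = rng.beta(a, b, size=S)
    # keep Beta shape parameters finite and the spectrum away from fixation
    anc = np.clip(anc, 1e-4, 1 - 1e-4)
    if c == 0.0:
        pool_freqs = np.repeat(anc[:, None], K, axis=1)
    else:
        shape1 = anc * (1 - c) / c
        shape2 = (1 - anc) * (1 - c) / c
        pool_freqs = rng.beta(shape1[:, None], shape2[:, None], size=(S, K))

    for pool, span, freq in params.sweep_regions:
        pool_freqs[span[0] : span[1], pool] = freq

    chrom_alt = rng.binomial(sizes[None, :], pool_freqs)
    sample_freq = chrom_alt / sizes[None, :]
    for pool, span in params.low_het_regions:
        sl = slice(span[0], span[1])
        sample_freq[sl, pool] = np.where(sample_freq[sl, pool] >= 0.5, 1.0, 0.0)

    depth = rng.poisson(params.mean_depth, size=(S, K))
    alt_reads = rng.binomial(depth, sample_freq)
    ref_reads = depth - alt_reads

    pos = np.cumsum(1 + rng.poisson(_MEAN_SPACING - 1, size=S))
    ref_base = rng.choice(np.array(["A", "C", "G", "T"], dtype=object), size=S)
    alt_base = np.where(ref_base == "A", "G", "A").astype(object)

    counts = PoolCounts(
        chrom=np.full(S, "1", dtype=object),
        pos=pos,
        ref_allele=ref_base,
        alt_allele=alt_base,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
        pool_names=[f"pool{i}" for i in range(K)],
        pool_haploid_sizes=sizes,
    )
    truth = SimTruth(
        pool_freqs=pool_freqs,
        sweep_regions=tuple(params.sweep_regions),
        low_het_regions=tuple(params.low_het_regions),
        fst_per_snp=_population_fst(pool_freqs),
    )
    return counts, truth


def simulate_sweep_haplotypes(
    n_haplotypes: int,
    n_markers: int,
    sweep_core: int,
    sweep_freq: float,
    decay_bp: float,
    positions: np.ndarray | None = None,
    seed: int = 0,
    chrom: str = "1",
) -> HaplotypePanel:
    """Phased panel containing a partial hard sweep around ``sweep_core``.

    A fraction ``sweep_freq`` of haplotypes carry the derived allele at the
    core and are copies of a single founder; each copied site is independently
    reverted to a random allele with probability ``1 - exp(-|pos - core_pos| /
    decay_bp)``, so haplotype homozygosity among carriers decays with physical
    distance.  Remaining haplotypes carry independent alleles at frequency 0.5
    per marker, with the ancestral allele at the core.  Allele 1 is derived
    everywhere (the founder carries the derived core allele by construction).
    """
    if not 0.0 < sweep_freq < 1.0:
        raise ValueError("sweep_freq must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = np.cumsum(
            1 + rng.poisson(_MEAN_SPACING - 1, size=n_markers)
        ).astype(np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        if len(positions) != n_markers or (np.diff(positions) <= 0).any():
            raise ValueError("positions must be strictly increasing, length n_markers")
    if not 0 <= sweep_core < n_markers:
        raise ValueError("sweep_core out of range")

    n_sweep = int(round(sweep_freq * n_haplotypes))
    n_sweep = max(1, min(n_haplotypes - 1, n_sweep))

    alleles = (rng.random((n_markers, n_haplotypes)) < 0.5).astype(np.int8)
    founder = (rng.random(n_markers) < 0.5).astype(np.int8)
    founder[sweep_core] = 1

    dist = np.abs(positions - positions[sweep_core]).astype(float)
    if np.isinf(decay_bp):
        p_revert = np.zeros(n_markers)
    else:
        p_revert = 1.0 - np.exp(-dist / float(decay_bp))
    revert = rng.random((n_markers, n_sweep)) < p_revert[:, None]
    fresh = (rng.random((n_markers, n_sweep)) < 0.5).astype(np.int8)
    sweep_block = np.where(revert, fresh, founder[:, None]).astype(np.int8)
    sweep_block[sweep_core, :] = 1

    alleles[:, :n_sweep] = sweep_block
    alleles[sweep_core, n_sweep:] = 0  # non-carriers are ancestral at the core

    return HaplotypePanel(
        alleles=alleles,
        positions=positions,
        marker_ids=[f"m{i}" for i in range(n_markers)],
        chrom=chrom,
    )


def simulate_neutral_haplotypes(
    n_haplotypes: int,
    n_markers: int,
    positions: np.ndarray | None = None,
    n_founders: int | None = 20,
    switch_bp: float = 25_000.0,
    derived_freq: float = 0.5,
    seed: int = 0,
    chrom: str = "1",
) -> HaplotypePanel:
    """Sweep-free panel with realistic haplotype-block structure.

    Each haplotype is a recombinant mosaic of ``n_founders`` founder
    haplotypes (founder alleles i.i.d. at ``derived_freq`` per marker),
    switching founder between adjacent markers with probability
    ``1 - exp(-gap_bp / switch_bp)``.  The mosaic produces the smooth
    multi-marker EHH decay that haplotype statistics presuppose; pass
    ``n_founders=None`` for fully independent alleles (no linkage at all, a
    degenerate regime useful only for small closed-form checks).
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = np.cumsum(
            1 + rng.poisson(_MEAN_SPACING - 1, size=n_markers)
        ).astype(np.int64)
    positions = np.asarray(positions, dtype=np.int64)
    if n_founders is None:
        alleles = (rng.random((n_markers, n_haplotypes)) < derived_freq).astype(np.int8)
    else:
        founders = (rng.random((n_markers, n_founders)) < derived_freq).astype(np.int8)
        p_switch = 1.0 - np.exp(-np.diff(positions).astype(float) / switch_bp)
        src = np.empty((n_markers, n_haplotypes), dtype=np.int64)
        src[0] = rng.integers(0, n_founders, n_haplotypes)
        switch = rng.random((n_markers - 1, n_haplotypes)) < p_switch[:, None]
        fresh = rng.integers(0, n_founders, (n_markers - 1, n_haplotypes))
        for m in range(1, n_markers):
            src[m] = np.where(switch[m - 1], fresh[m - 1], src[m - 1])
        alleles = founders[np.arange(n_markers)[:, None], src]
    return HaplotypePanel(
        alleles=alleles,
        positions=positions,
        marker_ids=[f"m{i}" for i in range(n_markers)],
        chrom=chrom,
    )


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_dist: tuple[float, float] = (0.8, 0.8),
    missing_rate: float = 0.0,
    inbreeding_f: float = 0.0,
    seed: int = 0,
    population: str = "pop1",
) -> GenotypeMatrix:
    """Individual 0/1/2 genotypes with inbreeding coefficient F.

    Per SNP with allele frequency p (drawn Beta(``maf_dist``)), genotype
    probabilities are (q^2 + Fpq, 2pq(1-F), p^2 + Fpq) for 0/1/2 alt copies;
    missing calls (-1) are inserted uniformly at ``missing_rate``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.clip(rng.beta(*maf_dist, size=n_snps), 0.01, 0.99)
    q = 1 - p
    f = float(inbreeding_f)
    f_min = -np.minimum(p / q, q / p)
    if (f < f_min).any():
        raise ValueError("inbreeding_f yields negative genotype probabilities")
    probs = np.stack(
        [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q], axis=1
    )
    u = rng.random((n_individuals, n_snps))
    cum = np.cumsum(probs, axis=1)  # snp x 3
    calls = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(
            rng.random((n_individuals, n_snps)) < missing_rate, -1, calls
        ).astype(np.int8)
    return GenotypeMatrix(
        calls=calls,
        individual_ids=[f"ind{i}" for i in range(n_individuals)],
        snp_ids=[f"snp{j}" for j in range(n_snps)],
        chrom=np.full(n_snps, "1", dtype=object),
        pos=np.arange(1, n_snps + 1, dtype=np.int64) * 1000,
        populations=[population] * n_individuals,
    )


def write_truth(truth: SimTruth, counts: PoolCounts, tsv_path: str, bed_path: str) -> None:
    """Write per-SNP truth as TSV and injected spans as BED (0-based half-open)."""
    import pandas as pd

    df = pd.DataFrame({"chrom": counts.chrom, "pos": counts.pos})
    for j in range(truth.pool_freqs.shape[1]):
        df[f"freq_{counts.pool_names[j]}"] = truth.pool_freqs[:, j]
    df["fst_true"] = truth.fst_per_snp
    df.to_csv(tsv_path, sep="\t", index=False)

    with open(bed_path, "w") as fh:
        for region in truth.sweep_regions:
            pool, span = region[0], region[1]
            lo, hi = counts.pos[span[0]], counts.pos[span[1] - 1]
            fh.write(f"{counts.chrom[span[0]]}\t{lo - 1}\t{hi}\tsweep_pool{pool}\n")
        for pool, span in truth.low_het_regions:
            lo, hi = counts.pos[span[0]], counts.pos[span[1] - 1]
            fh.write(f"{counts.chrom[span[0]]}\t{lo - 1}\t{hi}\tlowhet_pool{pool}\n")


def write_hap_map(panel: HaplotypePanel, hap_path: str, map_path: str) -> None:
    """IMPUTE-style .hap (marker rows of 0/1) and .map (id, chrom, pos) pair."""
    np.savetxt(hap_path, panel.alleles, fmt="%d")
    with open(map_path, "w") as fh:
        for mid, pos in zip(panel.marker_ids, panel.positions):
            fh.write(f"{mid}\t{panel.chrom}\t{pos}\n")


def read_hap_map(hap_path: str, map_path: str) -> HaplotypePanel:
    import pandas as pd

    alleles = np.loadtxt(hap_path, dtype=np.int8, ndmin=2)
    m = pd.read_csv(map_path, sep="\t", header=None, names=["id", "chrom", "pos"])
    return HaplotypePanel(
        alleles=alleles,
        positions=m["pos"].to_numpy(np.int64),
        marker_ids=m["id"].astype(str).tolist(),
        chrom=str(m["chrom"].iloc[0]),
    )


def write_genotype_vcf(g: GenotypeMatrix, path: str) -> None:
    """Minimal VCF with GT per individual (./. for missing)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j in range(g.n_snps):
            row = [gt_map[int(v)] for v in g.calls[:, j]]
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(row)
                + "\n"
            )
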