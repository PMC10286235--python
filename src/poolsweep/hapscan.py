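"""Haplotype-based selection statistics: EHH, iHS and XP-EHH.

Extended haplotype homozygosity (EHH) at distance s from a core marker is the
probability that two haplotypes drawn without replacement from a carrier
class are identical at every marker from the core out to s.  Integrating the
EHH curve over physical distance gives iHH (per core-allele class) and iES
(over all haplotypes).  Within one population,

    iHS = [ln(iHH_A/iHH_D) - E_p(ln(iHH_A/iHH_D))] / SD_p(ln(iHH_A/iHH_D))

standardized within derived-allele-frequency bins; between two populations,

    XP-EHH = [ln(iES_1/iES_2) - mean(unXP-EHH)] / SD(unXP-EHH)

standardized genome-wide.  Standardized scores are mapped to
-log10(2 * Phi(-|score|)) with Phi the Gaussian CDF; markers with
-log10 p >= 4 are flagged as outliers.

Distances are physical bp (no genetic map); the EHH estimator uses the
unbiased pair form sum n_h(n_h-1) / (n_c(n_c-1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "EhhCurve",
    "ehh_at",
    "integrate_ihh",
    "ihs_scan",
    "xpehh_scan",
    "call_marker_outliers",
    "neg_log10_two_sided",
]

DEFAULT_CUTOFF = 0.05
OUTLIER_THRESHOLD = 4.0
MIN_BIN_MARKERS = 10


@dataclass
class HaplotypePanel:
    """Phased, complete marker x haplotype 0/1 panel (1 = derived allele)."""

    alleles: np.ndarray  # (n_markers, n_haplotypes), int8 over {0,1}
    positions: np.ndarray  # bp, strictly increasing
    marker_ids: list[str]
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (marker x haplotype)")
        if self.alleles.shape[0] != len(self.positions):
            raise ValueError("positions length != number of markers")
        if self.alleles.shape[0] < 3:
            raise ValueError("need >= 3 markers")
        if self.alleles.shape[1] < 4:
            raise ValueError("need >= 4 haplotypes")
        if ((self.alleles != 0) & (self.alleles != 1)).any():
            raise ValueError("alleles must be 0/1 (no missing calls)")
        if (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    def derived_frequency(self) -> np.ndarray:
        return self.alleles.mean(axis=1)


@dataclass
class EhhCurve:
    """EHH decay on both sides of a core marker.

    ``left``/``right`` hold (distance_bp, ehh) arrays at increasing distance
    from the core, truncated at the first marker where EHH falls below the
    walk cutoff (0 for full curves; values beyond a 0 are identically 0).
    ``core_ehh`` is 1 for single-allele classes and the core-site
    homozygosity for the "all" class.
    """

    core: int
    allele_class: str
    core_ehh: float
    left: tuple[np.ndarray, np.ndarray]
    right: tuple[np.ndarray, np.ndarray]


@njit(cache=True)
def _compress(group, counts, denom):
    """Relabel group keys to 0..g-1 in place; return homozygosity sum/denom."""
    n_c = group.shape[0]
    maxkey = 0
    for k in range(n_c):
        if group[k] > maxkey:
            maxkey = group[k]
        counts[group[k]] += 1
    s = 0.0
    nid = 0
    for key in range(maxkey + 1):
        c = counts[key]
        if c > 0:
            s += c * (c - 1.0)
            counts[key] = nid
            nid += 1
    for k in range(n_c):
        group[k] = counts[group[k]]
    for key in range(maxkey + 1):
        counts[key] = 0
    return s / denom


@njit(cache=True)
def _ehh_side(alleles, core, carriers, step, cutoff):
    """Walk outward from the core in direction ``step`` (+1/-1).

    Returns (marker_indices, ehh_values, n_filled, core_ehh).  The walk
    records each marker's EHH and stops after the first value < cutoff or
    == 0, or at the chromosome end.
    """
    n_c = carriers.shape[0]
    n_markers = alleles.shape[0]
    denom = n_c * (n_c - 1.0)
    group = np.empty(n_c, np.int64)
    counts = np.zeros(2 * n_c + 2, np.int64)
    for k in range(n_c):
        group[k] = alleles[core, carriers[k]]
    core_ehh = _compress(group, counts, denom)
    out_idx = np.empty(n_markers, np.int64)
    out_ehh = np.empty(n_markers, np.float64)
    cnt = 0
    ehh = core_ehh
    m = core + step
    while 0 <= m < n_markers and ehh >= cutoff and ehh > 0.0:
        for k in range(n_c):
            group[k] = group[k] * 2 + alleles[m, carriers[k]]
        ehh = _compress(group, counts, denom)
        out_idx[cnt] = m
        out_ehh[cnt] = ehh
        cnt += 1
        m += step
    return out_idx, out_ehh, cnt, core_ehh


def _carriers(panel: HaplotypePanel, core: int, allele_class: str) -> np.ndarray:
    if allele_class == "all":
        return np.arange(panel.n_haplotypes, dtype=np.int64)
    if allele_class == "derived":
        return np.flatnonzero(panel.alleles[core] == 1).astype(np.int64)
    if allele_class == "ancestral":
        return np.flatnonzero(panel.alleles[core] == 0).astype(np.int64)
    raise ValueError(f"unknown allele_class {allele_class!r}")


def ehh_at(
    panel: HaplotypePanel,
    core: int,
    allele_class: str = "all",
    cutoff: float = 0.0,
) -> EhhCurve:
    """EHH decay curve on both sides of ``core`` for one carrier class.

    Requires >= 2 carriers of the class; raises ``ValueError`` otherwise
    (the marker is excluded from scans).
    """
    carriers = _carriers(panel, core, allele_class)
    if len(carriers) < 2:
        raise ValueError(
            f"allele class {allele_class!r} has <2 carriers at marker {core}"
        )
    pos = panel.positions
    sides = []
    core_ehh = 1.0
    for step in (-1, +1):
        idx, ehh, cnt, core_ehh = _ehh_side(
            panel.alleles, core, carriers, step, cutoff
        )
        d = np.abs(pos[idx[:cnt]] - pos[core]).astype(np.int64)
        sides.append((d, ehh[:cnt].copy()))
    return EhhCurve(
        core=core,
        allele_class=allele_class,
        core_ehh=float(core_ehh),
        left=sides[0],
        right=sides[1],
    )


def _integrate_side(
    dists: np.ndarray, ehhs: np.ndarray, core_ehh: float, cutoff: float
) -> float:
    """Trapezoid integral of one side from distance 0, truncated at cutoff."""
    if core_ehh < cutoff:
        return 0.0
    area = 0.0
    d0, v0 = 0.0, core_ehh
    for d1, v1 in zip(dists, ehhs):
        if v1 < cutoff:
            # linear interpolation to the cutoff crossing
            frac = (v0 - cutoff) / (v0 - v1)
            d_star = d0 + frac * (d1 - d0)
            area += 0.5 * (v0 + cutoff) * (d_star - d0)
            return area
        area += 0.5 * (v0 + v1) * (d1 - d0)
        d0, v0 = d1, v1
    return area


def integrate_ihh(curve: EhhCurve, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Integrated EHH (bp): trapezoid over both sides, truncated at ``cutoff``.

    The core contributes its own EHH value at distance 0 (1 for allele-class
    curves).  Returns 0 when the curve never rises above the cutoff.
    """
    return _integrate_side(*curve.left, curve.core_ehh, cutoff) + _integrate_side(
        *curve.right, curve.core_ehh, cutoff
    )


def _ihh_both_sides(
    panel: HaplotypePanel, core: int, carriers: np.ndarray, cutoff: float
) -> float:
    """iHH for one carrier set, walking each side only down to the cutoff."""
    pos = panel.positions
    total = 0.0
    for step in (-1, +1):
        idx, ehh, cnt, core_ehh = _ehh_side(panel.alleles, core, carriers, step, cutoff)
        d = np.abs(pos[idx[:cnt]] - pos[core]).astype(float)
        total += _integrate_side(d, ehh[:cnt], core_ehh, cutoff)
    return total


def neg_log10_two_sided(scores: np.ndarray) -> np.ndarray:
    """-log10(2 * Phi(-|score|)) computed in log space (stable far in the tail)."""
    z = np.abs(np.asarray(scores, dtype=float))
    return -(np.log(2.0) + norm.logsf(z)) / np.log(10.0)


def _merge_bins(bin_ids: np.ndarray, min_markers: int = MIN_BIN_MARKERS) -> np.ndarray:
    """Greedily merge sparse frequency bins with their right neighbor.

    Returns a relabeling of ``bin_ids`` such that every output group holds at
    least ``min_markers`` markers (the trailing remainder joins the last
    group).  Merges are logged.
    """
    out = np.empty_like(bin_ids)
    order = np.unique(bin_ids)
    group, size, n_groups, merged = {}, 0, 0, 0
    for b in order:
        nb = int((bin_ids == b).sum())
        group[b] = n_groups
        size += nb
        if size >= min_markers:
            n_groups += 1
            size = 0
        else:
            merged += 1
    if size > 0 and n_groups > 0:  # leftover markers fold into the last group
        for b in order:
            if group[b] == n_groups:
                group[b] = n_groups - 1
    if merged:
        logger.info("standardization: merged %d sparse frequency bins", merged)
    for b in order:
        out[bin_ids == b] = group[b]
    return out


def ihs_scan(
    panel: HaplotypePanel,
    min_freq: float = 0.05,
    bin_width: float = 0.025,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Standardized iHS per marker with the -log10 p transform.

    Markers with derived frequency outside [min_freq, 1-min_freq] are not
    scored; markers where either class's iHH is 0 are dropped with a warning.
    Standardization (mean/SD of ln(iHH_A/iHH_D)) is within derived-frequency
    bins of width ``bin_width``; bins with <10 markers merge with a neighbor.
    """
    freq = panel.derived_frequency()
    rows = []
    n_zero = 0
    for m in range(panel.n_markers):
        p = freq[m]
        if not (min_freq <= p <= 1.0 - min_freq):
            continue
        anc = np.flatnonzero(panel.alleles[m] == 0).astype(np.int64)
        der = np.flatnonzero(panel.alleles[m] == 1).astype(np.int64)
        if len(anc) < 2 or len(der) < 2:
            continue
        ihh_a = _ihh_both_sides(panel, m, anc, cutoff)
        ihh_d = _ihh_both_sides(panel, m, der, cutoff)
        if ihh_a == 0.0 or ihh_d == 0.0:
            n_zero += 1
            continue
        rows.append((m, p, ihh_a, ihh_d, np.log(ihh_a / ihh_d)))
    if n_zero:
        logger.warning("ihs_scan: dropped %d markers with zero iHH", n_zero)
    if not rows:
        raise ValueError("no scoreable markers")
    df = pd.DataFrame(rows, columns=["marker", "freq_derived", "ihh_a", "ihh_d", "un_ihs"])
    bins = np.minimum(
        (df["freq_derived"].to_numpy() / bin_width).astype(int),
        int(1.0 / bin_width) - 1,
    )
    df["bin"] = _merge_bins(bins)
    z = np.empty(len(df))
    for _, grp in df.groupby("bin"):
        v = grp["un_ihs"].to_numpy()
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        if sd == 0:
            z[grp.index] = 0.0
        else:
            z[grp.index] = (v - v.mean()) / sd
    df["ihs"] = z
    df["neg_log10_p"] = neg_log10_two_sided(z)
    df.insert(0, "chrom", panel.chrom)
    df.insert(2, "pos", panel.positions[df["marker"].to_numpy()])
    return df.drop(columns="bin")


def xpehh_scan(
    panel_1: HaplotypePanel,
    panel_2: HaplotypePanel,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Standardized XP-EHH per marker between two populations.

    iES per population is the integrated all-haplotype EHH curve; unXP-EHH =
    ln(iES_1/iES_2), standardized by its genome-wide mean and SD.  Markers
    with iES = 0 in either population are dropped with a warning.
    """
    if panel_1.n_markers != panel_2.n_markers or (
        panel_1.positions != panel_2.positions
    ).any():
        raise ValueError("panels must share an identical marker grid")
    all_1 = np.arange(panel_1.n_haplotypes, dtype=np.int64)
    all_2 = np.arange(panel_2.n_haplotypes, dtype=np.int64)
    rows = []
    n_zero = 0
    for m in range(panel_1.n_markers):
        ies_1 = _ihh_both_sides(panel_1, m, all_1, cutoff)
        ies_2 = _ihh_both_sides(panel_2, m, all_2, cutoff)
        if ies_1 == 0.0 or ies_2 == 0.0:
            n_zero += 1
            continue
        rows.append((m, ies_1, ies_2, np.log(ies_1 / ies_2)))
    if n_zero:
        logger.warning("xpehh_scan: dropped %d markers with zero iES", n_zero)
    if not rows:
        raise ValueError("no scoreable markers")
    df = pd.DataFrame(rows, columns=["marker", "ies_1", "ies_2", "un_xpehh"])
    v = df["un_xpehh"].to_numpy()
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of unXP-EHH; cannot standardize")
    df["xpehh"] = (v - v.mean()) / sd
    df["neg_log10_p"] = neg_log10_two_sided(df["xpehh"].to_numpy())
    df.insert(0, "chrom", panel_1.chrom)
    df.insert(2, "pos", panel_1.positions[df["marker"].to_numpy()])
    return df


def call_marker_outliers(
    scores: pd.DataFrame, threshold: float = OUTLIER_THRESHOLD
) -> pd.DataFrame:
    """Markers whose -log10 p is >= ``threshold`` (boundary inclusive)."""
    if len(scores) == 0:
        return scores.copy()
    if not np.isfinite(scores["neg_log10_p"]).all():
        raise ValueError("non-finite scores")
    return scores[scores["neg_log10_p"] >= threshold].copy()
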