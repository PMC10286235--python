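"""From scan tracks to candidate sweep regions, genes and enriched terms.

Outlier windows (extreme 0.1% tail of a statistic's empirical distribution)
contribute their window midpoints as "top positions"; top positions closer
than 100 kb are merged into regions; genes within the region plus a 50-kb
flank are attached from a GFF3 annotation; regions found across multiple
pairwise comparisons, or matching haplotype-scan outlier markers within
50 kb, are reported as shared signals; gene lists are tested for term
enrichment by the upper-tail hypergeometric test with Benjamini–Hochberg
q-values (enriched when q < 0.10 with more than one query gene in the term).

Coordinates are 1-based inclusive throughout (GFF3 convention); BED output
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "GeneModel",
    "call_window_outliers",
    "merge_top_positions",
    "annotate_regions",
    "cross_method_common",
    "shared_across_comparisons",
    "hypergeometric_enrichment",
    "read_gene_models",
    "write_regions_bed",
]

MERGE_GAP = 100_000
FLANK = 50_000
CROSS_METHOD_DIST = 50_000
OUTLIER_FRACTION = 0.001


@dataclass
class Region:
    """A merged run of top positions on one chromosome."""

    chrom: str
    left: int
    right: int
    top_positions: list[int]
    source: str = ""
    comparisons: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("left > right")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def call_window_outliers(
    track: pd.DataFrame, tail: str, fraction: float = OUTLIER_FRACTION
) -> pd.DataFrame:
    """Top positions of the most extreme ``ceil(fraction * n)`` windows.

    ``tail`` is "upper" (differentiation) or "lower" (heterozygosity);
    windows tied with the threshold value are all included.  Returns a frame
    with chrom, mid_pos and value.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    n = len(track)
    if n < 1.0 / fraction:
        warnings.warn(
            f"only {n} windows for outlier fraction {fraction}; "
            "the empirical tail is coarse",
            stacklevel=2,
        )
    k = math.ceil(fraction * n)
    values = track["value"].to_numpy(dtype=float)
    if tail == "upper":
        thresh = np.sort(values)[::-1][k - 1]
        sel = values >= thresh
    elif tail == "lower":
        thresh = np.sort(values)[k - 1]
        sel = values <= thresh
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    if sel.all() and values.min() == values.max():
        warnings.warn("degenerate track: all windows tied at one value", stacklevel=2)
    out = track.loc[sel, ["chrom", "mid_pos", "value"]].copy()
    return out.sort_values(["chrom", "mid_pos"]).reset_index(drop=True)


def merge_top_positions(
    positions: pd.DataFrame, merge_gap: int = MERGE_GAP, source: str = ""
) -> list[Region]:
    """Greedy single-pass merge of top positions into regions.

    A new region starts whenever the gap to the previous position on the same
    chromosome exceeds ``merge_gap`` (a gap exactly equal to it still merges);
    singleton regions are allowed.
    """
    regions: list[Region] = []
    for chrom, grp in positions.groupby("chrom", sort=True):
        pos = np.sort(grp["mid_pos"].to_numpy(dtype=np.int64))
        current = [int(pos[0])]
        for p in pos[1:]:
            if p - current[-1] > merge_gap:
                regions.append(
                    Region(str(chrom), current[0], current[-1], current, source)
                )
                current = [int(p)]
            else:
                current.append(int(p))
        regions.append(Region(str(chrom), current[0], current[-1], current, source))
    return regions


def annotate_regions(
    regions: list[Region], genes: list[GeneModel], flank: int = FLANK
) -> list[Region]:
    """Attach genes overlapping ``[left - flank, right + flank]`` (clipped at 1).

    Interval overlap is strand-agnostic on 1-based inclusive coordinates.
    Regions on chromosomes absent from the annotation get an empty list with
    a warning.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    out = []
    for r in regions:
        lo = max(1, r.left - flank)
        hi = r.right + flank
        if r.chrom not in by_chrom:
            warnings.warn(f"chromosome {r.chrom} absent from annotation", stacklevel=2)
            hits: list[str] = []
        else:
            hits = [
                g.gene_id for g in by_chrom[r.chrom] if g.start <= hi and g.end >= lo
            ]
        out.append(
            Region(r.chrom, r.left, r.right, list(r.top_positions), r.source,
                   list(r.comparisons), hits)
        )
    return out


def cross_method_common(
    window_positions: pd.DataFrame,
    marker_positions: pd.DataFrame,
    max_dist: int = CROSS_METHOD_DIST,
) -> pd.DataFrame:
    """Window-scan / marker-scan signal pairs within ``max_dist`` bp.

    Inputs are frames with chrom + mid_pos (window track top positions) and
    chrom + pos (marker outliers); pairs on the same chromosome with
    ``|mid_pos - pos| <= max_dist`` (boundary inclusive) are common signals.
    """
    rows = []
    for chrom, wg in window_positions.groupby("chrom"):
        mg = marker_positions[marker_positions["chrom"] == chrom]
        if len(mg) == 0:
            continue
        for mid in wg["mid_pos"].to_numpy(dtype=np.int64):
            for mpos in mg["pos"].to_numpy(dtype=np.int64):
                if abs(int(mid) - int(mpos)) <= max_dist:
                    rows.append(
                        {
                            "chrom": chrom,
                            "window_mid": int(mid),
                            "marker_pos": int(mpos),
                            "distance": abs(int(mid) - int(mpos)),
                        }
                    )
    return pd.DataFrame(rows, columns=["chrom", "window_mid", "marker_pos", "distance"])


def shared_across_comparisons(
    region_sets: dict[str, list[Region]],
    min_comparisons: int = 2,
    flank: int = FLANK,
) -> list[Region]:
    """Regions supported by >= ``min_comparisons`` pairwise comparisons.

    Regions from all comparisons form an overlap graph (intervals extended by
    ``flank`` on both sides, matching the gene-annotation convention);
    connected components supported by enough distinct comparisons are emitted
    with merged bounds and the sorted comparison labels.
    """
    if len(region_sets) < 2:
        raise ValueError("need >= 2 comparison region sets")
    nodes = [
        (label, r) for label, regs in region_sets.items() for r in regs
    ]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            ri, rj = nodes[i][1], nodes[j][1]
            if ri.chrom != rj.chrom:
                continue
            if ri.left - flank <= rj.right + flank and rj.left - flank <= ri.right + flank:
                graph.add_edge(i, j)
    out = []
    for comp in nx.connected_components(graph):
        labels = sorted({nodes[i][0] for i in comp})
        if len(labels) < min_comparisons:
            continue
        members = [nodes[i][1] for i in comp]
        tops = sorted({p for r in members for p in r.top_positions})
        out.append(
            Region(
                chrom=members[0].chrom,
                left=min(r.left for r in members),
                right=max(r.right for r in members),
                top_positions=tops,
                source=members[0].source,
                comparisons=labels,
            )
        )
    out.sort(key=lambda r: (r.chrom, r.left))
    return out


def hypergeometric_enrichment(
    query_genes: set[str],
    gene_to_terms: dict[str, set[str]],
    universe: set[str] | None = None,
    q_max: float = 0.10,
    min_count: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH q-values.

    The universe defaults to all genes with at least one term.  A term is
    flagged ``enriched`` when q < ``q_max`` and the query overlap is >=
    ``min_count`` genes.
    """
    if universe is None:
        universe = {g for g, t in gene_to_terms.items() if t}
    query = set(query_genes) & universe
    if not set(query_genes) <= universe:
        logger.info(
            "enrichment: %d query genes outside the universe ignored",
            len(set(query_genes) - universe),
        )
    if not query:
        return pd.DataFrame(
            columns=["term", "term_size", "overlap", "p", "q", "enriched", "genes"]
        )
    term_members: dict[str, set[str]] = {}
    for gene in universe:
        for term in gene_to_terms.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)
    big_n, small_n = len(universe), len(query)
    rows = []
    for term, members in sorted(term_members.items()):
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, big_n, len(members), small_n))
        rows.append(
            {
                "term": term,
                "term_size": len(members),
                "overlap": k,
                "p": min(1.0, p),
                "genes": ",".join(sorted(members & query)),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["enriched"] = (df["q"] < q_max) & (df["overlap"] >= min_count)
    return df[["term", "term_size", "overlap", "p", "q", "enriched", "genes"]]


def read_gene_models(gff3_path: str) -> list[GeneModel]:
    """Gene features from a GFF3 file (ID, else Name, as the gene id)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", feat.attributes.get("Name", [feat.id]))[0]
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end, feat.strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def read_gene_terms(path: str) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) into a gene -> term-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "left": [r.left for r in regions],
            "right": [r.right for r in regions],
            "n_top_positions": [len(r.top_positions) for r in regions],
            "source": [r.source for r in regions],
            "comparisons": [",".join(r.comparisons) for r in regions],
            "genes": [",".join(r.genes) for r in regions],
        }
    )


def write_regions_bed(regions: list[Region], path: str) -> None:
    """BED (0-based half-open) of region bounds."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.source or "region"
            fh.write(f"{r.chrom}\t{r.left - 1}\t{r.right}\t{name}\n")
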