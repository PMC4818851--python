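"""The Evolutionary Triangulation filter.

An ET design names an outlier population A (where the phenotype of interest
is differentially prevalent) and a similar pair (B, C). ET SNPs are those
simultaneously in the upper tail of the F_ST distributions of both outlier
pairs (A-B and A-C) and in the lower tail of the similar pair (B-C) — a
high/high/low pattern mirroring a phenotype common in A and comparably rare
in B and C. ET genes are the genes whose interval, widened by a window
(±100 kb by default), contains an ET SNP.

Percentile cutoffs are nearest-rank, computed on each pair's own theta
distribution over the common SNP universe (SNPs defined in all three pairs),
and all comparisons are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .fst import PairwiseFstTable, ThresholdSpec, percentile_cutoff
from .io import GeneAnnotation

logger = logging.getLogger("evotri")

__all__ = [
    "TriangleDesign",
    "WindowSpec",
    "ETSelection",
    "ETGeneSet",
    "select_et_snps",
    "map_snps_to_genes",
    "proportion_in_region",
    "two_way_selection",
]


@dataclass(frozen=True)
class TriangleDesign:
    """The (outlier, similar, similar) population triple."""

    outlier: str
    similar_pair: tuple[str, str]
    phenotype_label: str = ""

    def __post_init__(self) -> None:
        labels = {self.outlier, *self.similar_pair}
        if len(labels) != 3:
            raise ValueError("design requires three distinct population labels")

    @property
    def populations(self) -> tuple[str, str, str]:
        return (self.outlier, *self.similar_pair)


@dataclass(frozen=True)
class WindowSpec:
    """Symmetric window, in bases, by which gene intervals are widened."""

    width: int = 100_000

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("window width must be >= 0")


@dataclass
class ETSelection:
    """SNPs passing the three-way filter, with realized cutoffs.

    ``snps`` has columns snp_id, chrom, pos, theta_ab, theta_ac, theta_bc
    where ab/ac are the outlier pairs and bc the similar pair.
    """

    design: TriangleDesign
    thresholds: ThresholdSpec
    cutoff_high_ab: float
    cutoff_high_ac: float
    cutoff_low_bc: float
    snps: pd.DataFrame
    universe_size: int
    n_dropped: int

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> frozenset:
        return frozenset(self.snps["snp_id"])


def _infer_design(
    fst_ab: PairwiseFstTable, fst_ac: PairwiseFstTable, fst_bc: PairwiseFstTable
) -> TriangleDesign:
    ab, ac, bc = set(fst_ab.pair), set(fst_ac.pair), set(fst_bc.pair)
    shared = ab & ac
    if len(shared) != 1:
        raise ValueError("the two high-F_ST tables must share exactly one (outlier) population")
    outlier = shared.pop()
    similar = (ab | ac) - {outlier}
    if bc != similar:
        raise ValueError(
            f"low-F_ST pair {sorted(bc)} does not match the similar pair {sorted(similar)}"
        )
    b = next(p for p in fst_ab.pair if p != outlier)
    c = next(p for p in fst_ac.pair if p != outlier)
    return TriangleDesign(outlier=outlier, similar_pair=(b, c))


def select_et_snps(
    fst_ab: PairwiseFstTable,
    fst_ac: PairwiseFstTable,
    fst_bc: PairwiseFstTable,
    thresholds: ThresholdSpec,
) -> ETSelection:
    """Apply the three-way high/high/low percentile filter.

    The first two tables are the outlier pairs (selected at or above the
    ``q_high`` nearest-rank cutoff of their own distributions); the third is
    the similar pair (selected at or below its ``q_low`` cutoff). Cutoffs are
    computed over the common universe of SNPs with all three thetas defined;
    SNPs outside that universe are dropped and counted.
    """
    design = _infer_design(fst_ab, fst_ac, fst_bc)

    merged = fst_ab.data.rename(columns={"theta": "theta_ab"}).merge(
        fst_ac.data[["snp_id", "theta"]].rename(columns={"theta": "theta_ac"}), on="snp_id"
    ).merge(
        fst_bc.data[["snp_id", "theta"]].rename(columns={"theta": "theta_bc"}), on="snp_id"
    )
    defined = merged[["theta_ab", "theta_ac", "theta_bc"]].notna().all(axis=1)
    universe = merged.loc[defined].reset_index(drop=True)
    all_ids = set(fst_ab.data["snp_id"]) | set(fst_ac.data["snp_id"]) | set(fst_bc.data["snp_id"])
    n_dropped = len(all_ids) - len(universe)
    if len(universe) == 0:
        raise ValueError("no SNP has defined theta in all three population pairs")

    cut_ab = percentile_cutoff(universe["theta_ab"], thresholds.q_high)
    cut_ac = percentile_cutoff(universe["theta_ac"], thresholds.q_high)
    cut_bc = percentile_cutoff(universe["theta_bc"], thresholds.q_low)
    hit = (
        (universe["theta_ab"] >= cut_ab)
        & (universe["theta_ac"] >= cut_ac)
        & (universe["theta_bc"] <= cut_bc)
    )
    snps = universe.loc[hit].reset_index(drop=True)
    logger.info(
        "ET %s: universe=%d dropped=%d cutoffs=(%.4g, %.4g, %.4g) selected=%d",
        thresholds, len(universe), n_dropped, cut_ab, cut_ac, cut_bc, len(snps),
    )
    return ETSelection(
        design=design,
        thresholds=thresholds,
        cutoff_high_ab=cut_ab,
        cutoff_high_ac=cut_ac,
        cutoff_low_bc=cut_bc,
        snps=snps,
        universe_size=len(universe),
        n_dropped=n_dropped,
    )


@dataclass
class ETGeneSet:
    """Genes supported by at least one selected SNP (set semantics).

    ``support`` lists every (gene_id, snp_id, distance) pair; ``genes`` is
    the deduplicated per-gene view. Distance is 0 for a SNP inside the gene
    body, otherwise the base-pair gap to the nearer gene edge.
    """

    genes: pd.DataFrame  # gene_id, chrom, start, end, n_support
    support: pd.DataFrame  # gene_id, snp_id, pos, distance
    window: WindowSpec = field(default_factory=WindowSpec)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> frozenset:
        return frozenset(self.genes["gene_id"])


def _snp_frame(snps) -> pd.DataFrame:
    if isinstance(snps, ETSelection):
        return snps.snps
    return snps


def map_snps_to_genes(
    snps, annotation: GeneAnnotation, window: WindowSpec = WindowSpec()
) -> ETGeneSet:
    """Map selected SNPs to genes whose widened interval contains them.

    Gene g (1-based inclusive [start, end]) is supported by SNP s iff they
    share a chromosome and ``g.start - width <= s.pos <= g.end + width``,
    both boundaries inclusive. Each gene appears once however many SNPs
    support it.
    """
    df = _snp_frame(snps)
    if len(annotation) == 0:
        logger.warning("empty gene annotation: ET gene set is empty")
    w = window.width

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotation.genes.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            # interval is half-open; +1 keeps the inclusive right boundary
            tree.addi(row.start - w, row.end + w + 1, (row.gene_id, row.start, row.end))
        trees[chrom] = tree

    records = []
    for row in df.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in tree.at(row.pos):
            gene_id, gstart, gend = hit.data
            if gstart <= row.pos <= gend:
                dist = 0
            elif row.pos < gstart:
                dist = gstart - row.pos
            else:
                dist = row.pos - gend
            records.append((gene_id, row.snp_id, row.pos, dist))

    support = pd.DataFrame(records, columns=["gene_id", "snp_id", "pos", "distance"])
    if len(support):
        counts = support.groupby("gene_id").size().rename("n_support")
        genes = (
            annotation.genes.merge(counts, left_on="gene_id", right_index=True)
            .sort_values(["chrom", "start", "gene_id"])
            .reset_index(drop=True)
        )
    else:
        genes = annotation.genes.iloc[0:0].assign(n_support=pd.Series(dtype=int))
    return ETGeneSet(genes=genes, support=support, window=window)


def proportion_in_region(snps, region, window: WindowSpec = WindowSpec()) -> float:
    """Fraction of selected SNPs within the window-widened region.

    ``region`` is a (chrom, start, end) triple or a mapping with those keys,
    1-based inclusive. Undefined (raises) on an empty SNP set.
    """
    df = _snp_frame(snps)
    if len(df) == 0:
        raise ValueError("proportion_in_region is undefined for an empty SNP set")
    if isinstance(region, dict):
        chrom, start, end = region["chrom"], region["start"], region["end"]
    else:
        chrom, start, end = region
    w = window.width
    inside = (
        (df["chrom"] == chrom)
        & (df["pos"] >= start - w)
        & (df["pos"] <= end + w)
    )
    return float(inside.mean())


def two_way_selection(fst: PairwiseFstTable, q_high: float) -> pd.DataFrame:
    """SNPs at or above the nearest-rank ``q_high`` cutoff of one pair.

    The baseline against which the three-way filter is contrasted: a plain
    upper-tail outlier scan on a single population pair.
    """
    defined = fst.data.loc[fst.data["theta"].notna()]
    if len(defined) == 0:
        raise ValueError("no defined theta values")
    cut = percentile_cutoff(defined["theta"], q_high)
    return defined.loc[defined["theta"] >= cut].reset_index(drop=True)
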