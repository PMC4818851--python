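"""Population Branch Statistic (PBS) for three populations.

PBS converts pairwise F_ST into branch lengths, T_XY = -log(1 - F_ST(X,Y)),
and isolates the focal population's branch since the three-way split:

    PBS_A = (T_AB + T_AC - T_BC) / 2

Large values mark SNPs whose allele frequency moved specifically along the
focal branch. Unlike the triangulation filter, PBS imposes no constraint on
the phenotype prevalence of the third population; it is included here as the
head-to-head baseline method.

Theta is clamped to [0, 1 - 1e-12] before the log transform: negative
estimates are sampling noise around zero on a branch length, and the upper
clamp keeps fixed differences finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst import PairwiseFstTable
from .io import GeneAnnotation
from .triangulate import ETGeneSet, WindowSpec, map_snps_to_genes

__all__ = ["PBSResult", "compute_pbs", "top_k_snps", "pbs_gene_comparison", "branch_length"]

_THETA_MAX = 1.0 - 1e-12


def branch_length(theta: np.ndarray) -> np.ndarray:
    """T = -log(1 - theta) with theta clamped to [0, 1 - 1e-12]."""
    t = np.clip(np.asarray(theta, float), 0.0, _THETA_MAX)
    return -np.log1p(-t)


@dataclass
class PBSResult:
    """Per-SNP PBS for one focal population.

    ``data`` columns: snp_id, chrom, pos, t_ab, t_ac, t_bc, pbs, where ab and
    ac are the two pairs containing the focal population. ``ranking`` orders
    SNP ids by descending PBS (ties broken by chrom, pos).
    """

    focal: str
    populations: tuple[str, str, str]
    data: pd.DataFrame
    n_dropped: int

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ranking(self) -> tuple:
        ordered = self.data.sort_values(
            ["pbs", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
        )
        return tuple(ordered["snp_id"])


def compute_pbs(
    fst_ab: PairwiseFstTable,
    fst_ac: PairwiseFstTable,
    fst_bc: PairwiseFstTable,
    focal: str,
) -> PBSResult:
    """PBS of ``focal`` from the three pairwise theta tables.

    The tables may be passed in any order; the two containing the focal
    population are identified by their pair labels. SNPs with any undefined
    theta are dropped and counted.
    """
    tables = [fst_ab, fst_ac, fst_bc]
    pops = set()
    for t in tables:
        pops.update(t.pair)
    if len(pops) != 3:
        raise ValueError(f"tables must cover exactly three populations, got {sorted(pops)}")
    if focal not in pops:
        raise ValueError(f"focal population {focal!r} not among {sorted(pops)}")
    focal_tables = [t for t in tables if focal in t.pair]
    (off_table,) = [t for t in tables if focal not in t.pair]
    if len(focal_tables) != 2:
        raise ValueError("focal population must appear in exactly two pairs")
    b = next(p for p in focal_tables[0].pair if p != focal)
    c = next(p for p in focal_tables[1].pair if p != focal)

    merged = (
        focal_tables[0].data.rename(columns={"theta": "theta_ab"})
        .merge(
            focal_tables[1].data[["snp_id", "theta"]].rename(columns={"theta": "theta_ac"}),
            on="snp_id",
        )
        .merge(
            off_table.data[["snp_id", "theta"]].rename(columns={"theta": "theta_bc"}),
            on="snp_id",
        )
    )
    all_ids = set().union(*(set(t.data["snp_id"]) for t in tables))
    defined = merged[["theta_ab", "theta_ac", "theta_bc"]].notna().all(axis=1)
    merged = merged.loc[defined].reset_index(drop=True)
    n_dropped = len(all_ids) - len(merged)

    t_ab = branch_length(merged["theta_ab"])
    t_ac = branch_length(merged["theta_ac"])
    t_bc = branch_length(merged["theta_bc"])
    out = merged[["snp_id", "chrom", "pos"]].copy()
    out["t_ab"] = t_ab
    out["t_ac"] = t_ac
    out["t_bc"] = t_bc
    out["pbs"] = (t_ab + t_ac - t_bc) / 2.0
    return PBSResult(focal=focal, populations=(focal, b, c), data=out, n_dropped=n_dropped)


def top_k_snps(result: PBSResult, k: int) -> pd.DataFrame:
    """The k highest-PBS SNPs, ties at rank k broken by (chrom, pos)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(result.data):
        raise ValueError(f"k={k} exceeds the {len(result.data)} SNPs with defined PBS")
    ordered = result.data.sort_values(
        ["pbs", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    if k < len(ordered):
        kth = ordered["pbs"].iloc[k - 1]
        if ordered["pbs"].iloc[k] == kth:
            import logging

            logging.getLogger("evotri").info("tie at PBS rank %d (value %.6g)", k, kth)
    return ordered.head(k).reset_index(drop=True)


def pbs_gene_comparison(
    snps: pd.DataFrame, annotation: GeneAnnotation, window: WindowSpec = WindowSpec()
) -> ETGeneSet:
    """Map top-PBS SNPs to genes; identical contract to the ET gene mapping."""
    return map_snps_to_genes(snps, annotation, window)
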