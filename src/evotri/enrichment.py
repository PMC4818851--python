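"""Association flagging and permutation-based gene-set enrichment.

A (gene, phenotype) pair counts as a "true" association when it has at least
five supporting publications or a genome-wide-significant GWAS signal
(p < 5e-8, strict). Only phenotypes flagged as appropriately distributed —
prevalence pattern matching the population design — count toward enrichment,
and a gene is counted once no matter how many qualifying phenotypes it has
(pleiotropy does not inflate the statistic).

The enrichment test draws, for each permutation, the same number of genes as
the observed gene set uniformly without replacement from the full annotation
universe, counts qualifying genes among them, and reports the empirical
p-value: the fraction of permutations with a count at least the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AssociationCatalog, GeneAnnotation

__all__ = [
    "EnrichmentReport",
    "flag_true_associations",
    "qualifying_genes",
    "count_associated_genes",
    "permutation_enrichment",
]

GWAS_SIGNIFICANCE = 5e-8
MIN_PUBLICATIONS = 5


def flag_true_associations(
    catalog: AssociationCatalog, appropriately_distributed_only: bool = False
) -> frozenset:
    """(gene_id, phenotype) pairs meeting the evidence rule.

    A pair qualifies iff n_publications >= 5 OR gwas_min_p < 5e-8 (strict;
    exactly 5e-8 does not qualify). With ``appropriately_distributed_only``
    the pair must additionally carry the distribution flag — the subset that
    feeds the enrichment statistic.
    """
    df = catalog.entries
    ok = (df["n_publications"] >= MIN_PUBLICATIONS) | (
        df["gwas_min_p"].notna() & (df["gwas_min_p"] < GWAS_SIGNIFICANCE)
    )
    if appropriately_distributed_only:
        ok &= df["appropriately_distributed"]
    return frozenset(zip(df.loc[ok, "gene_id"], df.loc[ok, "phenotype"]))


def qualifying_genes(catalog: AssociationCatalog) -> frozenset:
    """Genes with >= 1 qualifying, appropriately distributed association."""
    pairs = flag_true_associations(catalog, appropriately_distributed_only=True)
    return frozenset(g for g, _ in pairs)


def count_associated_genes(genes, qualifying) -> int:
    """Number of genes in ``genes`` with >= 1 qualifying pair, each once.

    ``qualifying`` may be a set of (gene_id, phenotype) pairs or of gene ids.
    """
    qual_genes = {q[0] if isinstance(q, tuple) else q for q in qualifying}
    return len(set(genes) & qual_genes)


@dataclass
class EnrichmentReport:
    """Outcome of the genome-resampling enrichment test."""

    universe_size: int
    et_gene_count: int
    observed_k: int
    n_perm: int
    perm_counts: np.ndarray = field(repr=False)  # histogram over count values 0..et_gene_count
    p_value: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "et_gene_count": self.et_gene_count,
            "observed_k": self.observed_k,
            "n_perm": self.n_perm,
            "perm_counts": [int(c) for c in self.perm_counts],
            "p_value": self.p_value,
            "seed": self.seed,
        }


def _sample_qualifying_counts(
    rng: np.random.Generator, is_qual: np.ndarray, m: int, n_perm: int
) -> np.ndarray:
    """Qualifying-gene count in n_perm draws of m genes without replacement.

    Each permutation assigns every universe member an independent uniform key
    and takes the m smallest — a uniform subset. Chunked to bound memory.
    """
    n = is_qual.size
    if m == 0:
        return np.zeros(n_perm, dtype=np.int64)
    counts = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, int(5_000_000 // n))
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        keys = rng.random((hi - lo, n))
        if m < n:
            idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        else:
            idx = np.broadcast_to(np.arange(n), (hi - lo, n))
        counts[lo:hi] = is_qual[idx].sum(axis=1)
    return counts


def permutation_enrichment(
    et_genes,
    annotation: GeneAnnotation,
    qualifying,
    n_perm: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> EnrichmentReport:
    """Genome-resampling enrichment test for a gene set.

    Draws ``n_perm`` random gene sets of the observed size from the full
    annotation universe (without replacement within each draw) and counts
    qualifying genes in each. The empirical p-value is the fraction of draws
    with a count >= the observed count; with ``plus_one`` the
    (count+1)/(n_perm+1) finite-sample correction is used instead.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gene_ids = (
        et_genes.gene_ids if hasattr(et_genes, "gene_ids") else frozenset(et_genes)
    )
    universe = list(annotation.genes["gene_id"])
    universe_set = set(universe)
    if not gene_ids <= universe_set:
        stray = sorted(gene_ids - universe_set)[:5]
        raise ValueError(f"ET genes not in annotation universe: {stray} ...")
    m = len(gene_ids)
    if m > len(universe):
        raise ValueError("gene set larger than annotation universe")

    qual_genes = {q[0] if isinstance(q, tuple) else q for q in qualifying}
    observed_k = count_associated_genes(gene_ids, qual_genes)

    is_qual = np.fromiter((g in qual_genes for g in universe), dtype=bool, count=len(universe))
    rng = np.random.default_rng(seed)
    counts = _sample_qualifying_counts(rng, is_qual, m, n_perm)
    n_ge = int((counts >= observed_k).sum())
    p = (n_ge + 1) / (n_perm + 1) if plus_one else n_ge / n_perm
    hist = np.bincount(counts, minlength=m + 1)
    return EnrichmentReport(
        universe_size=len(universe),
        et_gene_count=m,
        observed_k=observed_k,
        n_perm=n_perm,
        perm_counts=hist,
        p_value=float(p),
        seed=seed,
    )
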