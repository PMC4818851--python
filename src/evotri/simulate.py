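"""Synthetic three-population datasets under a Balding–Nichols drift model.

The generator emulates the population structure the triangulation design
assumes: an outlier population A that has drifted substantially (large F)
and a similar pair B, C that drifted little (small, shared F). For each SNP
an ancestral frequency p is drawn uniformly from a mid-range interval and
each population's latent frequency is Beta-distributed with mean p and
variance F·p(1-p). Observed frequencies add binomial sampling noise from a
finite number of allele copies.

A subset of SNPs is planted as "signal": the outlier's latent frequency is
shifted upward by delta (clipped away from the boundaries) while B and C are
forced to share one latent draw — an allele that is, by construction,
appropriately distributed for the (A; B, C) design. The matching annotation
tiles genes along the chromosome and labels every gene near a signal SNP
with one qualifying, appropriately distributed phenotype, so planted signal
is recoverable end to end without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AssociationCatalog, GeneAnnotation, VariantFrequencyTable

__all__ = ["SimulationConfig", "SignalTruth", "simulate_frequencies", "simulate_annotation", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the planted-signal conditions used throughout the test
    surface: 20,000 SNPs of which 50 carry a 0.4 outlier shift, drift
    F_A = 0.1 versus F_BC = 0.01, and 200 sampled allele copies per
    population.
    """

    n_snps: int = 20_000
    n_signal: int = 50
    f_outlier: float = 0.1       # Balding-Nichols F of population A
    f_similar: float = 0.01      # shared F of populations B and C
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    delta: float = 0.4           # latent-frequency shift of A at signal SNPs
    n_chrom: int = 200           # sampled allele copies per population
    chrom: str = "chr1"
    # one synthetic "genome" laid out as a single coordinate axis; genome-scale
    # length and gene spacing give ~10,000 genes, so the fraction of genes
    # labeled by 50 signal SNPs (<1%) matches the small genome-wide base
    # rate of qualifying associations the resampling test assumes
    chrom_length: int = 3_000_000_000
    gene_length: int = 20_000
    # spacing exceeds gene_length + 2*window, so distinct genes' widened
    # windows are disjoint: every SNP maps to at most one gene and the
    # gene-level permutation null of the enrichment test is exact for data
    # from this generator (no locus clustering)
    gene_spacing: int = 300_000
    window: int = 100_000        # labeling window for the synthetic catalog
    cluster_signal: bool = False  # place signal SNPs contiguously mid-chromosome
    populations: tuple[str, str, str] = ("A", "B", "C")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_signal <= self.n_snps:
            raise ValueError("need 0 <= n_signal <= n_snps")
        for f in (self.f_outlier, self.f_similar):
            if not 0.0 <= f < 1.0:
                raise ValueError("drift F must be in [0, 1)")
        if not 0.0 < self.ancestral_low <= self.ancestral_high < 1.0:
            raise ValueError("ancestral frequency range must lie within (0, 1)")
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if self.chrom_length < self.n_snps:
            raise ValueError("chrom_length must allow unique SNP positions")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SignalTruth:
    """Which SNPs carry planted signal, and (if clustered) their region."""

    snp_ids: tuple[str, ...]
    positions: tuple[int, ...]
    region: tuple[str, int, int] | None = None


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Latent population frequencies: Beta with mean p, variance f*p*(1-p)."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[VariantFrequencyTable, SignalTruth]:
    """Draw one three-population frequency table plus its signal truth table.

    Positions are laid uniformly along the chromosome (fixed stride, so they
    are unique and deterministic). Bit-identical output for a fixed config.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_snps
    step = config.chrom_length // n
    pos = (np.arange(n, dtype=np.int64) * step) + step  # step, 2*step, ...

    if config.cluster_signal:
        start = (n - config.n_signal) // 2
        signal_idx = np.arange(start, start + config.n_signal)
    else:
        signal_idx = np.sort(rng.choice(n, size=config.n_signal, replace=False))
    is_signal = np.zeros(n, dtype=bool)
    is_signal[signal_idx] = True

    ancestral = rng.uniform(config.ancestral_low, config.ancestral_high, size=n)
    lat_a = _balding_nichols(rng, ancestral, config.f_outlier)
    lat_b = _balding_nichols(rng, ancestral, config.f_similar)
    lat_c = _balding_nichols(rng, ancestral, config.f_similar)
    # planted signal: outlier shifted by delta, similar pair forced equal.
    # The shift is directed away from the nearer frequency boundary: F_ST is
    # allele-label invariant, so the sign is immaterial downstream, while a
    # fixed +delta would saturate at the clip for high ancestral frequencies
    # and silently erase the planted differentiation.
    base = lat_a[is_signal]
    shift = np.where(base + config.delta <= 0.99, config.delta, -config.delta)
    lat_a[is_signal] = np.clip(base + shift, 0.01, 0.99)
    lat_c[is_signal] = lat_b[is_signal]

    data = {
        "snp_id": [f"snp{i:06d}" for i in range(n)],
        "chrom": config.chrom,
        "pos": pos,
        "allele_ref": "A",
        "allele_alt": "G",
    }
    for label, latent in zip(config.populations, (lat_a, lat_b, lat_c)):
        observed = rng.binomial(config.n_chrom, latent) / config.n_chrom
        data[f"{label}.n_chrom"] = float(config.n_chrom)
        data[f"{label}.freq_alt"] = observed
    table = VariantFrequencyTable(pd.DataFrame(data), config.populations)

    region = None
    if config.cluster_signal and config.n_signal:
        region = (config.chrom, int(pos[signal_idx[0]]), int(pos[signal_idx[-1]]))
    truth = SignalTruth(
        snp_ids=tuple(data["snp_id"][i] for i in signal_idx),
        positions=tuple(int(pos[i]) for i in signal_idx),
        region=region,
    )
    return table, truth


SIGNAL_PHENOTYPE = "synthetic_signal_trait"


def simulate_annotation(
    config: SimulationConfig, truth: SignalTruth
) -> tuple[GeneAnnotation, AssociationCatalog]:
    """Tile genes along the chromosome and label those near planted signal.

    Genes start every ``gene_spacing`` bases with length ``gene_length``.
    A gene whose interval widened by ``window`` contains a signal SNP gets
    one qualifying (5 publications), appropriately distributed phenotype;
    all other genes carry no catalog entry.
    """
    starts = np.arange(1, config.chrom_length - config.gene_length + 2, config.gene_spacing, dtype=np.int64)
    ends = starts + config.gene_length - 1
    gene_ids = [f"G{i:05d}" for i in range(len(starts))]
    annotation = GeneAnnotation(
        pd.DataFrame({"gene_id": gene_ids, "chrom": config.chrom, "start": starts, "end": ends}),
        build_label="synthetic",
    )
    sig_pos = np.asarray(truth.positions, dtype=np.int64)
    rows = []
    if sig_pos.size:
        lo = starts - config.window
        hi = ends + config.window
        # for each gene: any signal SNP inside [lo, hi]
        left = np.searchsorted(sig_pos, lo, side="left")
        right = np.searchsorted(sig_pos, hi, side="right")
        for gid, has in zip(gene_ids, right > left):
            if has:
                rows.append((gid, SIGNAL_PHENOTYPE, 5, np.nan, True))
    catalog = AssociationCatalog(
        pd.DataFrame(
            rows,
            columns=["gene_id", "phenotype", "n_publications", "gwas_min_p", "appropriately_distributed"],
        )
    )
    return annotation, catalog


def simulate_dataset(config: SimulationConfig):
    """Frequencies, truth, annotation and catalog for one config."""
    table, truth = simulate_frequencies(config)
    annotation, catalog = simulate_annotation(config, truth)
    return table, truth, annotation, catalog
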