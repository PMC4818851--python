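"""End-to-end orchestration: (simulate | ingest) → F_ST → triangulate →
map genes → enrichment → report, over a sweep of threshold stringencies.

All randomness flows from one top-level seed through named
:class:`numpy.random.SeedSequence` substreams, so each stage is
independently reproducible and the whole run is idempotent given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import permutation_enrichment, qualifying_genes
from .fst import ThresholdSpec, pairwise_fst_table
from .io import (
    AssociationCatalog,
    GeneAnnotation,
    VariantFrequencyTable,
    read_association_catalog,
    read_frequency_table,
    read_gene_annotation,
    write_association_catalog,
    write_frequency_table,
    write_gene_annotation,
)
from .simulate import SimulationConfig, simulate_dataset
from .triangulate import TriangleDesign, WindowSpec, map_snps_to_genes, select_et_snps

logger = logging.getLogger("evotri")

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

DEFAULT_SWEEP = (
    ThresholdSpec(95, 5),
    ThresholdSpec(90, 10),
    ThresholdSpec(85, 15),
    ThresholdSpec(80, 20),
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``freq_path``/``annotation_path``/``catalog_path`` point at input
    files, or ``simulation`` requests a synthetic dataset. ``thresholds`` is
    a stringency sweep, most stringent first.
    """

    design: TriangleDesign
    thresholds: tuple[ThresholdSpec, ...] = DEFAULT_SWEEP
    window: WindowSpec = field(default_factory=WindowSpec)
    n_perm: int = 10_000
    seed: int = 0
    freq_path: str | None = None
    annotation_path: str | None = None
    annotation_format: str = "bed"
    catalog_path: str | None = None
    simulation: SimulationConfig | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.freq_path is None:
            raise ValueError("either simulation or freq_path must be given")
        order = [(-t.q_high, t.q_low) for t in self.thresholds]
        if order != sorted(order):
            raise ValueError("thresholds must be sorted most stringent first")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a flat YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    design = TriangleDesign(
        outlier=raw["outlier"],
        similar_pair=tuple(raw["similar"]),
        phenotype_label=raw.get("phenotype", ""),
    )
    thresholds = tuple(
        ThresholdSpec(q_high=pair[0], q_low=pair[1])
        for pair in raw.get("thresholds", [[95, 5], [90, 10], [85, 15], [80, 20]])
    )
    sim = None
    if "simulation" in raw:
        sim = SimulationConfig(**raw["simulation"])
    return RunConfig(
        design=design,
        thresholds=thresholds,
        window=WindowSpec(int(raw.get("window", 100_000))),
        n_perm=int(raw.get("n_perm", 10_000)),
        seed=int(raw.get("seed", 0)),
        freq_path=raw.get("freq"),
        annotation_path=raw.get("annotation"),
        annotation_format=raw.get("annotation_format", "bed"),
        catalog_path=raw.get("catalog"),
        simulation=sim,
        out_dir=raw.get("out_dir"),
    )


def _stage_seed(seed: int, name: str) -> int:
    """Independent substream seed for a named stage (kept below 2**31)."""
    import zlib

    import numpy as np

    child = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the machine-readable summary.

    When ``out_dir`` is set, per-threshold ET SNP/gene tables, the enrichment
    reports and a ``summary.json`` are written there, all in formats the
    package's own readers accept.
    """
    design = config.design
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "design": {
            "outlier": design.outlier,
            "similar_pair": list(design.similar_pair),
            "phenotype_label": design.phenotype_label,
        },
        "window": config.window.width,
        "n_perm": config.n_perm,
        "thresholds": [],
    }

    if config.simulation is not None:
        sim = config.simulation.with_(seed=_stage_seed(config.seed, "simulate"))
        table, truth, annotation, catalog = simulate_dataset(sim)
        summary["simulation"] = {"n_snps": sim.n_snps, "n_signal": sim.n_signal, "seed": sim.seed}
    else:
        table = read_frequency_table(config.freq_path)
        truth = None
        annotation = (
            read_gene_annotation(config.annotation_path, format=config.annotation_format)
            if config.annotation_path
            else None
        )
        catalog = read_association_catalog(config.catalog_path) if config.catalog_path else None

    table = table.restrict(design.populations)
    summary["snps_total"] = len(table)
    summary["snps_dropped_missing_population"] = table.n_dropped

    a, (b, c) = design.outlier, design.similar_pair
    fst_ab = pairwise_fst_table(table, (a, b))
    fst_ac = pairwise_fst_table(table, (a, c))
    fst_bc = pairwise_fst_table(table, (b, c))
    summary["fst_defined_counts"] = {
        f"{a}|{b}": fst_ab.defined_count,
        f"{a}|{c}": fst_ac.defined_count,
        f"{b}|{c}": fst_bc.defined_count,
    }

    qual = qualifying_genes(catalog) if catalog is not None else frozenset()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_frequency_table(table, out_dir / "frequencies.tsv")
        if annotation is not None:
            write_gene_annotation(annotation, out_dir / "genes.bed", format="bed")
        if catalog is not None:
            write_association_catalog(catalog, out_dir / "catalog.tsv")

    for spec in config.thresholds:
        selection = select_et_snps(fst_ab, fst_ac, fst_bc, spec)
        entry = {
            "threshold": {"q_high": spec.q_high, "q_low": spec.q_low},
            "cutoffs": {
                f"{a}|{b}": selection.cutoff_high_ab,
                f"{a}|{c}": selection.cutoff_high_ac,
                f"{b}|{c}": selection.cutoff_low_bc,
            },
            "universe_size": selection.universe_size,
            "snps_dropped": selection.n_dropped,
            "et_snp_count": len(selection),
        }
        tag = f"q{spec.q_high:g}_{spec.q_low:g}"
        if truth is not None:
            hits = selection.snp_ids & set(truth.snp_ids)
            entry["signal_snps_recovered"] = len(hits)
        if annotation is not None:
            gene_set = map_snps_to_genes(selection, annotation, config.window)
            entry["et_gene_count"] = len(gene_set)
            if catalog is not None:
                report = permutation_enrichment(
                    gene_set,
                    annotation,
                    qual,
                    n_perm=config.n_perm,
                    seed=_stage_seed(config.seed, f"enrich_{tag}"),
                )
                entry["enrichment"] = {
                    "observed_k": report.observed_k,
                    "p_value": report.p_value,
                    "seed": report.seed,
                }
            if out_dir:
                gene_set.genes.to_csv(out_dir / f"et_genes_{tag}.tsv", sep="\t", index=False)
        if out_dir:
            selection.snps.to_csv(out_dir / f"et_snps_{tag}.tsv", sep="\t", index=False)
        logger.info("threshold %s: %d ET SNPs", spec, len(selection))
        summary["thresholds"].append(entry)

    if out_dir:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
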