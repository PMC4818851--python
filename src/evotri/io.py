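"""Readers and writers for the tabular formats the pipeline consumes.

Everything external is normalized at this boundary into three in-memory
containers backed by :class:`pandas.DataFrame`:

* :class:`VariantFrequencyTable` — per-SNP alternate-allele frequencies and
  sampled allele-copy counts for one or more populations,
* :class:`GeneAnnotation` — gene intervals in 1-based inclusive coordinates,
* :class:`AssociationCatalog` — gene → phenotype evidence records standing in
  for a literature-curated association database.

Coordinate convention: internal coordinates are 1-based inclusive everywhere;
BED input (0-based half-open) is converted on read and back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("evotri")

__all__ = [
    "FormatError",
    "EmptyInputError",
    "VariantFrequencyTable",
    "GeneAnnotation",
    "AssociationCatalog",
    "read_frequency_table",
    "write_frequency_table",
    "read_hapmap_frequencies",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_association_catalog",
    "write_association_catalog",
]


class FormatError(ValueError):
    """Input file does not match the expected dialect."""


class EmptyInputError(ValueError):
    """Input file contains no data rows."""


_FREQ_META = ["snp_id", "chrom", "pos", "allele_ref", "allele_alt"]


@dataclass
class VariantFrequencyTable:
    """Per-SNP allele frequencies for a set of populations.

    ``data`` holds one row per SNP with the metadata columns
    ``snp_id, chrom, pos, allele_ref, allele_alt`` followed by, for every
    population label ``P``, the pair ``P.n_chrom`` (sampled allele copies,
    >= 1) and ``P.freq_alt`` (alternate-allele fraction in [0, 1]).
    """

    data: pd.DataFrame
    populations: tuple[str, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in _FREQ_META if c not in self.data.columns]
        if missing:
            raise FormatError(f"frequency table missing column(s): {missing}")
        for pop in self.populations:
            for suffix in ("n_chrom", "freq_alt"):
                if f"{pop}.{suffix}" not in self.data.columns:
                    raise FormatError(f"missing column {pop}.{suffix}")
        if self.data["snp_id"].duplicated().any():
            dup = self.data.loc[self.data["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id: {dup}")

    def __len__(self) -> int:
        return len(self.data)

    def freq(self, pop: str) -> np.ndarray:
        """Alternate-allele frequency vector for one population."""
        return self.data[f"{self._check(pop)}.freq_alt"].to_numpy(float)

    def n_chrom(self, pop: str) -> np.ndarray:
        """Sampled allele-copy counts for one population."""
        return self.data[f"{self._check(pop)}.n_chrom"].to_numpy(float)

    def _check(self, pop: str) -> str:
        if pop not in self.populations:
            raise KeyError(f"unknown population label: {pop!r}")
        return pop

    def restrict(self, populations: tuple[str, ...]) -> "VariantFrequencyTable":
        """Subset to SNPs fully observed in ``populations``; drops are counted."""
        mask = np.ones(len(self.data), dtype=bool)
        for pop in populations:
            self._check(pop)
            mask &= self.data[f"{pop}.n_chrom"].notna().to_numpy()
            mask &= self.data[f"{pop}.freq_alt"].notna().to_numpy()
        kept = self.data.loc[mask].reset_index(drop=True)
        return VariantFrequencyTable(kept, self.populations, int((~mask).sum()))


def _infer_populations(columns) -> tuple[str, ...]:
    pops = []
    for col in columns:
        if col.endswith(".n_chrom"):
            pop = col[: -len(".n_chrom")]
            if f"{pop}.freq_alt" in columns:
                pops.append(pop)
    return tuple(pops)


def read_frequency_table(source, dialect: str = "normalized_tsv") -> VariantFrequencyTable:
    """Read a frequency table.

    ``dialect="normalized_tsv"`` expects one TSV with the normalized layout;
    ``source`` is its path. ``dialect="hapmap_freq"`` expects a mapping
    ``{population label: path}`` of per-population HapMap-style allele
    frequency files, joined on rs id (see :func:`read_hapmap_frequencies`).
    Rows with an unparsable frequency, a frequency outside [0, 1], or a
    non-positive sample size are dropped; the drop count is recorded on the
    returned table and logged.
    """
    if dialect == "hapmap_freq":
        if not isinstance(source, Mapping):
            raise FormatError("hapmap_freq dialect requires a {population: path} mapping")
        return read_hapmap_frequencies(source)
    if dialect != "normalized_tsv":
        raise FormatError(f"unknown dialect: {dialect!r}")

    path = Path(source)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty frequency file: {path}") from None
    if len(df) == 0:
        raise EmptyInputError(f"no data rows in frequency file: {path}")
    missing = [c for c in _FREQ_META if c not in df.columns]
    if missing:
        raise FormatError(f"frequency table {path} missing column(s): {missing}")
    pops = _infer_populations(df.columns)
    if not pops:
        raise FormatError(f"no population columns (POP.n_chrom / POP.freq_alt) in {path}")

    mask = np.ones(len(df), dtype=bool)
    for pop in pops:
        n = pd.to_numeric(df[f"{pop}.n_chrom"], errors="coerce")
        f = pd.to_numeric(df[f"{pop}.freq_alt"], errors="coerce")
        df[f"{pop}.n_chrom"] = n
        df[f"{pop}.freq_alt"] = f
        mask &= n.notna().to_numpy() & (n >= 1).to_numpy()
        mask &= f.notna().to_numpy() & (f >= 0).to_numpy() & (f <= 1).to_numpy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.warning("dropped %d invalid row(s) from %s", n_dropped, path)
    df = df.loc[mask].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    return VariantFrequencyTable(df, pops, n_dropped)


def write_frequency_table(table: VariantFrequencyTable, path) -> None:
    cols = _FREQ_META + [f"{p}.{s}" for p in table.populations for s in ("n_chrom", "freq_alt")]
    table.data[cols].to_csv(path, sep="\t", index=False)


# Columns of a HapMap Phase III allele-frequency file that the adapter needs;
# remaining columns (strand, center, QC code, ...) are ignored.
_HAPMAP_REQUIRED = [
    "rs#", "chrom", "pos", "refallele", "refallele_freq",
    "otherallele", "otherallele_freq", "totalcount",
]


def read_hapmap_frequencies(paths: Mapping[str, object], drop_monomorphic: bool = False) -> VariantFrequencyTable:
    """Join per-population HapMap-style allele-frequency files on rs id.

    Only SNPs present in *every* population are retained; the count of
    discarded SNPs (union minus intersection, plus invalid rows) is recorded.
    Allele labels are harmonized to the first population's ref/alt assignment;
    a SNP whose alleles cannot be reconciled is discarded. ``drop_monomorphic``
    removes SNPs whose alternate allele is absent or fixed in all populations
    (the upstream QC choice is not standardized, so it is a switch, off by
    default).
    """
    if not paths:
        raise EmptyInputError("no HapMap input files given")
    per_pop: dict[str, pd.DataFrame] = {}
    all_ids: set[str] = set()
    for pop, path in paths.items():
        try:
            df = pd.read_csv(path, sep=r"\s+", dtype={"rs#": str, "chrom": str})
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"empty HapMap file: {path}") from None
        missing = [c for c in _HAPMAP_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"HapMap file {path} missing column(s): {missing}")
        df = df[_HAPMAP_REQUIRED].rename(columns={"rs#": "snp_id"})
        ok = (
            pd.to_numeric(df["otherallele_freq"], errors="coerce").between(0, 1)
            & (pd.to_numeric(df["totalcount"], errors="coerce") >= 1)
        )
        df = df.loc[ok.fillna(False)].drop_duplicates("snp_id")
        per_pop[pop] = df.set_index("snp_id")
        all_ids.update(df["snp_id"])

    pops = tuple(paths)
    first = per_pop[pops[0]]
    common = first.index
    for pop in pops[1:]:
        common = common.intersection(per_pop[pop].index)
    common = common.sort_values()

    base = first.loc[common]
    out = pd.DataFrame(
        {
            "snp_id": common,
            "chrom": base["chrom"].astype(str).to_numpy(),
            "pos": base["pos"].astype(int).to_numpy(),
            "allele_ref": base["refallele"].to_numpy(),
            "allele_alt": base["otherallele"].to_numpy(),
        }
    )
    keep = np.ones(len(out), dtype=bool)
    for pop in pops:
        sub = per_pop[pop].loc[common]
        same = (sub["refallele"].to_numpy() == out["allele_ref"].to_numpy()) & (
            sub["otherallele"].to_numpy() == out["allele_alt"].to_numpy()
        )
        flipped = (sub["refallele"].to_numpy() == out["allele_alt"].to_numpy()) & (
            sub["otherallele"].to_numpy() == out["allele_ref"].to_numpy()
        )
        freq = sub["otherallele_freq"].to_numpy(float).copy()
        freq[flipped] = 1.0 - freq[flipped]
        keep &= same | flipped
        out[f"{pop}.n_chrom"] = sub["totalcount"].to_numpy(float)
        out[f"{pop}.freq_alt"] = freq
    out = out.loc[keep].reset_index(drop=True)
    if drop_monomorphic:
        freqs = out[[f"{p}.freq_alt" for p in pops]].to_numpy(float)
        poly = ~(np.all(freqs == 0.0, axis=1) | np.all(freqs == 1.0, axis=1))
        out = out.loc[poly].reset_index(drop=True)
    n_dropped = len(all_ids) - len(out)
    if n_dropped:
        logger.info("HapMap merge: %d SNP(s) not shared by all populations or discarded", n_dropped)
    if len(out) == 0:
        raise EmptyInputError("no SNPs shared across all HapMap inputs")
    return VariantFrequencyTable(out, pops, n_dropped)


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, unique ``gene_id``."""

    genes: pd.DataFrame  # gene_id, chrom, start, end
    build_label: str = ""
    n_rejected: int = 0

    def __post_init__(self) -> None:
        need = ["gene_id", "chrom", "start", "end"]
        missing = [c for c in need if c not in self.genes.columns]
        if missing:
            raise FormatError(f"gene annotation missing column(s): {missing}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id: {dup}")
        bad = (self.genes["start"] > self.genes["end"]).sum()
        if bad:
            raise FormatError(f"{bad} gene record(s) with start > end")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.genes["gene_id"])


def read_gene_annotation(path, format: str = "bed", build_label: str = "") -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open) or normalized TSV.

    BED records are converted to 1-based inclusive (start+1, end). Records that
    are empty after conversion (zero-length BED intervals) are rejected with a
    diagnostic and counted.
    """
    path = Path(path)
    if format == "bed":
        try:
            df = pd.read_csv(
                path, sep=r"\s+", header=None, comment="#",
                names=["chrom", "start", "end", "gene_id"], usecols=[0, 1, 2, 3],
                dtype={"chrom": str, "gene_id": str},
            )
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"empty BED file: {path}") from None
        df["start"] = df["start"].astype(int) + 1
        df["end"] = df["end"].astype(int)
    elif format == "normalized_tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"empty annotation file: {path}") from None
    else:
        raise FormatError(f"unknown annotation format: {format!r}")
    if len(df) == 0:
        raise EmptyInputError(f"no records in annotation file: {path}")
    ok = df["start"] <= df["end"]
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d degenerate gene record(s) in %s", n_rejected, path)
    df = df.loc[ok, ["gene_id", "chrom", "start", "end"]].reset_index(drop=True)
    return GeneAnnotation(df, build_label=build_label, n_rejected=n_rejected)


def write_gene_annotation(annotation: GeneAnnotation, path, format: str = "bed") -> None:
    if format == "bed":
        out = annotation.genes.copy()
        out["start"] = out["start"] - 1
        out[["chrom", "start", "end", "gene_id"]].to_csv(path, sep="\t", index=False, header=False)
    elif format == "normalized_tsv":
        annotation.genes[["gene_id", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown annotation format: {format!r}")


_BOOL_LITERALS = {
    "true": True, "false": False, "yes": True, "no": False, "1": True, "0": False,
    "y": True, "n": False,
}


@dataclass
class AssociationCatalog:
    """Gene → phenotype evidence records.

    One row per (gene_id, phenotype) with ``n_publications`` (count of
    supporting publications), optional ``gwas_min_p`` (smallest reported
    genome-wide association p-value) and ``appropriately_distributed``
    (whether the phenotype's prevalence pattern matches the population
    design — a per-study judgment supplied as input, never inferred).
    """

    entries: pd.DataFrame  # gene_id, phenotype, n_publications, gwas_min_p, appropriately_distributed

    def __post_init__(self) -> None:
        need = ["gene_id", "phenotype", "n_publications", "appropriately_distributed"]
        missing = [c for c in need if c not in self.entries.columns]
        if missing:
            raise FormatError(f"association catalog missing column(s): {missing}")
        if "gwas_min_p" not in self.entries.columns:
            self.entries = self.entries.assign(gwas_min_p=np.nan)
        if (self.entries["n_publications"] < 0).any():
            raise FormatError("negative n_publications")
        p = self.entries["gwas_min_p"]
        if ((p <= 0) | (p > 1)).fillna(False).any():
            raise FormatError("gwas_min_p outside (0, 1]")

    def __len__(self) -> int:
        return len(self.entries)


def read_association_catalog(path) -> AssociationCatalog:
    """Read a gene/phenotype evidence TSV.

    Duplicate (gene, phenotype) rows are merged by maximum evidence:
    largest publication count, smallest GWAS p, boolean OR of the
    distribution flag.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "phenotype": str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty catalog file: {path}") from None
    need = ["gene_id", "phenotype", "n_publications", "appropriately_distributed"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"association catalog {path} missing column(s): {missing}")
    if "gwas_min_p" not in df.columns:
        df["gwas_min_p"] = np.nan

    def parse_bool(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        key = str(v).strip().lower()
        if key not in _BOOL_LITERALS:
            raise FormatError(f"unknown boolean literal {v!r} in appropriately_distributed")
        return _BOOL_LITERALS[key]

    df["appropriately_distributed"] = df["appropriately_distributed"].map(parse_bool)
    df["n_publications"] = pd.to_numeric(df["n_publications"]).astype(int)
    df["gwas_min_p"] = pd.to_numeric(df["gwas_min_p"], errors="coerce")
    merged = (
        df.groupby(["gene_id", "phenotype"], as_index=False)
        .agg(
            n_publications=("n_publications", "max"),
            gwas_min_p=("gwas_min_p", "min"),
            appropriately_distributed=("appropriately_distributed", "any"),
        )
    )
    return AssociationCatalog(merged)


def write_association_catalog(catalog: AssociationCatalog, path) -> None:
    cols = ["gene_id", "phenotype", "n_publications", "gwas_min_p", "appropriately_distributed"]
    catalog.entries[cols].to_csv(path, sep="\t", index=False)
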