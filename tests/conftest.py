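import numpy as np
import pandas as pd
import pytest

from evotri.io import GeneAnnotation, VariantFrequencyTable


def make_freq_table(rows, populations=("A", "B", "C")):
    """Build a VariantFrequencyTable from (snp_id, chrom, pos, {pop: (n, freq)})."""
    records = []
    for snp_id, chrom, pos, pop_data in rows:
        rec = {
            "snp_id": snp_id,
            "chrom": chrom,
            "pos": pos,
            "allele_ref": "A",
            "allele_alt": "G",
        }
        for pop, (n, f) in pop_data.items():
            rec[f"{pop}.n_chrom"] = float(n)
            rec[f"{pop}.freq_alt"] = float(f)
        records.append(rec)
    return VariantFrequencyTable(pd.DataFrame(records), tuple(populations))


def make_annotation(genes, build_label="test"):
    """Build a GeneAnnotation from (gene_id, chrom, start, end) tuples."""
    df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation(df, build_label=build_label)


@pytest.fixture
def small_freq_table():
    """Three SNPs, three populations, all defined."""
    return make_freq_table(
        [
            ("rs1", "chr1", 1000, {"A": (100, 0.9), "B": (120, 0.1), "C": (80, 0.15)}),
            ("rs2", "chr1", 2000, {"A": (100, 0.5), "B": (120, 0.5), "C": (80, 0.5)}),
            ("rs3", "chr2", 500, {"A": (100, 0.2), "B": (120, 0.8), "C": (80, 0.25)}),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_927)
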