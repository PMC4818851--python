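"""Per-SNP two-population Weir–Cockerham F_ST (theta) and percentile cutoffs.

The estimator is the 1984 Weir & Cockerham ANOVA theta in its allele-count
(haploid-draw) formulation, appropriate when the input is population allele
frequencies with sample sizes in allele copies and no genotype-level
heterozygote information. With r = 2 populations, sample sizes n1, n2 and
alternate-allele frequencies p1, p2:

    n_bar = (n1 + n2) / 2
    n_c   = n1 + n2 - (n1^2 + n2^2) / (n1 + n2)
    p_bar = (n1 p1 + n2 p2) / (n1 + n2)
    s^2   = [n1 (p1 - p_bar)^2 + n2 (p2 - p_bar)^2] / ((r-1) n_bar)
    X     = p_bar (1 - p_bar) - s^2 (r-1)/r
    b     = n_bar / (n_bar - 1) * X            (within-population component)
    a     = n_bar / n_c * (s^2 - X/(n_bar-1))  (among-population component)
    theta = a / (a + b)

theta is undefined (NaN) when a + b = 0, i.e. the pooled sample is
monomorphic. Negative estimates (expectation -1/(n-1) at equal sample
frequencies) are retained, not clamped: the empirical percentile ranking
used downstream needs the full distribution including its lower tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VariantFrequencyTable

__all__ = [
    "FstComponents",
    "PairwiseFstTable",
    "ThresholdSpec",
    "anova_components",
    "pairwise_theta",
    "pairwise_fst_table",
    "percentile_cutoff",
]


@dataclass(frozen=True)
class FstComponents:
    """ANOVA components of the two-population theta estimate."""

    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    a: float
    b: float
    r: int = 2


def _validate_scalar(n1: float, p1: float, n2: float, p2: float) -> None:
    for n in (n1, n2):
        if not math.isfinite(n) or n < 1:
            raise ValueError(f"sample size must be finite and >= 1, got {n}")
    for p in (p1, p2):
        if not math.isfinite(p) or not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency must be in [0, 1], got {p}")


def anova_components(n1: float, p1: float, n2: float, p2: float) -> FstComponents:
    """Weir–Cockerham variance components for one SNP and one population pair."""
    _validate_scalar(n1, p1, n2, p2)
    r = 2
    n_tot = n1 + n2
    n_bar = n_tot / 2.0
    n_c = n_tot - (n1 * n1 + n2 * n2) / n_tot
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    x = p_bar * (1.0 - p_bar) - s2 * (r - 1) / r
    if n_bar <= 1.0:
        # a single allele copy per population carries no within-population
        # information; components degenerate
        b = math.nan
        a = math.nan
    else:
        b = n_bar / (n_bar - 1.0) * x
        a = n_bar / n_c * (s2 - x / (n_bar - 1.0))
    return FstComponents(n_bar=n_bar, n_c=n_c, p_bar=p_bar, s2=s2, a=a, b=b, r=r)


def pairwise_theta(n1: float, p1: float, n2: float, p2: float) -> float:
    """Two-population Weir–Cockerham theta for one SNP.

    Returns NaN when the estimate is undefined (a + b = 0, pooled sample
    monomorphic). Negative values are retained.
    """
    c = anova_components(n1, p1, n2, p2)
    denom = c.a + c.b
    if not math.isfinite(denom) or denom == 0.0:
        return math.nan
    return c.a / denom


def theta_vector(
    n1: np.ndarray, p1: np.ndarray, n2: np.ndarray, p2: np.ndarray
) -> np.ndarray:
    """Vectorized theta over per-SNP arrays; NaN where undefined."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if np.any(~np.isfinite(n1)) or np.any(~np.isfinite(n2)) or np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("sample sizes must be finite and >= 1")
    if (
        np.any(~np.isfinite(p1)) or np.any(~np.isfinite(p2))
        or np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1))
    ):
        raise ValueError("allele frequencies must be in [0, 1]")
    r = 2
    n_tot = n1 + n2
    n_bar = n_tot / 2.0
    n_c = n_tot - (n1 * n1 + n2 * n2) / n_tot
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    x = p_bar * (1.0 - p_bar) - s2 * (r - 1) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        b = n_bar / (n_bar - 1.0) * x
        a = n_bar / n_c * (s2 - x / (n_bar - 1.0))
        theta = a / (a + b)
    theta = np.where((a + b) == 0.0, np.nan, theta)
    return theta


@dataclass
class PairwiseFstTable:
    """Per-SNP theta for one population pair.

    ``data`` has columns snp_id, chrom, pos, theta (NaN where undefined).
    """

    pair: tuple[str, str]
    data: pd.DataFrame
    defined_count: int

    def __len__(self) -> int:
        return len(self.data)

    @property
    def theta(self) -> np.ndarray:
        return self.data["theta"].to_numpy(float)

    def defined_theta(self) -> np.ndarray:
        t = self.theta
        return t[np.isfinite(t)]


def pairwise_fst_table(table: VariantFrequencyTable, pair: tuple[str, str]) -> PairwiseFstTable:
    """Theta for every SNP of ``table`` between the two named populations.

    Symmetric in the pair ordering. SNPs with missing data in either
    population yield NaN.
    """
    pop1, pop2 = pair
    for pop in (pop1, pop2):
        if pop not in table.populations:
            raise KeyError(f"unknown population label: {pop!r}")
    n1, f1 = table.n_chrom(pop1), table.freq(pop1)
    n2, f2 = table.n_chrom(pop2), table.freq(pop2)
    ok = np.isfinite(n1) & np.isfinite(n2) & np.isfinite(f1) & np.isfinite(f2)
    theta = np.full(len(table.data), np.nan)
    theta[ok] = theta_vector(n1[ok], f1[ok], n2[ok], f2[ok])
    out = table.data[["snp_id", "chrom", "pos"]].copy()
    out["theta"] = theta
    return PairwiseFstTable(pair=(pop1, pop2), data=out, defined_count=int(np.isfinite(theta).sum()))


def percentile_cutoff(values, q: float) -> float:
    """Nearest-rank percentile of the defined values.

    Returns the k-th smallest defined value with k = ceil(q/100 * N)
    (clamped to at least 1). NaNs are excluded before ranking. Downstream
    comparisons against the cutoff are inclusive (>= for high thresholds,
    <= for low ones).
    """
    v = np.asarray(values, float)
    v = np.sort(v[np.isfinite(v)])
    if v.size == 0:
        raise ValueError("percentile_cutoff: no defined values")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {q}")
    k = max(1, math.ceil(q / 100.0 * v.size))
    return float(v[k - 1])


@dataclass(frozen=True)
class ThresholdSpec:
    """Percentile pair defining one ET stringency level.

    ``q_high`` marks high differentiation for the two outlier pairs
    (upper-tail, in (50, 100]); ``q_low`` marks similarity for the
    remaining pair (lower-tail, in [0, 50)).
    """

    q_high: float
    q_low: float

    def __post_init__(self) -> None:
        if not 50.0 < self.q_high <= 100.0:
            raise ValueError(f"q_high must be in (50, 100], got {self.q_high}")
        if not 0.0 <= self.q_low < 50.0:
            raise ValueError(f"q_low must be in [0, 50), got {self.q_low}")
        if self.q_low >= self.q_high:
            raise ValueError("q_low must be below q_high")

    def __str__(self) -> str:
        def fmt(q: float) -> str:
            return f"{q:g}"

        return f"{fmt(self.q_high)}/{fmt(self.q_low)}"
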