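"""Independent reference implementations used only to check the package.

These are deliberately written from different formulations than the
implementation (ANOVA mean squares instead of the a/b variance components,
full sort instead of partial ranking) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import math

import numpy as np


def wc_theta_anova(n1: float, p1: float, n2: float, p2: float) -> float:
    """Weir-Cockerham theta via the one-way ANOVA mean squares.

    MSP (among populations) and MSG (within, per allele draw) with the
    effective-size coefficient n_c give theta = (MSP - MSG) /
    (MSP + (n_c - 1) MSG). NaN where the pooled sample is monomorphic.
    """
    n_tot = n1 + n2
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2  # df = r - 1 = 1
    if n_tot - 2 <= 0:
        return math.nan
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
    n_c = n_tot - (n1 * n1 + n2 * n2) / n_tot
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return math.nan
    return (msp - msg) / denom


def nearest_rank(values, q: float) -> float:
    """Nearest-rank percentile by full sort."""
    v = sorted(x for x in values if not math.isnan(x))
    k = max(1, math.ceil(q / 100.0 * len(v)))
    return v[k - 1]


def brute_force_et(thetas: dict, q_high: float, q_low: float) -> set:
    """Exhaustive three-way selection over {snp_id: (t_ab, t_ac, t_bc)}."""
    c_ab = nearest_rank([t[0] for t in thetas.values()], q_high)
    c_ac = nearest_rank([t[1] for t in thetas.values()], q_high)
    c_bc = nearest_rank([t[2] for t in thetas.values()], q_low)
    return {
        s
        for s, (t_ab, t_ac, t_bc) in thetas.items()
        if t_ab >= c_ab and t_ac >= c_ac and t_bc <= c_bc
    }


def genes_near_positions(starts, ends, gene_ids, positions, width: int) -> set:
    """Brute-force interval check: genes whose widened span holds a position."""
    out = set()
    for gid, s, e in zip(gene_ids, starts, ends):
        for pos in positions:
            if s - width <= pos <= e + width:
                out.add(gid)
                break
    return out
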