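"""Between-population comparisons of pooled 5hmCG counts.

Global levels of two nuclear fractions are compared with a Pearson
chi-square test (df=1, no continuity correction) on the 2x2 table of
protected vs converted read observations. Counts here are on the order of
10^5, so the continuity correction is immaterial. Raw counts are used:
protection-rate scaling multiplies a proportion, not a count, so a scaled
count test is not well defined. Two pairwise comparisons are reported with
raw p-values; multiple-testing correction is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .calibration import GlobalLevel
from .errors import DegenerateTableError, UndefinedRateError
from .metagene import MetageneProfile


@dataclass(frozen=True)
class PopulationComparison:
    """Chi-square comparison of two samples' global 5hmCG proportions."""

    sample_a: str
    sample_b: str
    table: tuple  # ((a_protected, a_converted), (b_protected, b_converted))
    statistic: float
    pvalue: float
    pct_difference: float  # a.pct - b.pct, raw percentage points


def chi_square_global(
    a: GlobalLevel, b: GlobalLevel, label_a: str = "a", label_b: str = "b"
) -> PopulationComparison:
    """Pearson chi-square (df=1, uncorrected) on pooled protected/converted counts."""
    table = np.array(
        [
            [a.total_5hmCG, a.total_CG - a.total_5hmCG],
            [b.total_5hmCG, b.total_CG - b.total_5hmCG],
        ],
        dtype=np.int64,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in 2x2 table {table.tolist()}")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return PopulationComparison(
        sample_a=label_a,
        sample_b=label_b,
        table=tuple(map(tuple, table.tolist())),
        statistic=float(stat),
        pvalue=float(p),
        pct_difference=a.pct_5hmCG - b.pct_5hmCG,
    )


def gene_body_fold_change(profile_hi: MetageneProfile, profile_lo: MetageneProfile) -> float:
    """Ratio of pooled gene-body weighted 5hmCG levels (high / low quintile).

    Levels are pooled over the 20 GB bins' counts within each profile before
    forming the ratio, so the fold is read-weighted and invariant to
    protection-rate scaling (the rate cancels).
    """
    if profile_hi.sample_id != profile_lo.sample_id:
        raise UndefinedRateError(
            "fold change requires profiles from the same sample "
            f"({profile_hi.sample_id!r} vs {profile_lo.sample_id!r})"
        )
    hi_p, hi_t = profile_hi.region_counts("GB")
    lo_p, lo_t = profile_lo.region_counts("GB")
    if hi_t == 0 or lo_t == 0:
        raise UndefinedRateError("gene-body region has no covered reads in one profile")
    lo_level = lo_p / lo_t
    if lo_level == 0:
        raise UndefinedRateError("low-quintile gene-body level is 0; fold undefined")
    return (hi_p / hi_t) / lo_level
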