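"""qRT-PCR-style relative quantification and sex-difference testing.

Expression is quantified per replicate as the ratio of target to reference
(housekeeping) copy numbers; sex differences are assessed with a pooled-
variance two-sample two-tailed Student's t-test at alpha = 0.01, with group
means and sample standard deviations (n-1 denominator) reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

DEFAULT_ALPHA = 0.01


def relative_expression(target_copies: float, reference_copies: float) -> float:
    """Per-replicate relative expression: target / reference copies."""
    if reference_copies <= 0:
        raise ValueError("reference copies must be positive")
    if target_copies < 0:
        raise ValueError("target copies must be non-negative")
    return target_copies / reference_copies


@dataclass(frozen=True)
class SexBiasResult:
    gene_id: str
    female_mean: float
    female_sd: float
    female_n: int
    male_mean: float
    male_sd: float
    male_n: int
    t_statistic: float
    df: int
    p_value: float
    alpha: float
    significant: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def sex_bias_test(
    female: Sequence[float],
    male: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    gene_id: str = "",
) -> SexBiasResult:
    """Pooled-variance two-tailed t-test between female and male replicates.

    Degrees of freedom are n1 + n2 - 2. With zero pooled variance the test
    statistic is undefined: equal means give p = 1 (no evidence of a
    difference), unequal means give p = 0; both are flagged degenerate.
    """
    f = np.asarray(female, dtype=float)
    m = np.asarray(male, dtype=float)
    if len(f) < 2 or len(m) < 2:
        raise ValueError("each group needs at least 2 replicates")
    df = len(f) + len(m) - 2
    pooled_var = (
        (len(f) - 1) * f.var(ddof=1) + (len(m) - 1) * m.var(ddof=1)
    ) / df
    if pooled_var == 0.0:
        if f.mean() == m.mean():
            t, p, degenerate = 0.0, 1.0, True
        else:
            t = math.copysign(math.inf, f.mean() - m.mean())
            p, degenerate = 0.0, True
    else:
        res = sp_stats.ttest_ind(f, m, equal_var=True)
        t, p, degenerate = float(res.statistic), float(res.pvalue), False
    return SexBiasResult(
        gene_id=gene_id,
        female_mean=float(f.mean()),
        female_sd=float(f.std(ddof=1)),
        female_n=len(f),
        male_mean=float(m.mean()),
        male_sd=float(m.std(ddof=1)),
        male_n=len(m),
        t_statistic=t,
        df=df,
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
        degenerate=degenerate,
    )
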