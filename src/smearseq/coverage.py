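"""Amplicon-panel coverage QC and the exact rank-sum test.

Coverage summaries follow targeted-panel convention: the per-sample median
of per-amplicon mean coverage, uniformity as the fraction of amplicons whose
mean coverage exceeds 20% of that median (strict ">", per the "more than 20%
median coverage" definition), and normalized coverage as mean coverage over
the median.  Normalizing by the median rather than the mean keeps the
summary robust to a few very hot amplicons and anchors it to the same
quantity the uniformity cutoff uses.

`mwu_exact` is the two-sided Mann-Whitney U test with an exact null: for
small groups (n_a + n_b <= 14) the U distribution is enumerated over all
C(n_a+n_b, n_a) assignments of the pooled (mid)ranks, ties handled by
midranks; larger inputs fall back to the normal approximation with tie
correction.  With two groups of five and complete separation the exact
two-sided p is 2/252 ~ 0.0079.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AmpliconCoverage:
    """Mean read coverage of one panel amplicon."""

    amplicon_id: str
    chrom: str
    start: int
    end: int
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for amplicon {self.amplicon_id}")
        if self.mean_coverage < 0:
            raise ValueError(f"negative coverage for amplicon {self.amplicon_id}")


def read_amplicon_tsv(path: str) -> list[AmpliconCoverage]:
    """Read a per-amplicon coverage table (amplicon_id, chrom, start, end,
    mean_coverage)."""
    df = pd.read_csv(path, sep="\t")
    required = {"amplicon_id", "chrom", "start", "end", "mean_coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        AmpliconCoverage(
            str(r.amplicon_id), str(r.chrom), int(r.start), int(r.end), float(r.mean_coverage)
        )
        for r in df.itertuples()
    ]


def coverage_summary(
    amplicons: Sequence[AmpliconCoverage],
) -> tuple[float, float, pd.DataFrame]:
    """Median coverage, uniformity, and per-amplicon normalized coverage.

    uniformity = fraction of amplicons with mean coverage > 0.2 x median;
    normalized coverage = mean coverage / median.  Scaling all coverages by
    a positive constant leaves both unchanged.
    """
    if not amplicons:
        raise ValueError("empty amplicon list")
    cov = np.array([a.mean_coverage for a in amplicons], dtype=float)
    median = float(np.median(cov))
    if median == 0:
        raise ValueError("median coverage is zero: normalized coverage undefined")
    uniformity = float(np.mean(cov > 0.2 * median))
    table = pd.DataFrame(
        {
            "amplicon_id": [a.amplicon_id for a in amplicons],
            "chrom": [a.chrom for a in amplicons],
            "start": [a.start for a in amplicons],
            "end": [a.end for a in amplicons],
            "mean_coverage": cov,
            "normalized_coverage": cov / median,
        }
    )
    return median, uniformity, table


def mwu_exact(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value with an exact small-sample null.

    The exact p is the doubled smaller one-sided tail of the U distribution
    enumerated over all rank assignments (midranks for ties), capped at 1.
    For n_a + n_b > 14 the normal approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    if n > 14:
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    rank_sum_a = ranks[:n_a].sum()
    u_obs = rank_sum_a - n_a * (n_a + 1) / 2.0

    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        total += 1
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return float(min(1.0, p))
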