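"""Algorithmic selection of the smear-noise VAF boundary.

Smear-specific artifact calls accumulate below a low-VAF boundary while
genuine shared variants do not.  Visual inspection of the post-subtraction
VAF distribution puts that boundary around 2.5%; this module replaces the
visual call with a reproducible rule:

* bin the VAF axis into half-open bins ``[k*step, (k+1)*step)`` up to a
  search ceiling;
* per bin compute the enrichment ratio
  ``r_b = n_smear_unique(b) / (n_shared(b) + 1)`` — the +1 regularizes empty
  shared bins so that sparse shared counts cannot create division-by-zero or
  spurious runs;
* the boundary is the upper edge of the last bin of the maximal initial
  contiguous run with ``r_b >= rho``; if the very first bin already fails,
  no boundary is reported.

Because the statistic is a ratio, the estimate is invariant to duplicating
every input VAF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class BoundaryEstimate:
    """Selected noise boundary plus the per-bin evidence behind it."""

    boundary: Optional[float]
    grid_step: float
    table: pd.DataFrame  # columns: bin_low, bin_high, n_smear_unique, n_shared, ratio
    rho: float
    vaf_max: float

    def boundary_percent(self) -> Optional[float]:
        return None if self.boundary is None else 100.0 * self.boundary


def estimate_noise_boundary(
    smear_unique_vafs: Sequence[float],
    shared_vafs: Sequence[float],
    grid_step: float = 0.005,
    vaf_max: float = 0.10,
    rho: float = 2.0,
) -> BoundaryEstimate:
    """Estimate the VAF below which smear-unique calls are noise.

    Parameters
    ----------
    smear_unique_vafs, shared_vafs
        VAFs (fractions) of post-subtraction smear-unique and shared calls.
    grid_step
        Bin width on the VAF axis (default 0.5%).
    vaf_max
        Search ceiling (default 10%); artifacts above it are not modeled.
    rho
        Minimum per-bin enrichment of smear-unique over shared calls for a
        bin to count as noise-dominated.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not 0 < vaf_max <= 1:
        raise ValueError("vaf_max must lie in (0, 1]")
    n_bins = int(round(vaf_max / grid_step))

    def _bin_counts(vafs: Sequence[float]) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=int)
        if len(vafs):
            idx = np.floor(np.asarray(vafs, dtype=float) / grid_step).astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(counts, idx, 1)
        return counts

    n_unique = _bin_counts(smear_unique_vafs)
    n_shared = _bin_counts(shared_vafs)
    ratio = n_unique / (n_shared + 1)

    edges_low = np.round(np.arange(n_bins) * grid_step, 10)
    edges_high = np.round(np.arange(1, n_bins + 1) * grid_step, 10)
    table = pd.DataFrame(
        {
            "bin_low": edges_low,
            "bin_high": edges_high,
            "n_smear_unique": n_unique,
            "n_shared": n_shared,
            "ratio": ratio,
        }
    )

    boundary: Optional[float] = None
    if len(smear_unique_vafs):
        run_end = -1
        for b in range(n_bins):
            if ratio[b] >= rho:
                run_end = b
            else:
                break
        if run_end >= 0:
            boundary = float(edges_high[run_end])

    return BoundaryEstimate(
        boundary=boundary, grid_step=grid_step, table=table, rho=rho, vaf_max=vaf_max
    )
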