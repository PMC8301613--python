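"""Paired smear/BMC call concordance.

Classifies the calls of a smear/BMC pair into shared, smear-unique and
BMC-unique variants by normalized key, and summarizes their VAF x depth
structure.  Degraded smear DNA produces excess smear-unique low-VAF calls;
the partition is the raw material for the noise-reduction cascade and for
judging how faithfully a smear reproduces the fresh-cell call set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .variants import CallSet, VariantCall


@dataclass
class PairedComparison:
    """Three-way partition of one smear/BMC pair by normalized key."""

    pair_id: str
    shared: list[tuple[VariantCall, VariantCall]] = field(default_factory=list)
    smear_unique: list[VariantCall] = field(default_factory=list)
    bmc_unique: list[VariantCall] = field(default_factory=list)

    def shared_keys(self) -> set:
        return {s.key for s, _ in self.shared}


def classify_paired(smear: CallSet, bmc: CallSet, pair_id: str | None = None) -> PairedComparison:
    """Partition a smear/BMC pair into shared / smear-unique / BMC-unique.

    Matching is by normalized key equality.  Swapping the inputs swaps the
    two unique sets and leaves the shared set unchanged.
    """
    if smear.caller_class != bmc.caller_class:
        raise ValueError(
            f"caller_class mismatch: {smear.caller_class!r} vs {bmc.caller_class!r}"
        )
    s_by, b_by = smear.by_key(), bmc.by_key()
    shared_keys = sorted(s_by.keys() & b_by.keys())
    return PairedComparison(
        pair_id=pair_id or f"{smear.sample_id}|{bmc.sample_id}",
        shared=[(s_by[k], b_by[k]) for k in shared_keys],
        smear_unique=[v for v in smear if v.key not in b_by],
        bmc_unique=[v for v in bmc if v.key not in s_by],
    )


def concordance_fractions(
    cmp: Union[PairedComparison, Sequence[PairedComparison]],
) -> dict[str, float]:
    """Fractions of union keys that are shared / smear-unique / BMC-unique.

    The denominator is the number of distinct keys in the union of the pair
    (a shared variant counts once).  A list of comparisons is pooled by
    concatenating per-pair partitions before computing, without
    re-deduplicating across patients.
    """
    cmps = [cmp] if isinstance(cmp, PairedComparison) else list(cmp)
    n_shared = sum(len(c.shared) for c in cmps)
    n_smear = sum(len(c.smear_unique) for c in cmps)
    n_bmc = sum(len(c.bmc_unique) for c in cmps)
    total = n_shared + n_smear + n_bmc
    if total == 0:
        raise ValueError("empty union: no variants to classify")
    return {
        "shared": n_shared / total,
        "smear_unique": n_smear / total,
        "bmc_unique": n_bmc / total,
        "n_shared": n_shared,
        "n_smear_unique": n_smear,
        "n_bmc_unique": n_bmc,
    }


def vaf_concordance(cmp: PairedComparison) -> tuple[pd.DataFrame, float, float]:
    """VAF agreement of shared variants between BMC (x) and smear (y).

    Returns (table, max |smear VAF - BMC VAF|, Pearson r).  The correlation
    is NaN when fewer than 3 shared points exist or either side has zero
    variance.
    """
    if not cmp.shared:
        raise ValueError("no shared variants: VAF concordance undefined")
    rows = [
        {
            "pair_id": cmp.pair_id,
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "bmc_vaf": b.vaf,
            "smear_vaf": s.vaf,
        }
        for s, b in cmp.shared
    ]
    table = pd.DataFrame(rows)
    diffs = (table["smear_vaf"] - table["bmc_vaf"]).abs()
    max_diff = float(diffs.max())
    x, y = table["bmc_vaf"].to_numpy(), table["smear_vaf"].to_numpy()
    if len(table) >= 3 and x.std() > 0 and y.std() > 0:
        corr = float(np.corrcoef(x, y)[0, 1])
    else:
        corr = float("nan")
    return table, max_diff, corr


def vaf_depth_table(cmp: PairedComparison) -> pd.DataFrame:
    """Long-format (vaf, depth, class) table, one row per variant.

    VAF is exported in percent, matching how the results are reported.
    """
    rows = []

    def _row(v: VariantCall, cls: str) -> dict:
        return {
            "pair_id": cmp.pair_id,
            "class": cls,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "vaf_percent": 100.0 * v.vaf,
            "depth": v.depth,
        }

    for s, _b in cmp.shared:
        rows.append(_row(s, "shared"))
    for v in cmp.smear_unique:
        rows.append(_row(v, "smear_unique"))
    for v in cmp.bmc_unique:
        rows.append(_row(v, "bmc_unique"))
    cols = ["pair_id", "class", "chrom", "pos", "ref", "alt", "vaf_percent", "depth"]
    return pd.DataFrame(rows, columns=cols)
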