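"""The noise-reduction cascade.

Smear-derived DNA yields abundant low-VAF artifact calls.  The cascade
removes them in a fixed order:

1. caller-flag filter (somatic-style calls: keep FILTER == PASS) or hard
   filters on QD / MQ / FS annotations (germline-style calls),
2. panel-of-normals (PON) subtraction — keys recurring in >= ``min_samples``
   tumor-free samples are assay artifacts,
3. VAF threshold — calls below the noise boundary (default 2.5%) are removed,
4. population-frequency exclusion — common polymorphisms (population
   prevalence strictly greater than 1%) are removed.

Each stage returns (retained CallSet, removed records); `run_cascade`
assembles them into a :class:`FilterReport` with conserved counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .variants import GERMLINE, SOMATIC, CallSet, VariantCall, VariantKey

logger = logging.getLogger(__name__)


@dataclass
class PanelOfNormals:
    """Multiset of normalized variant keys seen across tumor-free samples."""

    entries: dict[VariantKey, int]
    n_samples: int
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        bad = {k: c for k, c in self.entries.items() if not 1 <= c <= self.n_samples}
        if bad:
            raise ValueError(f"PON counts outside [1, n_samples]: {bad}")

    def is_subtractable(self, key: VariantKey) -> bool:
        return self.entries.get(key, 0) >= self.min_samples


@dataclass
class CascadeConfig:
    """Thresholds of the cascade; defaults follow common practice and are
    all overridable from the run configuration."""

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    vaf_threshold: float = 0.025
    pop_af_max: float = 0.01


@dataclass
class FilterReport:
    """Removed/retained counts per stage, in the order applied."""

    n_input: int = 0
    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, removed, retained)

    def add(self, name: str, removed: int, retained: int) -> None:
        prev_retained = self.stages[-1][2] if self.stages else self.n_input
        if removed + retained != prev_retained:
            raise ValueError(
                f"count conservation violated at stage {name!r}: "
                f"{removed}+{retained} != {prev_retained}"
            )
        self.stages.append((name, removed, retained))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "removed", "retained"])

    def to_json(self) -> str:
        return json.dumps(
            [{"stage": s, "removed": r, "retained": k} for s, r, k in self.stages],
            indent=2,
        )


def _split(cs: CallSet, keep) -> tuple[CallSet, list[VariantCall]]:
    kept, removed = [], []
    for v in cs:
        (kept if keep(v) else removed).append(v)
    return cs.with_variants(kept), removed


def apply_flag_filter(cs: CallSet) -> tuple[CallSet, list[VariantCall]]:
    """Keep exactly the records whose FILTER is PASS (upstream caller
    filtering, e.g. FilterMutectCalls, consumed via the FILTER column)."""
    return _split(cs, lambda v: v.is_pass)


def apply_hard_filters(
    cs: CallSet, qd_min: float = 2.0, mq_min: float = 40.0, fs_max: float = 60.0
) -> tuple[CallSet, list[VariantCall]]:
    """Hard-filter germline-style calls on quality/depth (QD), mapping
    quality (MQ) and strand bias (FS).  Missing annotations pass."""
    if qd_min < 0 or mq_min < 0 or fs_max < 0:
        raise ValueError("hard-filter thresholds must be non-negative")
    if cs.caller_class != GERMLINE:
        raise ValueError("hard filters apply to germline-style call sets")

    def keep(v: VariantCall) -> bool:
        qd, mq, fs = v.info.get("QD"), v.info.get("MQ"), v.info.get("FS")
        if qd is not None and qd < qd_min:
            return False
        if mq is not None and mq < mq_min:
            return False
        if fs is not None and fs > fs_max:
            return False
        return True

    return _split(cs, keep)


def build_pon(normals: Iterable[CallSet], min_samples: int = 2) -> PanelOfNormals:
    """Merge tumor-free call sets into a panel of normals keyed by
    normalized variant, with per-key member counts."""
    normals = list(normals)
    if not normals:
        raise ValueError("cannot build a PON from zero normal samples")
    counts: dict[VariantKey, int] = {}
    for cs in normals:
        for key in cs.keys():
            counts[key] = counts.get(key, 0) + 1
    return PanelOfNormals(entries=counts, n_samples=len(normals), min_samples=min_samples)


def subtract_pon(cs: CallSet, pon: PanelOfNormals) -> tuple[CallSet, list[VariantCall]]:
    """Remove calls whose key recurs in >= min_samples normals."""
    return _split(cs, lambda v: not pon.is_subtractable(v.key))


def filter_vaf(cs: CallSet, threshold: float) -> tuple[CallSet, list[VariantCall]]:
    """Remove calls with VAF strictly below the noise boundary."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"VAF threshold must lie in [0, 1], got {threshold}")
    return _split(cs, lambda v: v.vaf >= threshold)


def filter_population_af(cs: CallSet, max_af: float = 0.01) -> tuple[CallSet, list[VariantCall]]:
    """Remove calls with population prevalence strictly greater than
    ``max_af``; calls without a population frequency are kept."""
    return _split(cs, lambda v: v.population_af is None or v.population_af <= max_af)


def classify_region(v: VariantCall) -> str:
    """Classify a filtered call as ``SNP``, ``exon+splice`` or ``intron``.

    Known-polymorphism status dominates; exonic or splice-proximal calls
    (annotated within 2 bases of an exon boundary) are ``exon+splice``;
    everything else is ``intron``.
    """
    if v.known_snp:
        return "SNP"
    if v.region == "exon" or v.region == "splice":
        return "exon+splice"
    exon_dist = v.info.get("EXON_DIST")
    if v.region == "intron" and exon_dist is not None and abs(int(exon_dist)) <= 2:
        return "exon+splice"
    if v.region == "unknown":
        logger.warning("variant %s has no region annotation; classified as intron", v.key)
    return "intron"


def run_cascade(
    cs: CallSet,
    pon: Optional[PanelOfNormals],
    config: CascadeConfig | None = None,
) -> tuple[CallSet, FilterReport]:
    """Run the full cascade in fixed order and account for every record.

    Somatic-style call sets start with the caller-flag filter, germline-style
    with the hard filters.  A ``None`` panel skips nothing: it behaves as an
    empty panel (identity).
    """
    config = config or CascadeConfig()
    report = FilterReport(n_input=len(cs))

    if cs.caller_class == SOMATIC:
        cs, removed = apply_flag_filter(cs)
        report.add("caller_flags", len(removed), len(cs))
    else:
        cs, removed = apply_hard_filters(cs, config.qd_min, config.mq_min, config.fs_max)
        report.add("hard_filters", len(removed), len(cs))

    if pon is None:
        pon = PanelOfNormals(entries={}, n_samples=1, min_samples=1)
    cs, removed = subtract_pon(cs, pon)
    report.add("pon_subtraction", len(removed), len(cs))

    cs, removed = filter_vaf(cs, config.vaf_threshold)
    report.add("vaf_threshold", len(removed), len(cs))

    cs, removed = filter_population_af(cs, config.pop_af_max)
    report.add("population_af", len(removed), len(cs))

    return cs, report
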