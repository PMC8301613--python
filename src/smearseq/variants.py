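"""Core domain types for variant calls and per-sample call sets.

A :class:`VariantCall` is one normalized allele substitution or indel with
its variant allele frequency (VAF, stored as a fraction in [0, 1]; reports
print percent), read depth, caller filter flags and annotations.  A
:class:`CallSet` collects the calls of one (sample, tissue, caller) triple
under unique normalized keys so calls from different callers and samples
become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

GERMLINE = "germline"
SOMATIC = "somatic"
CALLER_CLASSES = (GERMLINE, SOMATIC)

SMEAR = "smear"
BMC = "bmc"
TISSUES = (SMEAR, BMC)

#: normalized variant key: (chrom, pos, ref, alt)
VariantKey = tuple[str, int, str, str]


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Reduce an allele pair to minimal representation.

    Trims the longest shared suffix, then the longest shared prefix while
    keeping at least one base in each allele, advancing ``pos`` by the number
    of prefix bases trimmed.  Idempotent.  No reference-genome left-alignment
    is attempted (documented limitation): matching relies on callers reporting
    indels at the same anchor.

    >>> normalize_variant("chr1", 100, "TC", "TA")
    ('chr1', 101, 'C', 'A')
    >>> normalize_variant("chr1", 100, "CTT", "CT")
    ('chr1', 100, 'CT', 'C')
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if ref == alt:
        raise ValueError(f"not a variant: ref == alt == {ref!r}")
    # shared suffix, keep >=1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix, keep >=1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), int(pos), ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One normalized variant observation in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    filter_flags: frozenset[str] = frozenset({"PASS"})
    caller_class: str = SOMATIC
    gene: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    population_af: Optional[float] = None
    region: str = "unknown"  # exon | splice | intron | unknown
    known_snp: bool = False
    info: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"invalid allele pair {self.ref!r}/{self.alt!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.caller_class not in CALLER_CLASSES:
            raise ValueError(f"unknown caller_class {self.caller_class!r}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError(f"population_af must lie in [0, 1], got {self.population_af}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_pass(self) -> bool:
        return self.filter_flags == frozenset({"PASS"})

    def normalized(self) -> "VariantCall":
        chrom, pos, ref, alt = normalize_variant(self.chrom, self.pos, self.ref, self.alt)
        if (chrom, pos, ref, alt) == self.key:
            return self
        return replace(self, chrom=chrom, pos=pos, ref=ref, alt=alt)


@dataclass
class CallSet:
    """All calls for one (sample, tissue, caller class), unique by key."""

    sample_id: str
    tissue: str
    caller_class: str
    variants: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.caller_class not in CALLER_CLASSES:
            raise ValueError(f"unknown caller_class {self.caller_class!r}")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate normalized keys in CallSet {self.sample_id}")
        for v in self.variants:
            if v.caller_class != self.caller_class:
                raise ValueError(
                    f"variant {v.key} has caller_class {v.caller_class!r}, "
                    f"CallSet is {self.caller_class!r}"
                )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def keys(self) -> set[VariantKey]:
        return {v.key for v in self.variants}

    def by_key(self) -> dict[VariantKey, VariantCall]:
        return {v.key: v for v in self.variants}

    def with_variants(self, variants: Iterable[VariantCall]) -> "CallSet":
        return CallSet(self.sample_id, self.tissue, self.caller_class, list(variants))


def build_callset(
    records: Iterable[VariantCall], sample_id: str, tissue: str, caller_class: str
) -> CallSet:
    """Assemble a CallSet from already-normalized records.

    Duplicates by key are collapsed to the record with greater depth (the
    better-supported observation).  Mixed caller classes are an error.
    """
    best: dict[VariantKey, VariantCall] = {}
    for rec in records:
        if rec.caller_class != caller_class:
            raise ValueError(
                f"record {rec.key} has caller_class {rec.caller_class!r}, "
                f"expected {caller_class!r}"
            )
        prev = best.get(rec.key)
        if prev is None or rec.depth > prev.depth:
            best[rec.key] = rec
    return CallSet(sample_id, tissue, caller_class, list(best.values()))
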