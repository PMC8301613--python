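"""Two-caller fusion-gene consensus and ISCN karyotype concordance.

Targeted RNA sequencing of smear-derived RNA is run through two independent
fusion detectors (caller "A", JAFFA-like; caller "B", STAR-Fusion-like).
A fusion is called positive only when both detectors report the gene pair
AND its expression proxy — supporting reads per million mapped reads
(RPM) — clears a threshold; single-caller observations are decoys.

The positive calls are then checked against the patient's conventional
cytogenetics: an ISCN karyotype string is parsed for translocation
``t(a;b)(band;band)`` and inversion ``inv(c)(band1band2)`` tokens, and a
fusion is concordant when some rearrangement involves the chromosomes of
both partner genes with matching bands.  Band matching is at arm +
major-band prefix level (q22 matches q22.1) because ISCN resolution varies
between cytogenetics reports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CALLER_A = "A"
CALLER_B = "B"

#: Cytogenetic loci of the panel's fusion driver genes (chromosome, band).
GENE_CYTOBAND: dict[str, tuple[str, str]] = {
    "RUNX1": ("21", "q22"),
    "RUNX1T1": ("8", "q22"),
    "CBFB": ("16", "q22"),
    "MYH11": ("16", "p13"),
    "KMT2A": ("11", "q23"),
    "MLLT10": ("10", "p12"),
    "MLLT3": ("9", "p21"),
    "ETV6": ("12", "p13"),
    "CHIC2": ("4", "q12"),
    "NUP214": ("9", "q34"),
    "ABL1": ("9", "q34"),
    "ABL": ("9", "q34"),  # legacy symbol used in clinical reports
    "BCR": ("22", "q11"),
    "PML": ("15", "q24"),
    "RARA": ("17", "q21"),
    "DEK": ("6", "p22"),
    "NUP98": ("11", "p15"),
    "MECOM": ("3", "q26"),
    "GATA2": ("3", "q21"),
    "PDGFRA": ("4", "q12"),
    "PDGFRB": ("5", "q32"),
    "FGFR1": ("8", "p11"),
    "MYST3": ("8", "p11"),
    "CREBBP": ("16", "p13"),
}


@dataclass(frozen=True)
class FusionEvidence:
    """One caller's observation of a candidate fusion in one sample."""

    sample_id: str
    caller_id: str
    gene5: str
    gene3: str
    breakpoint5: str = ""
    breakpoint3: str = ""
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.caller_id not in (CALLER_A, CALLER_B):
            raise ValueError(f"caller_id must be 'A' or 'B', got {self.caller_id!r}")
        if self.gene5 == self.gene3:
            raise ValueError(f"fusion partners must differ, got {self.gene5}")
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.gene5, self.gene3})


@dataclass
class FusionResult:
    """Consensus decision for one gene pair in one sample."""

    sample_id: str
    gene_pair: tuple[str, str]  # (5', 3') as reported by the first caller seen
    rpm: float
    callers_detected: frozenset[str]
    positive: bool
    karyotype_concordant: Optional[bool] = None  # None = undetermined

    @property
    def label(self) -> str:
        return f"{self.gene_pair[0]}-{self.gene_pair[1]}"


@dataclass(frozen=True)
class Rearrangement:
    """One cytogenetic rearrangement token from an ISCN karyotype."""

    kind: str  # "translocation" | "inversion"
    chroms: tuple[str, ...]
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "translocation" and len(self.chroms) != 2:
            raise ValueError("translocation needs two chromosomes")
        if self.kind == "inversion" and len(self.chroms) != 1:
            raise ValueError("inversion needs one chromosome")


def compute_rpm(supporting_reads: int, mapped_reads: int) -> float:
    """Supporting reads per million mapped reads."""
    if mapped_reads <= 0:
        raise ValueError(f"mapped_reads must be positive, got {mapped_reads}")
    return supporting_reads / mapped_reads * 1e6


def consensus_call(
    evidence: Iterable[FusionEvidence],
    mapped_reads: int,
    rpm_min: float = 1000.0,
) -> list[FusionResult]:
    """Merge both callers' evidence for one sample into consensus calls.

    Gene pairs are matched order-insensitively between callers (5'/3'
    conventions differ).  A pair is positive iff both callers detected it
    AND its RPM — computed from the larger supporting-read count of the
    two callers — reaches ``rpm_min``.
    """
    evidence = list(evidence)
    samples = {e.sample_id for e in evidence}
    if len(samples) > 1:
        raise ValueError(f"evidence spans multiple samples: {sorted(samples)}")
    by_pair: dict[frozenset[str], list[FusionEvidence]] = {}
    order: list[frozenset[str]] = []
    for e in evidence:
        if e.pair not in by_pair:
            by_pair[e.pair] = []
            order.append(e.pair)
        by_pair[e.pair].append(e)

    results = []
    for pair in order:
        evs = by_pair[pair]
        callers = frozenset(e.caller_id for e in evs)
        support = max(e.supporting_reads for e in evs)
        rpm = compute_rpm(support, mapped_reads)
        first = evs[0]
        results.append(
            FusionResult(
                sample_id=first.sample_id,
                gene_pair=(first.gene5, first.gene3),
                rpm=rpm,
                callers_detected=callers,
                positive=(callers == frozenset({CALLER_A, CALLER_B}) and rpm >= rpm_min),
            )
        )
    return results


_TRANSLOCATION_RE = re.compile(
    r"t\((?P<c1>[0-9XY]+);(?P<c2>[0-9XY]+)\)\((?P<b1>[pq][0-9.]*);(?P<b2>[pq][0-9.]*)\)"
)
_INVERSION_RE = re.compile(
    r"inv\((?P<c>[0-9XY]+)\)\((?P<b1>[pq][0-9.]*)(?P<b2>[pq][0-9.]*)\)"
)

def parse_karyotype(iscn: str) -> list[Rearrangement]:
    """Extract translocations and inversions from an ISCN karyotype string.

    All clones (slash-separated) are scanned; cell counts in brackets,
    gains/losses (+8, -Y), and add/del/mar/idem tokens are ignored.
    Unparseable rearrangement-like tokens are skipped with a warning, never
    fatally.
    """
    rearrs: list[Rearrangement] = []
    seen: set[tuple] = set()
    matched_spans: list[tuple[int, int]] = []
    for m in _TRANSLOCATION_RE.finditer(iscn):
        matched_spans.append(m.span())
        key = ("translocation", m["c1"], m["c2"], m["b1"], m["b2"])
        if key in seen:
            continue
        seen.add(key)
        rearrs.append(
            Rearrangement("translocation", (m["c1"], m["c2"]), (m["b1"], m["b2"]))
        )
    for m in _INVERSION_RE.finditer(iscn):
        matched_spans.append(m.span())
        key = ("inversion", m["c"], m["b1"], m["b2"])
        if key in seen:
            continue
        seen.add(key)
        rearrs.append(Rearrangement("inversion", (m["c"],), (m["b1"], m["b2"])))
    # warn on t(...)/inv(...) shapes that did not parse (e.g. missing band lists)
    for m in re.finditer(r"(?<![a-z])(t|inv)\([^)]*\)(?!\()", iscn):
        if not any(lo <= m.start() < hi for lo, hi in matched_spans):
            logger.warning("skipping unparseable karyotype token %r in %r", m.group(0), iscn)
    return rearrs


def _band_major(band: str) -> str:
    """Arm + major band: 'q22.1' -> 'q22'."""
    m = re.match(r"([pq])(\d+)", band)
    return f"{m[1]}{m[2]}" if m else band


def _bands_match(stated: str, gene_band: str) -> bool:
    return _band_major(stated) == _band_major(gene_band)


def karyotype_concordance(
    result: FusionResult,
    rearrangements: Sequence[Rearrangement],
    locus_table: Optional[dict[str, tuple[str, str]]] = None,
) -> Optional[bool]:
    """Is a fusion call reflected in the karyotype?

    True iff some rearrangement involves the chromosomes of both partner
    genes and each stated band matches the corresponding partner band at
    arm + major-band level.  A normal karyotype, or no matching token,
    gives False.  A partner gene missing from the locus table gives None
    (undetermined), never False.
    """
    table = locus_table if locus_table is not None else GENE_CYTOBAND
    g1, g2 = result.gene_pair
    if g1 not in table or g2 not in table:
        logger.warning("gene(s) missing from locus table for %s", result.label)
        return None
    (chrom1, band1), (chrom2, band2) = table[g1], table[g2]
    for r in rearrangements:
        if r.kind == "translocation":
            pairings = [
                ((r.chroms[0], r.bands[0]), (r.chroms[1], r.bands[1])),
                ((r.chroms[1], r.bands[1]), (r.chroms[0], r.bands[0])),
            ]
            for (ca, ba), (cb, bb) in pairings:
                if (
                    ca == chrom1
                    and cb == chrom2
                    and _bands_match(ba, band1)
                    and _bands_match(bb, band2)
                ):
                    return True
        else:  # inversion: both partners on the one inverted chromosome
            if r.chroms[0] == chrom1 == chrom2:
                stated = {_band_major(b) for b in r.bands}
                if {_band_major(band1), _band_major(band2)} <= stated:
                    return True
    return False


# ---------------------------------------------------------------------------
# Caller-output table dialects
# ---------------------------------------------------------------------------

def read_caller_a_tsv(path: str) -> list[FusionEvidence]:
    """Caller-A dialect: columns sample_id, fusion_genes ('G1:G2'),
    spanning_reads."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        g5, g3 = str(r.fusion_genes).split(":", 1)
        out.append(
            FusionEvidence(
                sample_id=str(r.sample_id),
                caller_id=CALLER_A,
                gene5=g5,
                gene3=g3,
                supporting_reads=int(r.spanning_reads),
            )
        )
    return out


def read_caller_b_tsv(path: str) -> list[FusionEvidence]:
    """Caller-B dialect: columns sample_id, left_gene, right_gene,
    junction_reads."""
    df = pd.read_csv(path, sep="\t")
    return [
        FusionEvidence(
            sample_id=str(r.sample_id),
            caller_id=CALLER_B,
            gene5=str(r.left_gene),
            gene3=str(r.right_gene),
            supporting_reads=int(r.junction_reads),
        )
        for r in df.itertuples()
    ]
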