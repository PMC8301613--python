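"""HGVS-c span arithmetic for indels and internal tandem duplications.

Covers exactly the coding-DNA subset that clinical myeloid-panel reports
use: point substitutions (including splice-region positions such as
``c.802-2A>T``), ``dup``/``del`` spans with or without a stated sequence,
and ``ins`` with a stated sequence.  The useful output is length
arithmetic: an in-frame duplication of 48 nt (``c.1747_1794dup``) is a
16-amino-acid ITD.  Frameshift consequence naming is not computed; the
protein-level string is carried as annotation only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import pandas as pd

_SNV_RE = re.compile(
    r"^c\.(?P<pos>[-*]?\d+(?:[+-]\d+)?)(?P<ref>[ACGT])>(?P<alt>[ACGT])$"
)
_SPAN_RE = re.compile(
    r"^c\.(?P<start>[-*]?\d+(?:[+-]\d+)?)"
    r"(?:_(?P<end>[-*]?\d+(?:[+-]\d+)?))?"
    r"(?P<kind>dup|delins|del|ins)"
    r"(?P<seq>[ACGT]*)$"
)


@dataclass(frozen=True)
class HgvsSpan:
    """Parsed coding-DNA variant with its length arithmetic."""

    kind: str  # dup | del | ins | delins | snv
    start: int
    end: int
    stated_sequence: str
    nt_length: int
    in_frame: bool
    aa_length: Optional[int]
    raw: str
    start_raw: str = ""
    end_raw: str = ""

    def to_hgvs(self) -> str:
        """Regenerate the HGVS-c string from the parsed fields."""
        if self.kind == "snv":
            return self.raw
        pos = self.start_raw if self.end_raw in ("", self.start_raw) else (
            f"{self.start_raw}_{self.end_raw}"
        )
        return f"c.{pos}{self.kind}{self.stated_sequence}"


def _anchor(pos_token: str) -> int:
    """Coding position of a possibly offset token ('802-2' -> 802)."""
    m = re.match(r"^[-*]?\d+", pos_token)
    if not m:
        raise ValueError(f"bad HGVS position {pos_token!r}")
    return int(m.group(0).lstrip("*"))


def parse_hgvs_span(hgvs_c: str) -> HgvsSpan:
    """Parse one HGVS-c description into an :class:`HgvsSpan`.

    Raises ``ValueError`` for unsupported syntax, and when a stated
    del/dup sequence length disagrees with the coordinate span.
    """
    s = hgvs_c.strip()
    m = _SNV_RE.match(s)
    if m:
        pos = _anchor(m["pos"])
        return HgvsSpan(
            kind="snv",
            start=pos,
            end=pos,
            stated_sequence="",
            nt_length=1,
            in_frame=False,
            aa_length=None,
            raw=s,
            start_raw=m["pos"],
            end_raw=m["pos"],
        )
    m = _SPAN_RE.match(s)
    if not m:
        raise ValueError(f"unsupported HGVS-c syntax: {hgvs_c!r}")
    kind, seq = m["kind"], m["seq"] or ""
    start_raw = m["start"]
    end_raw = m["end"] or start_raw
    start, end = _anchor(start_raw), _anchor(end_raw)
    if end < start:
        raise ValueError(f"{hgvs_c!r}: end {end} precedes start {start}")
    span = end - start + 1

    if kind in ("dup", "del"):
        if seq and len(seq) != span:
            raise ValueError(
                f"{hgvs_c!r}: stated sequence length {len(seq)} != span length {span}"
            )
        nt_length = span
    elif kind == "ins":
        if not seq:
            raise ValueError(f"{hgvs_c!r}: ins requires a stated sequence")
        nt_length = len(seq)
    else:  # delins: net length change
        if not seq:
            raise ValueError(f"{hgvs_c!r}: delins requires a stated sequence")
        nt_length = abs(len(seq) - span)

    in_frame = nt_length % 3 == 0
    return HgvsSpan(
        kind=kind,
        start=start,
        end=end,
        stated_sequence=seq,
        nt_length=nt_length,
        in_frame=in_frame,
        aa_length=nt_length // 3 if in_frame else None,
        raw=s,
        start_raw=start_raw,
        end_raw=end_raw,
    )


def summarize_pathogenic(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-patient pathogenic-mutation summary.

    ``calls`` has one row per (patient, mutation) with at least the columns
    ``patient``, ``gene``, ``vaf_percent``; a row whose gene is empty or
    '-' means "no pathogenic mutation detected" for that patient.  Returns
    the summary sorted by patient then descending VAF, and the count of
    patients with at least one mutation.
    """
    if calls.empty:
        return calls.copy(), 0
    df = calls.copy()
    df["gene"] = df["gene"].fillna("").astype(str)
    has_mut = ~df["gene"].str.strip().isin(["", "-"])
    mutated = df[has_mut].copy()
    mutated["vaf_percent"] = pd.to_numeric(mutated["vaf_percent"], errors="coerce")
    mutated = mutated.sort_values(
        ["patient", "vaf_percent"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return mutated, int(mutated["patient"].nunique())
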