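"""VCF ingestion and export (pysam-backed).

Reads VCF v4.x produced by germline-style (HaplotypeCaller-like) or
somatic-style (Mutect2-like) callers.  Per alternate allele one
:class:`~smearseq.variants.VariantCall` is emitted (multiallelic records are
decomposed), alleles are trim-normalized, and the FILTER column maps to
``filter_flags`` (missing FILTER maps to PASS).

VAF/depth resolution: when a sample's FORMAT AD/DP are present they win
(closest to the read evidence); otherwise INFO AF and DP are used.  A record
from which no VAF is derivable is an error.

Recognized INFO keys: AF, DP, POP_AF (population frequency), GENE, HGVSC,
HGVSP, REGION (exon|splice|intron), SNP (flag), and the hard-filter
annotations QD, MQ, FS.
"""

from __future__ import annotations

import math
from typing import Optional

import pysam

from .variants import CallSet, VariantCall, build_callset, normalize_variant

_INFO_HEADERS = [
    ('AF', 'A', 'Float', 'Allele fraction of the event'),
    ('DP', '1', 'Integer', 'Approximate read depth'),
    ('POP_AF', 'A', 'Float', 'Population allele frequency'),
    ('GENE', '1', 'String', 'Gene symbol'),
    ('HGVSC', '1', 'String', 'HGVS coding-sequence name'),
    ('HGVSP', '1', 'String', 'HGVS protein name'),
    ('REGION', '1', 'String', 'Genic region class (exon/splice/intron)'),
    ('SNP', '0', 'Flag', 'Known inherited germline polymorphism'),
    ('QD', '1', 'Float', 'Quality by depth'),
    ('MQ', '1', 'Float', 'RMS mapping quality'),
    ('FS', '1', 'Float', 'Phred-scaled strand-bias Fisher p'),
]


def _first(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _nth(value, i):
    if isinstance(value, (tuple, list)):
        return value[i] if i < len(value) else None
    return value if i == 0 else None


def parse_vcf(path: str, sample_id: str, tissue: str, caller_class: str) -> CallSet:
    """Read one caller's VCF for one sample into a CallSet.

    Multiallelic records are decomposed into one VariantCall per ALT allele,
    each with its own AF entry.  Raises ``ValueError`` naming the offending
    record when a VAF cannot be derived.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        vcf_sample = sample_id if sample_id in list(vcf.header.samples) else (
            list(vcf.header.samples)[0] if vcf.header.samples else None
        )
        for idx, rec in enumerate(vcf, start=1):
            try:
                calls.extend(
                    _record_to_calls(rec, vcf_sample, caller_class)
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: record {idx} ({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return build_callset(calls, sample_id, tissue, caller_class)


def _record_to_calls(rec, vcf_sample: Optional[str], caller_class: str) -> list[VariantCall]:
    if rec.alts is None:
        return []
    flags = frozenset(rec.filter.keys()) if len(rec.filter) else frozenset({"PASS"})
    info = dict(rec.info)
    sample = rec.samples[vcf_sample] if vcf_sample is not None else None

    out = []
    for i, alt in enumerate(rec.alts):
        vaf = depth = None
        if sample is not None:
            ad = sample.get("AD")
            dp = sample.get("DP")
            if ad is not None and None not in ad:
                total = dp if dp is not None else sum(ad)
                if total:
                    vaf = ad[i + 1] / total
                    depth = int(total)
        if vaf is None:
            af = _nth(info.get("AF"), i)
            if af is not None and not (isinstance(af, float) and math.isnan(af)):
                vaf = float(af)
        if depth is None and info.get("DP") is not None:
            depth = int(_first(info["DP"]))
        if vaf is None:
            raise ValueError(
                f"VAF not derivable for ALT {alt!r}: no usable FORMAT AD/DP or INFO AF"
            )
        chrom, pos, ref, nalt = normalize_variant(rec.chrom, rec.pos, rec.ref, alt)
        pop_af = _nth(info.get("POP_AF"), i)
        out.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=nalt,
                vaf=min(1.0, max(0.0, float(vaf))),
                depth=int(depth) if depth is not None else 0,
                filter_flags=flags,
                caller_class=caller_class,
                gene=str(info.get("GENE", "") or ""),
                hgvs_c=str(info.get("HGVSC", "") or ""),
                hgvs_p=str(info.get("HGVSP", "") or ""),
                population_af=float(pop_af) if pop_af is not None else None,
                region=str(info.get("REGION", "unknown") or "unknown"),
                known_snp=bool(info.get("SNP", False)),
                info={k: info[k] for k in ("QD", "MQ", "FS") if k in info},
            )
        )
    return out


def _make_header(callset: CallSet) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, number, typ, desc in _INFO_HEADERS:
        header.add_meta(
            "INFO",
            items=[("ID", name), ("Number", number), ("Type", typ), ("Description", desc)],
        )
    filters = sorted({f for v in callset for f in v.filter_flags} - {"PASS"})
    for f in filters:
        header.add_meta("FILTER", items=[("ID", f), ("Description", "Caller filter flag")])
    for chrom in sorted({v.chrom for v in callset}):
        header.contigs.add(chrom, length=2_000_000_000)
    header.add_sample(callset.sample_id)
    header.formats.add("DP", 1, "Integer", "Read depth")
    return header


def write_vcf(callset: CallSet, path: str) -> None:
    """Write a CallSet as an uncompressed VCF v4.2 file (deterministic order)."""
    header = _make_header(callset)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(callset, key=lambda v: v.key):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for f in sorted(v.filter_flags):
                rec.filter.add(f)
            rec.info["AF"] = (round(v.vaf, 6),)
            rec.info["DP"] = v.depth
            if v.population_af is not None:
                rec.info["POP_AF"] = (round(v.population_af, 6),)
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.hgvs_c:
                rec.info["HGVSC"] = v.hgvs_c
            if v.hgvs_p:
                rec.info["HGVSP"] = v.hgvs_p
            if v.region != "unknown":
                rec.info["REGION"] = v.region
            if v.known_snp:
                rec.info["SNP"] = True
            for k, val in v.info.items():
                rec.info[k] = val
            rec.samples[callset.sample_id]["DP"] = v.depth
            out.write(rec)
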