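"""Seeded synthetic data emulating smear/BMC targeted sequencing.

The generator produces, with truth labels, the variant-call structure the
pipeline is built to digest:

* germline SNPs in both members of a pair, with VAF peaks near 50%
  (heterozygous) and 100% (homozygous), flagged as known polymorphisms with
  population frequency above 1%;
* somatic variants shared by smear and BMC at 5-50% VAF, jittered slightly
  (+/-2 percentage points) between the two tissues;
* smear-specific artifacts — the hallmark of degraded slide DNA — only in
  the smear member, Poisson-distributed in number, with VAF concentrated
  below a configurable noise boundary (default 2.5%) and low read depth;
* BMC-specific sequencing errors, the same shape on the other side;
* panel-shared assay artifacts present in both tissues and in the normal
  panel, which only PON subtraction can remove;
* fusion-caller evidence with two-caller true fusions and single-caller
  decoys, plus per-sample mapped-read totals and matching/normal ISCN
  karyotypes;
* log-normal per-amplicon coverage.

Everything is deterministic under a fixed (seed, pair_index).  What the
generator does NOT emulate: read-level errors, mapping ambiguity, real
genomic positions (variants live at synthetic coordinates on pseudo-
chromosomes; matching logic, not biology, is under test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .coverage import AmpliconCoverage
from .fusions import GENE_CYTOBAND, CALLER_A, CALLER_B, FusionEvidence
from .variants import BMC, SMEAR, SOMATIC, CallSet, VariantCall

#: truth classes
GERMLINE_SNP = "germline_snp"
SOMATIC_TRUE = "somatic"
SMEAR_ARTIFACT = "smear_artifact"
BMC_ERROR = "bmc_error"
ASSAY_ARTIFACT = "assay_artifact"

_GENES = [
    "FLT3", "NPM1", "DNMT3A", "IDH1", "IDH2", "TET2", "ASXL1", "RUNX1",
    "TP53", "NRAS", "KRAS", "CEBPA", "SRSF2", "SF3B1", "U2AF1", "STAG2",
    "EZH2", "WT1", "GATA2", "DDX41",
]
_BASES = np.array(list("ACGT"))

_TRUE_FUSION_PAIRS = [
    ("RUNX1", "RUNX1T1"),
    ("CBFB", "MYH11"),
    ("ETV6", "CHIC2"),
    ("KMT2A", "MLLT10"),
    ("NUP214", "ABL1"),
]
_DECOY_GENES = ["BRAF", "EGFR", "ALK", "ROS1", "RET", "NTRK1", "MET", "ERBB2"]


@dataclass
class FusionBlock:
    """Fusion-simulation settings: every true fusion is seen by both
    callers with expression above rpm_min; decoys by exactly one caller."""

    n_samples: int = 6
    n_true_fusions: int = 3
    decoys_per_caller: int = 2
    mapped_reads_low: int = 20_000
    mapped_reads_high: int = 170_000
    rpm_min: float = 1000.0
    true_rpm_low: float = 1500.0
    true_rpm_high: float = 20_000.0
    decoy_rpm_high: float = 500.0


@dataclass
class AmpliconBlock:
    """Coverage-simulation settings (log-normal per-amplicon coverage)."""

    n_amplicons: int = 568
    log_mu: float = float(np.log(1000.0))
    log_sigma: float = 0.35


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the structure of the five-pair smear/BMC comparison:
    hundreds of low-VAF smear artifacts per pair (Poisson mean 400) below a
    2.5% boundary, tens of genuine somatic variants at 5-50% VAF, germline
    SNP peaks at ~50%/100%, panel-shared assay artifacts, and a 13-sample
    normal panel.
    """

    seed: int = 0
    n_pairs: int = 5
    # germline
    n_germline_het: int = 30
    n_germline_hom: int = 15
    # somatic
    n_somatic: int = 60
    somatic_vaf_low: float = 0.05
    somatic_vaf_high: float = 0.50
    somatic_jitter: float = 0.02
    # smear artifacts
    artifact_rate: float = 400.0  # Poisson mean per pair
    artifact_vaf_dist: str = "uniform"  # "uniform" | "beta"
    artifact_vaf_low: float = 0.001
    artifact_boundary: float = 0.025
    artifact_beta_a: float = 1.0
    artifact_beta_b: float = 4.0
    # BMC-side errors
    n_bmc_errors: int = 20
    # panel-shared assay artifacts
    n_assay_artifacts: int = 10
    assay_vaf_low: float = 0.01
    assay_vaf_high: float = 0.10
    # depth model (negative binomial)
    depth_mean: float = 500.0
    depth_dispersion: float = 8.0
    artifact_depth_mean: float = 60.0
    # fraction of artifact/error records pre-flagged non-PASS upstream
    fraction_nonpass: float = 0.3
    # normal panel
    n_normals: int = 13
    fusion: FusionBlock = field(default_factory=FusionBlock)
    amplicons: AmpliconBlock = field(default_factory=AmpliconBlock)

    def validate(self) -> None:
        counts = [
            self.n_pairs, self.n_germline_het, self.n_germline_hom, self.n_somatic,
            self.n_bmc_errors, self.n_assay_artifacts, self.n_normals,
        ]
        if any(c < 0 for c in counts) or self.artifact_rate < 0:
            raise ValueError("counts and rates must be non-negative")
        for lo, hi in [
            (self.somatic_vaf_low, self.somatic_vaf_high),
            (self.assay_vaf_low, self.assay_vaf_high),
        ]:
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"bad VAF range ({lo}, {hi})")
        if not 0 < self.artifact_boundary <= 0.10:
            raise ValueError("artifact boundary must lie in (0, 0.10]")
        if not 0 <= self.fraction_nonpass <= 1:
            raise ValueError("fraction_nonpass must lie in [0, 1]")
        if self.artifact_vaf_dist not in ("uniform", "beta"):
            raise ValueError(f"unknown artifact VAF distribution {self.artifact_vaf_dist!r}")


TruthLabels = dict[tuple, str]


def _rng(config: SyntheticConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


def _depth(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size) + 1


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _artifact_vafs(rng: np.random.Generator, config: SyntheticConfig, n: int) -> np.ndarray:
    if config.artifact_vaf_dist == "beta":
        raw = rng.beta(config.artifact_beta_a, config.artifact_beta_b, size=n)
        lo = config.artifact_vaf_low
        return lo + raw * (config.artifact_boundary - lo)
    return rng.uniform(config.artifact_vaf_low, config.artifact_boundary, size=n)


def _assay_artifact_templates(config: SyntheticConfig) -> list[dict]:
    """Panel-shared artifact loci, fixed by the master seed so the same keys
    recur in every pair and every normal sample."""
    rng = _rng(config, 9_000)
    refs, alts = _alleles(rng, config.n_assay_artifacts)
    vafs = rng.uniform(config.assay_vaf_low, config.assay_vaf_high, config.n_assay_artifacts)
    return [
        {
            "chrom": "chrA",
            "pos": 900_000_000 + j,
            "ref": str(refs[j]),
            "alt": str(alts[j]),
            "vaf": float(vafs[j]),
            "gene": _GENES[j % len(_GENES)],
        }
        for j in range(config.n_assay_artifacts)
    ]


def _make_call(chrom, pos, ref, alt, vaf, depth, **kw) -> VariantCall:
    return VariantCall(
        chrom=chrom, pos=int(pos), ref=str(ref), alt=str(alt),
        vaf=float(np.clip(vaf, 0.0, 1.0)), depth=int(depth), **kw,
    )


def simulate_paired_callsets(
    config: SyntheticConfig, pair_index: int
) -> tuple[CallSet, CallSet, TruthLabels]:
    """One smear/BMC pair of somatic-style call sets plus truth labels.

    Deterministic under fixed (config.seed, pair_index).
    """
    config.validate()
    rng = _rng(config, 100, pair_index)
    base = (pair_index + 1) * 1_000_000
    smear: list[VariantCall] = []
    bmc: list[VariantCall] = []
    truth: TruthLabels = {}

    def _emit(call_s: Optional[VariantCall], call_b: Optional[VariantCall], label: str):
        key = (call_s or call_b).key
        truth[key] = label
        if call_s is not None:
            smear.append(call_s)
        if call_b is not None:
            bmc.append(call_b)

    # germline SNPs: ~50% het peak and ~100% hom peak, common polymorphisms
    n_het, n_hom = config.n_germline_het, config.n_germline_hom
    n_g = n_het + n_hom
    refs, alts = _alleles(rng, n_g)
    vafs = np.concatenate([
        np.clip(rng.normal(0.5, 0.03, n_het), 0.05, 0.95),
        np.clip(rng.normal(0.98, 0.015, n_hom), 0.9, 1.0),
    ])
    pop_afs = rng.uniform(0.02, 0.5, n_g)
    depths = _depth(rng, config.depth_mean, config.depth_dispersion, 2 * n_g)
    regions = rng.choice(["exon", "intron"], size=n_g, p=[0.4, 0.6])
    for j in range(n_g):
        pos = base + j
        common = dict(
            caller_class=SOMATIC, gene=_GENES[j % len(_GENES)],
            population_af=float(pop_afs[j]), region=str(regions[j]), known_snp=True,
        )
        jit = rng.uniform(-0.01, 0.01, 2)
        _emit(
            _make_call("chr1", pos, refs[j], alts[j], vafs[j] + jit[0], depths[2 * j], **common),
            _make_call("chr1", pos, refs[j], alts[j], vafs[j] + jit[1], depths[2 * j + 1], **common),
            GERMLINE_SNP,
        )

    # shared somatic variants, VAF drawn once then tissue-jittered
    n_s = config.n_somatic
    refs, alts = _alleles(rng, n_s)
    vafs = rng.uniform(config.somatic_vaf_low, config.somatic_vaf_high, n_s)
    depths = _depth(rng, config.depth_mean, config.depth_dispersion, 2 * n_s)
    regions = rng.choice(["exon", "splice", "intron"], size=n_s, p=[0.7, 0.05, 0.25])
    for j in range(n_s):
        pos = base + 100_000 + j
        common = dict(caller_class=SOMATIC, gene=_GENES[j % len(_GENES)],
                      region=str(regions[j]), known_snp=False)
        jit = rng.uniform(-config.somatic_jitter, config.somatic_jitter, 2)
        _emit(
            _make_call("chr1", pos, refs[j], alts[j], vafs[j] + jit[0], depths[2 * j], **common),
            _make_call("chr1", pos, refs[j], alts[j], vafs[j] + jit[1], depths[2 * j + 1], **common),
            SOMATIC_TRUE,
        )

    # smear-specific low-VAF artifacts
    n_a = int(rng.poisson(config.artifact_rate))
    refs, alts = _alleles(rng, n_a)
    vafs = _artifact_vafs(rng, config, n_a)
    depths = _depth(rng, config.artifact_depth_mean, config.depth_dispersion, n_a)
    nonpass = rng.random(n_a) < config.fraction_nonpass
    for j in range(n_a):
        pos = base + 200_000 + j
        flags = frozenset({"weak_evidence"}) if nonpass[j] else frozenset({"PASS"})
        _emit(
            _make_call("chr1", pos, refs[j], alts[j], vafs[j], depths[j],
                       caller_class=SOMATIC, filter_flags=flags, region="intron"),
            None,
            SMEAR_ARTIFACT,
        )

    # BMC-side sequencing errors
    n_e = config.n_bmc_errors
    refs, alts = _alleles(rng, n_e)
    vafs = _artifact_vafs(rng, config, n_e)
    depths = _depth(rng, config.artifact_depth_mean, config.depth_dispersion, n_e)
    nonpass = rng.random(n_e) < config.fraction_nonpass
    for j in range(n_e):
        pos = base + 300_000 + j
        flags = frozenset({"weak_evidence"}) if nonpass[j] else frozenset({"PASS"})
        _emit(
            None,
            _make_call("chr1", pos, refs[j], alts[j], vafs[j], depths[j],
                       caller_class=SOMATIC, filter_flags=flags, region="intron"),
            BMC_ERROR,
        )

    # panel-shared assay artifacts (same keys in every pair and normal)
    for tpl in _assay_artifact_templates(config):
        depth_pair = _depth(rng, config.depth_mean, config.depth_dispersion, 2)
        jit = rng.uniform(-0.005, 0.005, 2)
        common = dict(caller_class=SOMATIC, gene=tpl["gene"], region="intron")
        _emit(
            _make_call(tpl["chrom"], tpl["pos"], tpl["ref"], tpl["alt"],
                       tpl["vaf"] + jit[0], depth_pair[0], **common),
            _make_call(tpl["chrom"], tpl["pos"], tpl["ref"], tpl["alt"],
                       tpl["vaf"] + jit[1], depth_pair[1], **common),
            ASSAY_ARTIFACT,
        )

    pid = f"P{pair_index:02d}"
    return (
        CallSet(f"{pid}_smear", SMEAR, SOMATIC, smear),
        CallSet(f"{pid}_bmc", BMC, SOMATIC, bmc),
        truth,
    )


def simulate_normal_panel(config: SyntheticConfig) -> list[CallSet]:
    """Tumor-free BMC call sets for PON construction.

    Each normal carries its own germline SNPs plus every panel-shared assay
    artifact; no somatic or smear-artifact keys ever appear.
    """
    config.validate()
    if config.n_normals < 2:
        raise ValueError("a normal panel needs at least 2 samples")
    templates = _assay_artifact_templates(config)
    panel = []
    for i in range(config.n_normals):
        rng = _rng(config, 200, i)
        calls: list[VariantCall] = []
        n_g = config.n_germline_het + config.n_germline_hom
        refs, alts = _alleles(rng, n_g)
        vafs = np.where(rng.random(n_g) < 2 / 3,
                        rng.normal(0.5, 0.03, n_g), rng.normal(0.98, 0.015, n_g))
        depths = _depth(rng, config.depth_mean, config.depth_dispersion, n_g)
        for j in range(n_g):
            calls.append(_make_call(
                "chr1", 500_000_000 + i * 100_000 + j, refs[j], alts[j],
                np.clip(vafs[j], 0.05, 1.0), depths[j],
                caller_class=SOMATIC, known_snp=True,
                population_af=float(rng.uniform(0.02, 0.5)),
            ))
        depth_a = _depth(rng, config.depth_mean, config.depth_dispersion, len(templates))
        for j, tpl in enumerate(templates):
            calls.append(_make_call(
                tpl["chrom"], tpl["pos"], tpl["ref"], tpl["alt"],
                tpl["vaf"] + rng.uniform(-0.005, 0.005), depth_a[j],
                caller_class=SOMATIC, gene=tpl["gene"], region="intron",
            ))
        panel.append(CallSet(f"N{i:02d}", BMC, SOMATIC, calls))
    return panel


def simulate_fusion_evidence(config: SyntheticConfig):
    """Two fusion-caller evidence lists, a sample manifest, and truth.

    Returns (evidence_a, evidence_b, manifest, truth) where manifest is a
    list of dicts (sample_id, mapped_reads, karyotype) and truth maps
    sample_id -> set of true fusion gene pairs (frozensets).  True fusions
    appear in both callers with RPM above fusion.rpm_min and a concordant
    karyotype; decoys appear in exactly one caller at low support.
    """
    config.validate()
    fb = config.fusion
    rng = _rng(config, 300)
    ev_a: list[FusionEvidence] = []
    ev_b: list[FusionEvidence] = []
    manifest: list[dict] = []
    truth: dict[str, set[frozenset[str]]] = {}

    for i in range(fb.n_samples):
        sid = f"F{i:02d}"
        mapped = int(rng.integers(fb.mapped_reads_low, fb.mapped_reads_high))
        karyotype = "46,XX[20]"
        truth[sid] = set()
        if i < fb.n_true_fusions:
            g5, g3 = _TRUE_FUSION_PAIRS[i % len(_TRUE_FUSION_PAIRS)]
            rpm = rng.uniform(fb.true_rpm_low, fb.true_rpm_high)
            support = max(1, int(round(rpm * mapped / 1e6)))
            # the two callers see slightly different read support
            support_b = max(1, int(round(support * rng.uniform(0.7, 1.0))))
            ev_a.append(FusionEvidence(sid, CALLER_A, g5, g3, supporting_reads=support))
            ev_b.append(FusionEvidence(sid, CALLER_B, g3, g5, supporting_reads=support_b))
            truth[sid].add(frozenset({g5, g3}))
            (c1, b1), (c2, b2) = GENE_CYTOBAND[g5], GENE_CYTOBAND[g3]
            if c1 == c2:
                bands = sorted([b1, b2])  # p arm sorts before q
                karyotype = f"46,XX,inv({c1})({bands[0]}{bands[1]})[20]"
            else:
                (ca, ba), (cb, bb) = sorted(
                    [(c1, b1), (c2, b2)], key=lambda t: (len(t[0]), t[0])
                )
                karyotype = f"46,XX,t({ca};{cb})({ba};{bb})[20]"
        for d in range(fb.decoys_per_caller):
            pool = rng.choice(len(_DECOY_GENES), size=2, replace=False)
            g5, g3 = _DECOY_GENES[pool[0]], _DECOY_GENES[pool[1]]
            support = max(1, int(round(rng.uniform(1, fb.decoy_rpm_high) * mapped / 1e6)))
            caller = CALLER_A if rng.random() < 0.5 else CALLER_B
            ev = FusionEvidence(sid, caller, g5, g3, supporting_reads=support)
            (ev_a if caller == CALLER_A else ev_b).append(ev)
        manifest.append({"sample_id": sid, "mapped_reads": mapped, "karyotype": karyotype})
    return ev_a, ev_b, manifest, truth


def simulate_amplicon_coverage(config: SyntheticConfig) -> list[AmpliconCoverage]:
    """Log-normal per-amplicon mean coverage for one sample."""
    config.validate()
    ab = config.amplicons
    if ab.n_amplicons < 1:
        raise ValueError("need at least one amplicon")
    rng = _rng(config, 400)
    cov = rng.lognormal(ab.log_mu, ab.log_sigma, ab.n_amplicons)
    return [
        AmpliconCoverage(
            amplicon_id=f"AMPL{j:04d}",
            chrom="chr1",
            start=1 + 250 * j,
            end=250 * (j + 1),
            mean_coverage=float(cov[j]),
        )
        for j in range(ab.n_amplicons)
    ]
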