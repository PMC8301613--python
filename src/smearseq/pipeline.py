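"""End-to-end DNA and RNA workflows.

`run_dna_pipeline` takes paired smear/BMC call sets (from VCFs on disk or
from the synthetic generator), builds or loads a panel of normals, runs the
noise-reduction cascade on each member, and writes a report bundle:
per-pair partitions before and after filtering, per-stage filter reports,
pooled concordance fractions, the selected (or fixed) VAF noise boundary,
region-class counts of the retained calls, and — when truth labels exist —
somatic recall and artifact removal rates.

`run_rna_pipeline` merges two fusion callers' evidence tables with the
sample manifest (mapped reads + karyotype), applies the two-caller +
expression consensus rule, and reports per-sample fusion calls with
karyotype concordance.

Reports are plain TSV/JSON, written atomically (a temporary directory is
renamed into place) so partial outputs are never left behind.  Reruns with
identical configuration and seed are byte-identical.
"""

from __future__ import annotations

import json
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import simulate as sim
from .boundary import estimate_noise_boundary
from .concordance import (
    PairedComparison,
    classify_paired,
    concordance_fractions,
    vaf_concordance,
    vaf_depth_table,
)
from .filters import CascadeConfig, FilterReport, PanelOfNormals, build_pon, classify_region, run_cascade
from .fusions import (
    FusionResult,
    consensus_call,
    karyotype_concordance,
    parse_karyotype,
    read_caller_a_tsv,
    read_caller_b_tsv,
)
from .variants import CallSet
from .vcfio import parse_vcf


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str = "smearseq_out"
    seed: int = 0
    # DNA inputs: list of (pair_id, smear_vcf, bmc_vcf); empty => simulate
    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    pon_vcfs: list[str] = field(default_factory=list)  # empty => simulate
    caller_class: str = "somatic"
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    min_samples: int = 2
    threshold_mode: str = "fixed"  # "fixed" | "auto"
    # RNA inputs
    caller_a_tsv: Optional[str] = None
    caller_b_tsv: Optional[str] = None
    manifest_tsv: Optional[str] = None
    rpm_min: float = 1000.0
    synthetic: sim.SyntheticConfig = field(default_factory=sim.SyntheticConfig)

    def __post_init__(self) -> None:
        self.synthetic.seed = self.seed


@dataclass
class DnaReport:
    """In-memory result bundle of the DNA workflow."""

    comparisons_before: list[PairedComparison]
    comparisons_after: list[PairedComparison]
    fractions_before: dict
    fractions_after: dict
    filter_reports: dict[str, FilterReport]
    boundary: Optional[float]
    vaf_threshold_used: float
    region_counts: dict[str, int]
    truth_metrics: Optional[dict] = None


def _load_pairs(cfg: RunConfig) -> tuple[list[tuple[str, CallSet, CallSet]], dict]:
    truth: dict = {}
    if cfg.pairs:
        loaded = []
        for pair_id, smear_path, bmc_path in cfg.pairs:
            for p in (smear_path, bmc_path):
                if not os.path.exists(p):
                    raise FileNotFoundError(f"input VCF missing: {p}")
            loaded.append(
                (
                    pair_id,
                    parse_vcf(smear_path, f"{pair_id}_smear", "smear", cfg.caller_class),
                    parse_vcf(bmc_path, f"{pair_id}_bmc", "bmc", cfg.caller_class),
                )
            )
        return loaded, truth
    loaded = []
    for i in range(cfg.synthetic.n_pairs):
        smear, bmc, t = sim.simulate_paired_callsets(cfg.synthetic, i)
        loaded.append((f"P{i:02d}", smear, bmc))
        truth.update(t)
    return loaded, truth


def _load_pon(cfg: RunConfig) -> PanelOfNormals:
    if cfg.pon_vcfs:
        for p in cfg.pon_vcfs:
            if not os.path.exists(p):
                raise FileNotFoundError(f"PON VCF missing: {p}")
        normals = [
            parse_vcf(p, f"N{i:02d}", "bmc", cfg.caller_class)
            for i, p in enumerate(cfg.pon_vcfs)
        ]
    else:
        normals = sim.simulate_normal_panel(cfg.synthetic)
    return build_pon(normals, min_samples=cfg.min_samples)


def run_dna_pipeline(cfg: RunConfig, write: bool = True) -> DnaReport:
    """Run the full DNA noise-reduction workflow; optionally write the
    report bundle under ``cfg.out_dir/dna``."""
    pairs, truth = _load_pairs(cfg)
    pon = _load_pon(cfg)

    comparisons_before = [classify_paired(s, b, pair_id=pid) for pid, s, b in pairs]

    # auto threshold: estimate the noise boundary from post-subtraction
    # smear-unique vs shared VAFs pooled over pairs
    cascade_cfg = cfg.cascade
    boundary = None
    if cfg.threshold_mode == "auto":
        from .filters import subtract_pon

        smear_unique_vafs: list[float] = []
        shared_vafs: list[float] = []
        for pid, smear, bmc in pairs:
            s_sub, _ = subtract_pon(smear, pon)
            b_sub, _ = subtract_pon(bmc, pon)
            cmp_sub = classify_paired(s_sub, b_sub, pair_id=pid)
            smear_unique_vafs.extend(v.vaf for v in cmp_sub.smear_unique)
            shared_vafs.extend(s.vaf for s, _ in cmp_sub.shared)
        est = estimate_noise_boundary(smear_unique_vafs, shared_vafs)
        boundary = est.boundary
        if boundary is not None:
            cascade_cfg = CascadeConfig(
                qd_min=cfg.cascade.qd_min,
                mq_min=cfg.cascade.mq_min,
                fs_max=cfg.cascade.fs_max,
                vaf_threshold=boundary,
                pop_af_max=cfg.cascade.pop_af_max,
            )

    filter_reports: dict[str, FilterReport] = {}
    filtered_pairs = []
    retained_calls = []
    for pid, smear, bmc in pairs:
        smear_f, rep_s = run_cascade(smear, pon, cascade_cfg)
        bmc_f, rep_b = run_cascade(bmc, pon, cascade_cfg)
        filter_reports[f"{pid}_smear"] = rep_s
        filter_reports[f"{pid}_bmc"] = rep_b
        filtered_pairs.append((pid, smear_f, bmc_f))
        retained_calls.extend(smear_f)
    comparisons_after = [classify_paired(s, b, pair_id=pid) for pid, s, b in filtered_pairs]

    region_counts: dict[str, int] = {"SNP": 0, "exon+splice": 0, "intron": 0}
    for v in retained_calls:
        region_counts[classify_region(v)] += 1

    truth_metrics = None
    if truth:
        truth_metrics = _truth_metrics(pairs, filtered_pairs, truth)

    report = DnaReport(
        comparisons_before=comparisons_before,
        comparisons_after=comparisons_after,
        fractions_before=concordance_fractions(comparisons_before),
        fractions_after=concordance_fractions(comparisons_after),
        filter_reports=filter_reports,
        boundary=boundary,
        vaf_threshold_used=cascade_cfg.vaf_threshold,
        region_counts=region_counts,
        truth_metrics=truth_metrics,
    )
    if write:
        _write_dna_report(cfg, report)
    return report


def _truth_metrics(pairs, filtered_pairs, truth) -> dict:
    somatic_keys = {k for k, c in truth.items() if c == sim.SOMATIC_TRUE}
    noise_keys = {
        k for k, c in truth.items() if c in (sim.SMEAR_ARTIFACT, sim.ASSAY_ARTIFACT)
    }
    input_keys = set()
    for _pid, smear, bmc in pairs:
        input_keys |= smear.keys() | bmc.keys()
    kept_keys = set()
    for _pid, smear_f, bmc_f in filtered_pairs:
        kept_keys |= smear_f.keys() | bmc_f.keys()
    somatic_in = somatic_keys & input_keys
    noise_in = noise_keys & input_keys
    return {
        "somatic_recall": len(somatic_in & kept_keys) / len(somatic_in) if somatic_in else 1.0,
        "artifact_removal": len(noise_in - kept_keys) / len(noise_in) if noise_in else 1.0,
        "n_somatic_truth": len(somatic_in),
        "n_artifact_truth": len(noise_in),
    }


def _write_atomic(out_dir: str, writer) -> None:
    parent = os.path.dirname(os.path.abspath(out_dir)) or "."
    os.makedirs(parent, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix=".smearseq_tmp_", dir=parent)
    try:
        writer(tmp)
        if os.path.isdir(out_dir):
            shutil.rmtree(out_dir)
        os.replace(tmp, out_dir)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise


def _write_dna_report(cfg: RunConfig, report: DnaReport) -> None:
    def writer(tmp: str) -> None:
        frames = []
        for cmp_ in report.comparisons_before:
            df = vaf_depth_table(cmp_)
            df.insert(0, "stage", "before")
            frames.append(df)
        for cmp_ in report.comparisons_after:
            df = vaf_depth_table(cmp_)
            df.insert(0, "stage", "after")
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            os.path.join(tmp, "vaf_depth.tsv"), sep="\t", index=False
        )
        for name, rep in report.filter_reports.items():
            rep.to_frame().to_csv(
                os.path.join(tmp, f"filter_report_{name}.tsv"), sep="\t", index=False
            )
        shared_frames = []
        for cmp_ in report.comparisons_after:
            if cmp_.shared:
                table, max_diff, corr = vaf_concordance(cmp_)
                table["max_abs_diff"] = max_diff
                table["pearson_r"] = corr
                shared_frames.append(table)
        if shared_frames:
            pd.concat(shared_frames, ignore_index=True).to_csv(
                os.path.join(tmp, "vaf_concordance.tsv"), sep="\t", index=False
            )
        summary = {
            "fractions_before": report.fractions_before,
            "fractions_after": report.fractions_after,
            "boundary": report.boundary,
            "vaf_threshold_used": report.vaf_threshold_used,
            "region_counts": report.region_counts,
            "truth_metrics": report.truth_metrics,
            "seed": cfg.seed,
        }
        with open(os.path.join(tmp, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    _write_atomic(os.path.join(cfg.out_dir, "dna"), writer)


def run_rna_pipeline(cfg: RunConfig, write: bool = True) -> pd.DataFrame:
    """Two-caller fusion consensus + karyotype concordance.

    Returns one row per sample: karyotype, mapped reads, detected fusion,
    RPM and the concordance flag; fusion-negative samples carry '-'.
    """
    if cfg.caller_a_tsv and cfg.caller_b_tsv and cfg.manifest_tsv:
        ev_a = read_caller_a_tsv(cfg.caller_a_tsv)
        ev_b = read_caller_b_tsv(cfg.caller_b_tsv)
        manifest = pd.read_csv(cfg.manifest_tsv, sep="\t", dtype={"sample_id": str}).to_dict(
            "records"
        )
    else:
        ev_a, ev_b, manifest, _truth = sim.simulate_fusion_evidence(cfg.synthetic)

    by_sample: dict[str, list] = {}
    for e in [*ev_a, *ev_b]:
        by_sample.setdefault(e.sample_id, []).append(e)
    manifest_ids = {str(m["sample_id"]) for m in manifest}
    orphans = sorted(set(by_sample) - manifest_ids)
    if orphans:
        raise ValueError(f"samples in caller output but not in manifest: {orphans}")

    rows = []
    for m in manifest:
        sid = str(m["sample_id"])
        mapped = int(m["mapped_reads"])
        karyotype = str(m.get("karyotype", ""))
        rearrs = parse_karyotype(karyotype)
        results: list[FusionResult] = consensus_call(
            by_sample.get(sid, []), mapped, rpm_min=cfg.rpm_min
        )
        positives = [r for r in results if r.positive]
        if not positives:
            rows.append(
                {
                    "sample_id": sid,
                    "karyotype": karyotype,
                    "mapped_reads": mapped,
                    "fusion": "-",
                    "rpm": None,
                    "karyotype_concordant": None,
                }
            )
            continue
        for r in positives:
            r.karyotype_concordant = karyotype_concordance(r, rearrs)
            rows.append(
                {
                    "sample_id": sid,
                    "karyotype": karyotype,
                    "mapped_reads": mapped,
                    "fusion": r.label,
                    "rpm": round(r.rpm, 1),
                    "karyotype_concordant": r.karyotype_concordant,
                }
            )
    table = pd.DataFrame(rows)
    if write:
        _write_atomic(
            os.path.join(cfg.out_dir, "rna"),
            lambda tmp: table.to_csv(os.path.join(tmp, "fusions.tsv"), sep="\t", index=False),
        )
    return table
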