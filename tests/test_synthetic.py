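"""Synthetic-data generator: determinism, truth labels, and the noise
structure the pipeline is designed to remove."""

import numpy as np
import pytest
from scipy import stats

from smearseq.filters import build_pon, run_cascade, subtract_pon
from smearseq.fusions import consensus_call
from smearseq.simulate import (
    ASSAY_ARTIFACT,
    BMC_ERROR,
    GERMLINE_SNP,
    SMEAR_ARTIFACT,
    SOMATIC_TRUE,
    SyntheticConfig,
    simulate_amplicon_coverage,
    simulate_fusion_evidence,
    simulate_normal_panel,
    simulate_paired_callsets,
)
from smearseq.coverage import coverage_summary
from smearseq.vcfio import write_vcf


class TestPairedCallsets:
    def test_deterministic_under_seed_and_pair_index(self, tmp_path):
        c = SyntheticConfig(seed=5)
        s1, b1, t1 = simulate_paired_callsets(c, 2)
        s2, b2, t2 = simulate_paired_callsets(SyntheticConfig(seed=5), 2)
        assert t1 == t2
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(s1, str(p1))
        write_vcf(s2, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_truth_partition_covers_every_key_exactly_once(self):
        c = SyntheticConfig(seed=3)
        smear, bmc, truth = simulate_paired_callsets(c, 0)
        all_keys = smear.keys() | bmc.keys()
        assert set(truth) == all_keys
        assert set(truth.values()) <= {
            GERMLINE_SNP, SOMATIC_TRUE, SMEAR_ARTIFACT, BMC_ERROR, ASSAY_ARTIFACT,
        }

    def test_no_injected_noise_means_identical_key_sets(self):
        c = SyntheticConfig(seed=1, artifact_rate=0.0, n_bmc_errors=0)
        smear, bmc, _ = simulate_paired_callsets(c, 0)
        assert smear.keys() == bmc.keys()

    def test_artifacts_stay_below_boundary_and_smear_only(self):
        c = SyntheticConfig(seed=2)
        smear, bmc, truth = simulate_paired_callsets(c, 1)
        bmc_keys = bmc.keys()
        arts = [v for v in smear if truth[v.key] == SMEAR_ARTIFACT]
        assert arts
        assert all(v.vaf < c.artifact_boundary for v in arts)
        assert all(v.key not in bmc_keys for v in arts)

    def test_germline_snps_flagged_common_and_peaked(self):
        c = SyntheticConfig(seed=4)
        smear, _bmc, truth = simulate_paired_callsets(c, 0)
        snps = [v for v in smear if truth[v.key] == GERMLINE_SNP]
        assert all(v.known_snp and v.population_af > 0.01 for v in snps)
        vafs = np.array([v.vaf for v in snps])
        assert ((np.abs(vafs - 0.5) < 0.2) | (vafs > 0.85)).all()

    def test_smear_unique_count_poisson_distributed(self):
        """Mean artifact count over replicates sits inside the 99% interval
        of the configured Poisson rate."""
        lam = 400.0
        counts = []
        for seed in range(30):
            c = SyntheticConfig(seed=seed, artifact_rate=lam)
            smear, bmc, truth = simulate_paired_callsets(c, 0)
            counts.append(sum(1 for v in smear if truth[v.key] == SMEAR_ARTIFACT))
        mean = np.mean(counts)
        lo, hi = stats.norm.interval(0.99, loc=lam, scale=np.sqrt(lam / len(counts)))
        assert lo <= mean <= hi

    def test_invalid_config_errors_before_output(self):
        with pytest.raises(ValueError):
            simulate_paired_callsets(SyntheticConfig(artifact_boundary=0.5), 0)
        with pytest.raises(ValueError):
            simulate_paired_callsets(SyntheticConfig(n_somatic=-1), 0)


class TestNormalPanel:
    def test_panel_shape_and_contents(self):
        c = SyntheticConfig(seed=0)
        panel = simulate_normal_panel(c)
        assert len(panel) == 13
        smear, _bmc, truth = simulate_paired_callsets(c, 0)
        assay_keys = {k for k, cls in truth.items() if cls == ASSAY_ARTIFACT}
        somatic_keys = {k for k, cls in truth.items() if cls == SOMATIC_TRUE}
        for normal in panel:
            assert assay_keys <= normal.keys()
            assert not (somatic_keys & normal.keys())

    def test_assay_artifacts_subtractable_at_any_min_samples(self):
        c = SyntheticConfig(seed=0)
        pon = build_pon(simulate_normal_panel(c), min_samples=13)
        _smear, bmc, truth = simulate_paired_callsets(c, 0)
        for v in bmc:
            if truth[v.key] == ASSAY_ARTIFACT:
                assert pon.is_subtractable(v.key)

    def test_zero_assay_artifacts_makes_subtraction_identity_on_somatic(self):
        c = SyntheticConfig(seed=0, n_assay_artifacts=0)
        pon = build_pon(simulate_normal_panel(c), min_samples=2)
        smear, _bmc, truth = simulate_paired_callsets(c, 0)
        kept, _removed = subtract_pon(smear, pon)
        somatic = {k for k, cls in truth.items() if cls == SOMATIC_TRUE}
        assert somatic <= kept.keys()

    def test_too_few_normals_rejected(self):
        with pytest.raises(ValueError):
            simulate_normal_panel(SyntheticConfig(n_normals=1))


class TestFusionSimulation:
    def test_true_fusions_positive_and_decoys_negative(self):
        c = SyntheticConfig(seed=8)
        ev_a, ev_b, manifest, truth = simulate_fusion_evidence(c)
        by_sample = {}
        for e in [*ev_a, *ev_b]:
            by_sample.setdefault(e.sample_id, []).append(e)
        for m in manifest:
            sid = m["sample_id"]
            results = consensus_call(by_sample.get(sid, []), m["mapped_reads"],
                                     rpm_min=c.fusion.rpm_min)
            positives = {frozenset(r.gene_pair) for r in results if r.positive}
            assert positives == truth[sid]

    def test_decoys_single_caller(self):
        c = SyntheticConfig(seed=8)
        ev_a, ev_b, _manifest, truth = simulate_fusion_evidence(c)
        true_pairs = set().union(*truth.values()) if any(truth.values()) else set()
        pairs_a = {(e.sample_id, e.pair) for e in ev_a if e.pair not in true_pairs}
        pairs_b = {(e.sample_id, e.pair) for e in ev_b if e.pair not in true_pairs}
        assert pairs_a.isdisjoint(pairs_b)


class TestAmpliconSimulation:
    def test_seeded_determinism(self):
        a = simulate_amplicon_coverage(SyntheticConfig(seed=9))
        b = simulate_amplicon_coverage(SyntheticConfig(seed=9))
        assert a == b

    def test_zero_sigma_gives_full_uniformity(self):
        c = SyntheticConfig(seed=1)
        c.amplicons.log_sigma = 0.0
        _m, uniformity, _t = coverage_summary(simulate_amplicon_coverage(c))
        assert uniformity == 1.0

    def test_forced_low_coverage_tail_reduces_uniformity(self):
        c = SyntheticConfig(seed=1)
        c.amplicons.log_sigma = 0.0
        amps = simulate_amplicon_coverage(c)
        n_drop = len(amps) // 20  # 5% of amplicons at a tenth of the median
        dropped = [
            type(a)(a.amplicon_id, a.chrom, a.start, a.end, 0.1 * a.mean_coverage)
            if i < n_drop else a
            for i, a in enumerate(amps)
        ]
        _m, uniformity, _t = coverage_summary(dropped)
        assert uniformity == pytest.approx(1 - n_drop / len(amps))


def test_end_to_end_cascade_recovers_truth_over_seeds():
    """With default study conditions the cascade keeps >=95% of somatic
    truth and removes >=95% of smear/assay artifacts (multi-seed average)."""
    recalls, removals = [], []
    for seed in range(10):
        c = SyntheticConfig(seed=seed, n_pairs=2)
        pon = build_pon(simulate_normal_panel(c), min_samples=2)
        for i in range(c.n_pairs):
            smear, _bmc, truth = simulate_paired_callsets(c, i)
            kept, _report = run_cascade(smear, pon)
            kept_keys = kept.keys()
            somatic = {k for k, cls in truth.items() if cls == SOMATIC_TRUE}
            noise = {
                k for k, cls in truth.items()
                if cls in (SMEAR_ARTIFACT, ASSAY_ARTIFACT) and k in smear.keys()
            }
            recalls.append(len(somatic & kept_keys) / len(somatic))
            removals.append(len(noise - kept_keys) / len(noise))
    assert np.mean(recalls) >= 0.95
    assert np.mean(removals) >= 0.95
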