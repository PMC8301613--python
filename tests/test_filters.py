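"""Noise-reduction cascade: individual filters, PON, and the full run."""

import pytest
from hypothesis import given, settings, strategies as st

from smearseq.filters import (
    CascadeConfig,
    PanelOfNormals,
    apply_flag_filter,
    apply_hard_filters,
    build_pon,
    classify_region,
    filter_population_af,
    filter_vaf,
    run_cascade,
    subtract_pon,
)
from smearseq.variants import CallSet

from conftest import make_call, make_callset


def _cs(calls, caller_class="somatic"):
    return CallSet("S1", "smear", caller_class, calls)


class TestFlagFilter:
    def test_keeps_only_pass(self):
        cs = _cs([
            make_call(pos=1),
            make_call(pos=2, filter_flags=frozenset({"weak_evidence"})),
            make_call(pos=3, filter_flags=frozenset({"PASS", "weak_evidence"})),
        ])
        kept, removed = apply_flag_filter(cs)
        assert [v.pos for v in kept] == [1]
        assert len(removed) == 2

    def test_empty_callset(self):
        kept, removed = apply_flag_filter(_cs([]))
        assert len(kept) == 0 and removed == []


class TestHardFilters:
    def _germ(self, **info):
        return make_call(caller_class="germline", info=info)

    def test_low_qd_removed_and_boundary_inclusive(self):
        cs = CallSet("S1", "smear", "germline",
                     [make_call(pos=1, caller_class="germline", info={"QD": 1.5}),
                      make_call(pos=2, caller_class="germline", info={"QD": 2.0})])
        kept, removed = apply_hard_filters(cs, qd_min=2.0)
        assert [v.pos for v in kept] == [2]

    def test_missing_annotations_pass(self):
        kept, _ = apply_hard_filters(_cs([self._germ()], "germline"))
        assert len(kept) == 1

    @pytest.mark.parametrize("info,expected_kept", [
        ({"MQ": 39.0}, 0), ({"MQ": 40.0}, 1), ({"FS": 61.0}, 0), ({"FS": 60.0}, 1),
    ])
    def test_mq_and_fs_thresholds(self, info, expected_kept):
        kept, _ = apply_hard_filters(_cs([self._germ(**info)], "germline"))
        assert len(kept) == expected_kept

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_hard_filters(_cs([], "germline"), qd_min=-1)


class TestPon:
    def _normals(self, memberships):
        """memberships: list of position-lists, one per normal."""
        return [make_callset(m, tissue="bmc", sample_id=f"N{i}")
                for i, m in enumerate(memberships)]

    def test_counts_and_subtractable_threshold(self):
        pon = build_pon(self._normals([[1, 2], [1], [1, 3]]), min_samples=2)
        assert pon.entries[("chr1", 1, "A", "T")] == 3
        assert pon.is_subtractable(("chr1", 1, "A", "T"))
        assert not pon.is_subtractable(("chr1", 2, "A", "T"))  # 1 of 3 normals

    def test_min_samples_one_makes_any_present_key_subtractable(self):
        pon = build_pon(self._normals([[5]]), min_samples=1)
        assert pon.is_subtractable(("chr1", 5, "A", "T"))

    def test_empty_normals_rejected(self):
        with pytest.raises(ValueError):
            build_pon([])

    def test_subtract_removes_recurrent_keys(self):
        pon = build_pon(self._normals([[1, 2], [1, 2]]), min_samples=2)
        cs = make_callset([1, 2, 3, 4, 5])
        kept, removed = subtract_pon(cs, pon)
        assert {v.pos for v in kept} == {3, 4, 5}
        assert len(removed) + len(kept) == 5

    def test_empty_panel_is_identity(self):
        pon = PanelOfNormals(entries={}, n_samples=1, min_samples=1)
        cs = make_callset([1, 2])
        kept, removed = subtract_pon(cs, pon)
        assert len(kept) == 2 and not removed

    def test_min_samples_above_panel_size_is_identity(self):
        pon = build_pon(self._normals([[1], [1]]), min_samples=99)
        kept, removed = subtract_pon(make_callset([1]), pon)
        assert len(kept) == 1 and not removed


class TestVafAndPopulationFilters:
    def test_vaf_3_percent_survives_2_5_threshold(self):
        kept, _ = filter_vaf(_cs([make_call(vaf=0.0304)]), 0.025)
        assert len(kept) == 1

    def test_vaf_below_threshold_removed(self):
        kept, removed = filter_vaf(_cs([make_call(vaf=0.024)]), 0.025)
        assert not len(kept) and len(removed) == 1

    def test_zero_threshold_is_identity(self):
        kept, removed = filter_vaf(make_callset([1, 2, 3], vaf=0.001), 0.0)
        assert len(kept) == 3 and not removed

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            filter_vaf(_cs([]), 1.5)

    def test_population_af_strictly_greater_than_cut(self):
        cs = _cs([
            make_call(pos=1, population_af=0.02),
            make_call(pos=2, population_af=0.01),  # exactly 1%: kept
            make_call(pos=3, population_af=None),  # missing: kept
        ])
        kept, removed = filter_population_af(cs, 0.01)
        assert {v.pos for v in kept} == {2, 3}
        assert [v.pos for v in removed] == [1]


class TestClassifyRegion:
    def test_known_snp_dominates(self):
        assert classify_region(make_call(known_snp=True, region="exon")) == "SNP"

    @pytest.mark.parametrize("region,expected", [
        ("exon", "exon+splice"), ("splice", "exon+splice"), ("intron", "intron"),
    ])
    def test_region_annotation(self, region, expected):
        assert classify_region(make_call(region=region)) == expected

    def test_intron_within_two_bases_of_exon_is_splice(self):
        v = make_call(region="intron", info={"EXON_DIST": 2})
        assert classify_region(v) == "exon+splice"
        far = make_call(region="intron", info={"EXON_DIST": 3})
        assert classify_region(far) == "intron"

    def test_unannotated_defaults_to_intron(self):
        assert classify_region(make_call(region="unknown")) == "intron"


class TestRunCascade:
    def test_clean_input_is_identity(self):
        cs = make_callset([1, 2, 3], vaf=0.4)
        out, report = run_cascade(cs, None)
        assert len(out) == 3
        assert [r for _s, r, _k in report.stages] == [0, 0, 0, 0]

    def test_four_stages_in_fixed_order(self):
        _out, report = run_cascade(make_callset([1]), None)
        assert [s for s, _r, _k in report.stages] == [
            "caller_flags", "pon_subtraction", "vaf_threshold", "population_af",
        ]

    def test_each_stage_removes_exactly_one(self):
        pon = build_pon(
            [make_callset([2], tissue="bmc", sample_id=f"N{i}") for i in range(2)],
            min_samples=2,
        )
        cs = _cs([
            make_call(pos=1, filter_flags=frozenset({"weak_evidence"})),
            make_call(pos=2, vaf=0.4),                # in PON
            make_call(pos=3, vaf=0.01),               # below VAF cut
            make_call(pos=4, vaf=0.4, population_af=0.05),  # common SNP
            make_call(pos=5, vaf=0.4),                # survives
        ])
        out, report = run_cascade(cs, pon)
        assert [r for _s, r, _k in report.stages] == [1, 1, 1, 1]
        assert [v.pos for v in out] == [5]

    def test_counts_conserved_stage_to_stage(self):
        cs = make_callset(range(1, 20), vaf=0.02)
        _out, report = run_cascade(cs, None)
        prev = report.n_input
        for _stage, removed, retained in report.stages:
            assert removed + retained == prev
            prev = retained

    def test_germline_class_uses_hard_filters(self):
        cs = CallSet("S1", "smear", "germline",
                     [make_call(caller_class="germline", vaf=0.5, info={"QD": 1.0})])
        _out, report = run_cascade(cs, None)
        assert report.stages[0][0] == "hard_filters"
        assert report.stages[0][1] == 1


class TestFilterAlgebra:
    """Idempotence, commutation and threshold monotonicity."""

    @pytest.fixture
    def mixed(self):
        return _cs([
            make_call(pos=1, vaf=0.01),
            make_call(pos=2, vaf=0.03, population_af=0.2),
            make_call(pos=3, vaf=0.3, filter_flags=frozenset({"weak_evidence"})),
            make_call(pos=4, vaf=0.5, population_af=0.005),
            make_call(pos=5, vaf=0.024),
        ])

    @pytest.mark.parametrize("op", [
        apply_flag_filter,
        lambda cs: filter_vaf(cs, 0.025),
        lambda cs: filter_population_af(cs, 0.01),
    ])
    def test_filters_idempotent(self, mixed, op):
        once, _ = op(mixed)
        twice, removed_again = op(once)
        assert twice.keys() == once.keys() and not removed_again

    def test_vaf_and_population_filters_commute(self, mixed):
        ab, _ = filter_population_af(filter_vaf(mixed, 0.025)[0], 0.01)
        ba, _ = filter_vaf(filter_population_af(mixed, 0.01)[0], 0.025)
        assert ab.keys() == ba.keys()

    @settings(derandomize=True, max_examples=50)
    @given(t1=st.floats(0, 1), t2=st.floats(0, 1))
    def test_retention_monotone_in_vaf_threshold(self, t1, t2):
        cs = _cs([make_call(pos=i, vaf=v) for i, v in enumerate(
            [0.001, 0.01, 0.02, 0.025, 0.03, 0.1, 0.5, 1.0], start=1)])
        lo, hi = sorted([t1, t2])
        kept_lo, _ = filter_vaf(cs, lo)
        kept_hi, _ = filter_vaf(cs, hi)
        assert len(kept_hi) <= len(kept_lo)
        assert kept_hi.keys() <= kept_lo.keys()
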