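import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nics.cnv_calling.calls import Call, CNVCallSet
from nics.feature_extraction import (
    EUPLOID,
    FEATURE_NAMES,
    FULL_ABNORMAL,
    MOSAIC_ABNORMAL,
    calls_at_resolution,
    extract_features,
    redefine_by_threshold,
)


def _call(chrom="chr1", frac=0.6, scope="whole_chromosome", length_mb=100.0):
    direction = "gain"
    return Call(
        chromosome=chrom,
        start_bin=0,
        end_bin=int(length_mb),
        mean_copy_number=2 + frac,
        mosaic_fraction=frac,
        direction=direction,
        length_mb=length_mb,
        scope=scope,
    )


def _callset(calls, sex_call="XX"):
    classes = {}
    for c in calls:
        classes[c.chromosome] = c.scope
    return CNVCallSet("e", tuple(calls), classes, sex_call)


EMPTY = _callset([])


class TestCallsAtResolution:
    def test_empty_callset_euploid_everywhere(self):
        for res in ("segmental", "arm", "whole_chromosome"):
            assert calls_at_resolution(EMPTY, res) == EUPLOID

    def test_mosaic_event_only_at_its_resolution(self):
        cs = _callset([_call(frac=0.6, scope="whole_chromosome")])
        assert calls_at_resolution(cs, "whole_chromosome") == MOSAIC_ABNORMAL
        assert calls_at_resolution(cs, "segmental") == EUPLOID
        assert calls_at_resolution(cs, "arm") == EUPLOID

    def test_full_segmental_event(self):
        cs = _callset([_call(frac=1.0, scope="segmental", length_mb=15.0)])
        assert calls_at_resolution(cs, "segmental") == FULL_ABNORMAL

    def test_unknown_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            calls_at_resolution(EMPTY, "exon")

    def test_full_threshold_boundary(self):
        cs = _callset([_call(frac=0.8)])
        assert calls_at_resolution(cs, "whole_chromosome") == FULL_ABNORMAL
        cs = _callset([_call(frac=0.79)])
        assert calls_at_resolution(cs, "whole_chromosome") == MOSAIC_ABNORMAL


class TestRedefineByThreshold:
    @pytest.mark.parametrize(
        "frac,expected", [(0.4, EUPLOID), (0.6, FULL_ABNORMAL), (0.5, FULL_ABNORMAL)]
    )
    def test_threshold_rule(self, frac, expected):
        cs = _callset([_call(frac=frac)])
        assert redefine_by_threshold(cs, "whole_chromosome") == expected

    def test_idempotent(self):
        # a redefined call re-thresholded gives the same value: calls with
        # fraction >= 0.5 map to FULL regardless of how often applied
        for frac in (0.3, 0.5, 0.9):
            cs = _callset([_call(frac=frac)])
            once = redefine_by_threshold(cs, "whole_chromosome")
            again = redefine_by_threshold(cs, "whole_chromosome")
            assert once == again

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            redefine_by_threshold(EMPTY, "arm", threshold=1.5)


class TestExtractFeatures:
    def test_euploid_identity(self):
        f = extract_features(EMPTY)
        assert f.as_array().tolist() == [0, 0, 0, 0, 0, 0, 3, 0, 0.0, 0.0, 0]

    def test_single_40pct_whole_chromosome_gain(self):
        # hand-computed from the rules on a constructed callset
        cs = _callset([_call(chrom="chr21", frac=0.4, scope="whole_chromosome", length_mb=46.7)])
        f = extract_features(cs)
        assert f.f5_cnv_chrom == MOSAIC_ABNORMAL
        assert f.f6_cnv_chrom_redef == EUPLOID
        assert f.f7_euploid_resolution_count == 3
        assert f.f8_abnormal_chrom_count == 1
        assert f.f9_max_mosaic_fraction == pytest.approx(0.4)
        assert f.f10_largest_fragment_at_max_mosaic_mb == pytest.approx(46.7)
        assert f.f11_sex_chrom_abnormal is False

    def test_x_monosomy_like(self):
        cs = _callset(
            [_call(chrom="chrX", frac=1.0, scope="whole_chromosome", length_mb=156.0)],
            sex_call="abnormal",
        )
        f = extract_features(cs)
        assert f.f11_sex_chrom_abnormal is True
        assert f.f8_abnormal_chrom_count == 1

    def test_f10_tie_takes_largest_span(self):
        cs = _callset([
            _call(chrom="chr1", frac=0.7, scope="whole_chromosome", length_mb=248.0),
            _call(chrom="chr21", frac=0.7, scope="whole_chromosome", length_mb=46.7),
        ])
        f = extract_features(cs)
        assert f.f10_largest_fragment_at_max_mosaic_mb == pytest.approx(248.0)

    def test_f7_consistency_invariant(self):
        cs = _callset([
            _call(chrom="chr1", frac=0.9, scope="whole_chromosome"),
            _call(chrom="chr2", frac=0.6, scope="arm", length_mb=40.0),
            _call(chrom="chr3", frac=0.3, scope="segmental", length_mb=12.0),
        ])
        f = extract_features(cs)
        non_euploid_redefined = sum(
            redefine_by_threshold(cs, r) != EUPLOID
            for r in ("segmental", "arm", "whole_chromosome")
        )
        assert f.f7_euploid_resolution_count == 3 - non_euploid_redefined


fractions = st.lists(
    st.floats(min_value=0.3, max_value=1.0), min_size=0, max_size=4
)


@given(fracs=fractions)
@settings(max_examples=60, deadline=None)
def test_feature_vector_shape_and_finiteness(fracs):
    chroms = [f"chr{i + 1}" for i in range(len(fracs))]
    scopes = ["whole_chromosome", "arm", "segmental", "whole_chromosome"]
    calls = [
        _call(chrom=c, frac=f, scope=s, length_mb=20.0)
        for c, f, s in zip(chroms, fracs, scopes)
    ]
    vec = extract_features(_callset(calls)).as_array()
    assert vec.shape == (11,)
    assert np.isfinite(vec).all()
    assert len(FEATURE_NAMES) == 11


@given(
    frac=st.floats(min_value=0.3, max_value=0.99),
    bump=st.floats(min_value=0.001, max_value=0.5),
)
@settings(max_examples=60, deadline=None)
def test_monotone_in_severity(frac, bump):
    # raising an event's mosaic fraction never decreases any feature
    lo = extract_features(_callset([_call(frac=frac)])).as_array()
    hi = extract_features(_callset([_call(frac=min(frac + bump, 1.0))])).as_array()
    assert (hi[:6] >= lo[:6]).all()  # ordinal calls
    assert hi[7] >= lo[7] and hi[8] >= lo[8] and hi[9] >= lo[9]
    assert lo[6] >= hi[6]  # euploid-resolution count can only drop
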