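import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import grainscan as g
from grainscan.errors import ConfigError, InvalidInputError
from grainscan.grading import FeatureTally

# Published manual-vs-software average-grain-length comparison rows:
# (manual AGL, software AGL, percent deviation at 2-decimal rounding)
AGL_COMPARISON_ROWS = [
    (5.996, 6.146, -2.44),
    (5.63805, 5.816, -3.06),
    (5.9025, 6.044, -2.34),
    (5.789525, 5.951, -2.71),
    (5.63805, 5.82, -3.13),
    (5.941, 5.816, 2.15),
    (5.9025, 6.09, -3.08),
    (5.9025, 6.065, -2.68),
    (5.789525, 5.954, -2.76),
]


def _assessment(length, width=2.0, weight=0.02, threshold=4.8, **flags):
    geom = g.KernelGeometry(length_mm=length, width_mm=min(width, length), centroid=(0, 0))
    return g.assess_kernel(
        geometry=geom, color=None, predicted_weight_g=weight,
        broken_threshold_mm=threshold, **flags,
    )


class TestClassifyBroken:
    @pytest.mark.parametrize("length,threshold,broken",
                             [(4.0, 5.0, True), (6.0, 5.0, False), (5.0, 5.0, False)])
    def test_threshold_rule_with_tie_unbroken(self, length, threshold, broken):
        assert g.classify_broken(length, threshold) is broken

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigError):
            g.classify_broken(5.0, 0.0)

    def test_head_rice_requires_length_above_threshold(self):
        at = _assessment(4.8, threshold=4.8)
        assert not at.is_broken and not at.is_head_rice
        above = _assessment(5.0, threshold=4.8)
        assert above.is_head_rice


class TestPercentDeviation:
    @pytest.mark.parametrize("manual,software,expected", AGL_COMPARISON_ROWS)
    def test_published_comparison_rows_reproduced(self, manual, software, expected):
        assert g.percent_deviation(manual, software) == expected

    def test_identical_values_give_zero(self):
        assert g.percent_deviation(6.0, 6.0) == 0.0

    def test_zero_software_value_rejected(self):
        with pytest.raises(InvalidInputError):
            g.percent_deviation(5.0, 0.0)


class TestHistogram:
    def test_single_bin_sample(self):
        rows = g.build_histogram([_assessment(6.5) for _ in range(64)])
        by_range = {r.range_label: r for r in rows}
        assert by_range["(6-7)"].count == 64
        assert by_range["(6-7)"].percent_by_weight == 100.0
        assert all(r.count == 0 for r in rows if r.range_label != "(6-7)")

    def test_reproduces_reference_count_vector(self):
        # counts per unit bin: (0,0,2,4,8,44,6,0,0)
        counts = [0, 0, 2, 4, 8, 44, 6, 0, 0]
        assessments = []
        rng = np.random.default_rng(0)
        for lo, c in zip(range(1, 10), counts):
            for _ in range(c):
                assessments.append(_assessment(lo + rng.uniform(0.05, 0.95)))
        rows = g.build_histogram(assessments)
        assert [r.count for r in rows] == counts

    def test_unrounded_percents_sum_to_100_even_when_rounded_do_not(self):
        rng = np.random.default_rng(3)
        assessments = [
            _assessment(float(rng.uniform(3.2, 7.8)), weight=float(rng.uniform(0.01, 0.03)))
            for _ in range(37)
        ]
        rows = g.build_histogram(assessments)
        assert sum(r.percent_by_weight_unrounded for r in rows) == pytest.approx(100.0, abs=1e-9)
        # the displayed 1-decimal column is rounded per row, not renormalised
        assert all(r.percent_by_weight == round(r.percent_by_weight_unrounded, 1) for r in rows)

    def test_per_bin_mean_length_lies_inside_bin(self):
        rng = np.random.default_rng(4)
        rows = g.build_histogram(
            [_assessment(float(rng.uniform(1.1, 9.9))) for _ in range(100)]
        )
        for r in rows:
            if r.count and not r.is_overflow:
                assert r.lo_mm <= r.agl_mm < r.hi_mm

    def test_out_of_range_lengths_go_to_overflow_row(self):
        rows = g.build_histogram([_assessment(6.0), _assessment(12.0, threshold=4.8)])
        assert rows[-1].is_overflow and rows[-1].count == 1

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            g.build_histogram([])


class TestSummarize:
    def test_single_kernel_report(self):
        report = g.summarize([_assessment(6.0, width=2.0, weight=0.02)])
        assert report.total_grains == 1
        assert report.agl_mm == pytest.approx(6.0)
        assert report.agw_mm == pytest.approx(2.0)
        assert report.total_weight_g == pytest.approx(0.02)
        assert all(t.count == 0 for t in report.features.values())

    def test_damaged_fraction_matches_flags(self):
        assessments = [
            _assessment(6.0, is_damaged=(i % 5 == 0)) for i in range(40)
        ]  # exactly 20% damaged
        report = g.summarize(assessments)
        assert report.features["damaged"].count / report.total_grains == 0.2

    def test_broken_percent_by_weight_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        assessments = [
            _assessment(float(rng.uniform(3.0, 7.5)), weight=float(rng.uniform(0.01, 0.03)))
            for _ in range(60)
        ]
        report = g.summarize(assessments)
        broken_w = sum(a.predicted_weight_g for a in assessments if a.is_broken)
        total_w = sum(a.predicted_weight_g for a in assessments)
        assert report.broken_percent_by_weight == pytest.approx(100 * broken_w / total_w)

    def test_feature_weights_sum_predicted_weights_of_flagged(self):
        assessments = [_assessment(6.0, weight=0.02, is_paddy=True),
                       _assessment(6.2, weight=0.03), _assessment(3.0, weight=0.01)]
        report = g.summarize(assessments)
        assert report.features["paddy"] == FeatureTally(count=1, weight_g=pytest.approx(0.02))

    def test_report_serialisation(self, tmp_path):
        report = g.summarize([_assessment(6.0), _assessment(4.0)])
        report.to_json(tmp_path / "report.json")
        report.to_csv(tmp_path / "report.csv")
        assert (tmp_path / "report.json").stat().st_size > 0
        text = (tmp_path / "report.csv").read_text()
        assert "Percent by Weight" in text and "broken_count" in text


@given(seed=st.integers(0, 10_000))
def test_report_invariants_on_random_samples(seed):
    """Partition, conservation and percent-sum invariants hold for any sample."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 80))
    threshold = float(rng.uniform(3.5, 6.5))
    assessments = [
        _assessment(
            float(rng.uniform(1.2, 9.8)),
            weight=float(rng.uniform(0.005, 0.04)),
            threshold=threshold,
        )
        for _ in range(n)
    ]
    report = g.summarize(assessments)
    assert report.whole_count + report.broken_count == report.total_grains
    assert sum(r.count for r in report.histogram) == report.total_grains
    assert sum(r.percent_by_weight_unrounded for r in report.histogram) == pytest.approx(
        100.0, abs=1e-9
    )
    # head rice is a subset of unbroken kernels
    assert report.head_rice_count <= report.whole_count


@given(seed=st.integers(0, 10_000))
def test_broken_count_monotone_in_threshold(seed):
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(2.0, 8.0, size=30)
    counts = []
    for thr in (3.0, 4.0, 5.0, 6.0, 7.0):
        assessments = [_assessment(float(L), threshold=thr) for L in lengths]
        counts.append(g.summarize(assessments).broken_count)
    assert counts == sorted(counts)
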