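import numpy as np
import pandas as pd
import pytest

from btmap.exceptions import InvalidParameterError, UndefinedAlleleFrequencyError
from btmap.finemap import (
    FineMapping,
    MappedInterval,
    call_interval,
    delta_af,
    qc_amplicons,
)
from btmap.finemap import test_marker as marker_pvalue
from btmap.finemap import test_markers as marker_pvalues


def make_amplicons(rows):
    """rows: (id, pos, sel_R, sel_S, ctrl_R, ctrl_S)"""
    return pd.DataFrame(
        rows,
        columns=["amplicon_id", "pos", "sel_depth_R", "sel_depth_S",
                 "ctrl_depth_R", "ctrl_depth_S"],
    ).assign(chrom="chr9")[
        ["amplicon_id", "chrom", "pos", "sel_depth_R", "sel_depth_S",
         "ctrl_depth_R", "ctrl_depth_S"]
    ]


class TestQc:
    def test_control_band_and_depth_rule(self):
        # ctrl AFs 0.05, 0.20, 0.40, 0.60 at good depth; 0.30 at 400 reads
        rows = [
            (1, 100, 500, 500, 50, 950),
            (2, 200, 500, 500, 200, 800),
            (3, 300, 500, 500, 400, 600),
            (4, 400, 500, 500, 600, 400),
            (5, 500, 500, 500, 120, 280),
        ]
        kept = qc_amplicons(make_amplicons(rows))
        assert kept["amplicon_id"].tolist() == [2, 3]

    def test_clean_deep_panel_fully_retained(self):
        rows = [(i, i * 100, 19_000, 19_000, 9_500, 28_500) for i in range(1, 49)]
        kept = qc_amplicons(make_amplicons(rows))
        assert len(kept) == 48

    def test_nonspecific_contamination_is_excluded(self):
        # 90% off-target fixed-S reads on a 0.25-AF pool: ctrl AF 0.025 < 0.125
        rows = [(1, 100, 500, 500, 25, 975)]
        assert qc_amplicons(make_amplicons(rows)).empty

    def test_idempotent_and_order_preserving(self):
        rows = [
            (3, 300, 500, 500, 300, 700),
            (1, 100, 500, 500, 250, 750),
            (2, 200, 500, 500, 50, 950),
        ]
        once = qc_amplicons(make_amplicons(rows))
        twice = qc_amplicons(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once["amplicon_id"].tolist() == [3, 1]


class TestDeltaAf:
    @pytest.mark.parametrize(
        "sel,ctrl,expected", [(0.50, 0.25, 0.25), (0.3, 0.3, 0.0), (0.20, 0.30, -0.10)]
    )
    def test_sign_convention(self, sel, ctrl, expected):
        assert delta_af(sel, ctrl) == pytest.approx(expected)

    def test_undefined_frequency_propagates(self):
        with pytest.raises(UndefinedAlleleFrequencyError):
            delta_af(float("nan"), 0.25)


class TestMarkerTest:
    def test_strong_shift_is_highly_significant(self):
        assert marker_pvalue(500, 1000, 250, 1000) < 1e-6

    def test_identical_counts_sit_at_the_one_sided_null_center(self):
        assert marker_pvalue(250, 1000, 250, 1000) == pytest.approx(0.5, abs=1e-9)

    def test_shift_in_the_wrong_direction_is_not_significant(self):
        assert marker_pvalue(200, 1000, 250, 1000) > 0.5

    def test_zero_totals_rejected(self):
        with pytest.raises(UndefinedAlleleFrequencyError):
            marker_pvalue(0, 0, 10, 100)

    @pytest.mark.parametrize(
        "x1,n1,x2,n2,nsim",
        [
            (560, 2000, 500, 2000, 400_000),
            (300, 1000, 250, 1000, 400_000),
            (275, 1000, 250, 1000, 200_000),
            (255, 1000, 250, 1000, 100_000),
            (10_200, 38_000, 9_800, 38_000, 4_000_000),
        ],
    )
    def test_agrees_with_monte_carlo_two_binomial_oracle(self, x1, n1, x2, n2, nsim):
        """z-test p within 10% of an exact-sampling null oracle (p in [1e-4, 0.5])."""
        rng = np.random.default_rng(42)
        pooled = (x1 + x2) / (n1 + n2)
        d_obs = x1 / n1 - x2 / n2
        a = rng.binomial(n1, pooled, nsim) / n1
        b = rng.binomial(n2, pooled, nsim) / n2
        p_mc = float(((a - b) >= d_obs - 1e-12).mean())
        p_z = marker_pvalue(x1, n1, x2, n2)
        mc_se = np.sqrt(p_mc * (1 - p_mc) / nsim)
        assert abs(p_z - p_mc) <= 0.1 * p_mc + 3 * mc_se


class TestIntervalCall:
    def _results(self, rows):
        df = make_amplicons(rows)
        return marker_pvalues(df)

    def test_reproduces_675kb_interval_arithmetic(self):
        # strong selection at three inner markers, outermost significant at the
        # printed boundary positions
        rows = [
            (2, 1_528_061, 255_000, 745_000, 250_000, 750_000),
            (3, 1_767_453, 500_000, 500_000, 250_000, 750_000),
            (7, 2_073_992, 500_000, 500_000, 250_000, 750_000),
            (12, 2_442_587, 500_000, 500_000, 250_000, 750_000),
            (13, 2_546_746, 255_000, 745_000, 250_000, 750_000),
        ]
        interval, table, warnings = call_interval(self._results(rows))
        assert interval is not None
        assert (interval.start, interval.end) == (1_767_453, 2_442_587)
        assert interval.width_bp == 675_134
        assert interval.width_kb_display == "675 kb"
        assert interval.supporting_amplicons == (3, 7, 12)
        assert not warnings

    def test_no_significant_markers_means_no_interval(self):
        rows = [(i, i * 1000, 250_0, 750_0, 2_500, 7_500) for i in range(1, 6)]
        interval, _, _ = call_interval(self._results(rows))
        assert interval is None

    def test_single_significant_marker_gives_zero_width(self):
        rows = [
            (1, 1000, 2_500, 7_500, 2_500, 7_500),
            (2, 2000, 5_000, 5_000, 2_500, 7_500),
            (3, 3000, 2_500, 7_500, 2_500, 7_500),
        ]
        interval, _, _ = call_interval(self._results(rows))
        assert (interval.start, interval.end) == (2000, 2000)
        assert interval.width_bp == 0

    def test_isolated_distal_marker_is_warned_but_spanned(self):
        rows = [
            (1, 1000, 5_000, 5_000, 2_500, 7_500),
            (2, 2000, 5_000, 5_000, 2_500, 7_500),
            (3, 3000, 2_500, 7_500, 2_500, 7_500),
            (4, 9000, 5_000, 5_000, 2_500, 7_500),
        ]
        interval, _, warnings = call_interval(self._results(rows))
        assert (interval.start, interval.end) == (1000, 9000)
        assert len(warnings) == 1 and "amplicon 4" in warnings[0]

    def test_unsorted_positions_rejected(self):
        rows = [
            (1, 2000, 5_000, 5_000, 2_500, 7_500),
            (2, 1000, 5_000, 5_000, 2_500, 7_500),
        ]
        with pytest.raises(InvalidParameterError):
            call_interval(self._results(rows))

    def test_significance_requires_both_p_and_effect_floor(self):
        # huge depth makes a tiny shift significant by p alone; ΔAF floor blocks it
        rows = [(1, 1000, 2_600_000, 7_400_000, 2_500_000, 7_500_000)]
        res = self._results(rows)
        interval, table, _ = call_interval(res)
        assert table["p_adjusted"].iloc[0] < 0.01
        assert interval is None

    def test_interval_validates_orientation(self):
        with pytest.raises(InvalidParameterError):
            MappedInterval("chr9", 10, 5)


class TestMonotoneDecay:
    def test_expected_delta_af_decays_with_distance_from_causal_locus(self):
        """Mean ΔAF over 200 fine-mapping backcrosses is maximal at the
        nearest amplicon and non-increasing with genetic distance."""
        from btmap.panels import CHR9_AMPLICON_POSITIONS, finemap_genome
        from btmap.simulate import (
            BC2,
            SelectionModel,
            _pool_frequencies,
            apply_selection,
            make_backcross,
        )

        gmap, locus, amplicons = finemap_genome()
        idx = [gmap["chr9"].marker_index(p) for _, p in amplicons]
        total = np.zeros(len(amplicons))
        n_rep = 200
        for rep in range(n_rep):
            pop = make_backcross(BC2, gmap, 200, seed=5000 + rep, r2_locus=locus)
            survivors = apply_selection(
                pop, SelectionModel.against_s2s2(), seed=6000 + rep
            )
            f_sel = _pool_frequencies(survivors)["chr9"][idx]
            f_ctrl = _pool_frequencies(pop)["chr9"][idx]
            total += f_sel - f_ctrl
        mean_delta = total / n_rep
        dist = np.abs(np.array(CHR9_AMPLICON_POSITIONS) - locus[1])
        order = np.argsort(dist)
        assert order[0] == int(np.argmax(mean_delta))
        sorted_delta = mean_delta[order]
        assert np.all(np.diff(sorted_delta) <= 0.02)  # MC slack on 200 reps


def test_finemapping_model_summary_and_bed_roundtrip(tmp_path):
    rows = [
        (1, 1_000_000, 500_000, 500_000, 250_000, 750_000),
        (2, 2_000_000, 500_000, 500_000, 250_000, 750_000),
        (3, 3_000_000, 250_000, 750_000, 250_000, 750_000),
    ]
    df = pd.DataFrame(
        rows,
        columns=["amplicon_id", "pos", "sel_depth_R", "sel_depth_S",
                 "ctrl_depth_R", "ctrl_depth_S"],
    ).assign(chrom="chr9")
    res = FineMapping(df).fit()
    assert res.interval is not None
    assert "1,000,000-2,000,000" in res.summary()
    bed = tmp_path / "interval.bed"
    res.to_bed(bed)
    from btmap.io import read_interval_bed

    back = read_interval_bed(bed)
    assert (back.chrom, back.start, back.end) == ("chr9", 1_000_000, 2_000_000)
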