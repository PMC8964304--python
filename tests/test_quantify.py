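"""Semi-quantification formula, Kovats RI and the two-stage replicate QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volatilome import quantify, simulate
from volatilome.quantify import (
    REASON_ARBITRATION,
    REASON_CV_OK,
    REASON_SINGLE_DEVIANT,
    REASON_UNRESOLVED,
    AlkaneLadder,
    apply_qc,
    assemble_matrix,
    kovats_ri,
    qc_filter_triplet,
    semi_quantify,
)

from conftest import replicate_table


class TestSemiQuantify:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1000.0, 1000.0, 2.0, 2.0), 100.0),  # unit ratios
            ((2000.0, 1000.0, 2.0, 1.0), 400.0),  # 2 * 2 * 100
            ((0.0, 1000.0, 2.0, 1.0), 0.0),
        ],
    )
    def test_worked_values(self, args, expected):
        assert semi_quantify(*args) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "args", [(10.0, 0.0, 1.0, 1.0), (10.0, 1.0, 1.0, 0.0), (-1.0, 1.0, 1.0, 1.0)]
    )
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            semi_quantify(*args)

    @given(
        a=st.floats(0.0, 1e8),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linearity(self, a, scale):
        base = semi_quantify(a, 1000.0, 2.0, 0.5)
        assert semi_quantify(a * scale, 1000.0, 2.0, 0.5) == pytest.approx(base * scale)
        assert semi_quantify(a, 1000.0, 2.0 * scale, 0.5) == pytest.approx(base * scale)
        assert semi_quantify(a, 1000.0 * scale, 2.0, 0.5) == pytest.approx(base / scale)
        assert semi_quantify(a, 1000.0, 2.0, 0.5 * scale) == pytest.approx(base / scale)


class TestKovats:
    ladder = AlkaneLadder(carbons=(8, 9, 10, 11, 12), times=(5.0, 7.5, 10.0, 12.0, 15.0))

    @pytest.mark.parametrize(
        "t, expected",
        [(10.0, 1000.0), (11.0, 1050.0), (12.0, 1100.0), (5.0, 800.0), (15.0, 1200.0)],
    )
    def test_interpolation(self, t, expected):
        assert kovats_ri(t, self.ladder) == pytest.approx(expected)

    @pytest.mark.parametrize("t", [4.9, 15.1])
    def test_no_extrapolation(self, t):
        with pytest.raises(ValueError):
            kovats_ri(t, self.ladder)

    def test_monotone_in_retention_time(self):
        ts = np.linspace(5.0, 15.0, 101)
        ris = [kovats_ri(t, self.ladder) for t in ts]
        assert np.all(np.diff(ris) >= 0)

    def test_invalid_ladder(self):
        with pytest.raises(ValueError):
            AlkaneLadder(carbons=(8, 9), times=(5.0, 4.0))
        with pytest.raises(ValueError):
            AlkaneLadder(carbons=(9, 8), times=(4.0, 5.0))


class TestTripletQc:
    @pytest.mark.parametrize(
        "values, reason, excluded",
        [
            ((100.0, 100.0, 100.0), REASON_CV_OK, ()),  # CV = 0
            # CV ~ 67.8%; deviations 4.8% / 185.7% -> replicate 300 out
            ((100.0, 105.0, 300.0), REASON_SINGLE_DEVIANT, (3,)),
            # CV ~ 55.0%; min deviation 37.5% not < 35% -> unresolved
            ((100.0, 160.0, 300.0), REASON_UNRESOLVED, ()),
            ((100.0, 120.0), REASON_CV_OK, ()),  # < 3 replicates: kept
        ],
    )
    def test_worked_triplets(self, values, reason, excluded):
        d = qc_filter_triplet(values)
        assert d.reason == reason
        assert d.excluded == excluded
        assert set(d.kept) | set(d.excluded) == set(range(1, len(values) + 1))

    def test_low_deviant_excluded(self):
        # symmetric case: the *minimum* replicate is the single deviant
        d = qc_filter_triplet((10.0, 100.0, 105.0))
        assert d.reason == REASON_SINGLE_DEVIANT
        assert d.excluded == (1,)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            qc_filter_triplet((np.nan, np.nan, np.nan))

    @given(st.permutations([100.0, 105.0, 300.0]))
    @settings(max_examples=6, derandomize=True)
    def test_permutation_invariance(self, values):
        d = qc_filter_triplet(values)
        assert d.reason == REASON_SINGLE_DEVIANT
        assert values[d.excluded[0] - 1] == 300.0
        assert len(d.excluded) <= 1

    @given(
        st.lists(st.floats(1.0, 1e4), min_size=3, max_size=3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_never_excludes_more_than_one(self, values):
        d = qc_filter_triplet(values)
        assert len(d.excluded) <= 1


class TestRunArbitration:
    def test_consistent_low_quality_run_excluded(self):
        # run 3 is wildly off for all five high-CV volatiles: two resolved by
        # the single-deviant rule, three unresolved -> arbitration removes
        # run 3 from the unresolved ones
        cells = {
            ("s1", f"v{i}"): vals
            for i, vals in enumerate(
                [
                    [100.0, 105.0, 400.0],  # single deviant
                    [50.0, 52.0, 200.0],  # single deviant
                    [100.0, 160.0, 300.0],  # unresolved
                    [80.0, 130.0, 250.0],  # unresolved
                    [60.0, 100.0, 190.0],  # unresolved
                    [10.0, 10.0, 10.0],  # clean
                ]
            )
        }
        _, decisions = apply_qc(replicate_table(cells))
        by_vol = {d.volatile: d for d in decisions}
        for v in ("v2", "v3", "v4"):
            assert by_vol[v].reason == REASON_ARBITRATION
            assert by_vol[v].excluded == (3,)
        assert by_vol["v5"].reason == REASON_CV_OK

    def test_no_high_cv_no_exclusions(self):
        cells = {("s1", "v0"): [10.0, 11.0, 12.0], ("s1", "v1"): [5.0, 5.0, 6.0]}
        _, decisions = apply_qc(replicate_table(cells))
        assert all(d.reason == REASON_CV_OK and not d.excluded for d in decisions)

    def test_split_votes_keep_all(self):
        # three unresolved volatiles implicating runs 1, 2, 3 respectively:
        # no strict majority, everything retained
        cells = {
            ("s1", "v0"): [300.0, 100.0, 160.0],
            ("s1", "v1"): [100.0, 300.0, 160.0],
            ("s1", "v2"): [100.0, 160.0, 300.0],
        }
        _, decisions = apply_qc(replicate_table(cells))
        for d in decisions:
            assert d.reason == REASON_UNRESOLVED
            assert set(d.kept) == {1, 2, 3}


class TestAssemble:
    def test_mean_of_kept_replicates(self):
        cells = {
            ("s1", "v0"): [1.0, 2.0, 3.0],
            ("s1", "v1"): [100.0, 105.0, 300.0],  # 300 excluded -> 102.5
            ("s2", "v0"): [4.0, 4.0, 4.0],
            ("s2", "v1"): [None, None, None],  # fully missing cell
        }
        table = replicate_table(cells)
        matrix, missing = assemble_matrix(table)
        assert matrix.loc["s1", "v0"] == pytest.approx(2.0)
        assert matrix.loc["s1", "v1"] == pytest.approx(102.5)
        assert np.isnan(matrix.loc["s2", "v1"])
        assert missing == pytest.approx(1 / 4)

    def test_survey_scale_missing_fraction(self):
        # 412 planted missing cells in a 148 x 85 grid -> 3.28% missing
        design = simulate.default_design(seed=2, n_volatiles=85)
        panel = simulate.simulate_panel(design)
        reps = simulate.simulate_replicates(
            panel, cv_tech=0.0, outlier_rate=0.0, missing_rate=0.0, seed=0
        )
        rng = np.random.default_rng(0)
        cells = rng.choice(148 * 85, size=412, replace=False)
        samples = np.array(panel.sample_ids)[cells // 85]
        volatiles = np.array(panel.volatile_ids)[cells % 85]
        kill = pd.MultiIndex.from_arrays([reps["sample"], reps["volatile"]]).isin(
            list(zip(samples, volatiles))
        )
        reps.loc[kill, "area"] = np.nan
        matrix, missing = assemble_matrix(reps)
        assert matrix.shape == (148, 85)
        assert missing == pytest.approx(412 / 12580)
        assert round(100 * missing, 2) == 3.28

    def test_zero_noise_round_trip(self, small_panel):
        # noise-free replicates assemble back to the true expected panel
        reps = simulate.simulate_replicates(
            small_panel, cv_tech=0.0, outlier_rate=0.0, missing_rate=0.0, seed=0
        )
        matrix, missing = assemble_matrix(reps)
        assert missing == 0.0
        assert np.allclose(
            matrix.loc[small_panel.sample_ids, small_panel.volatile_ids].to_numpy(),
            small_panel.expected.to_numpy(),
            rtol=1e-12,
        )

    def test_qc_report_frame(self):
        cells = {("s1", "v0"): [100.0, 105.0, 300.0]}
        _, decisions = apply_qc(replicate_table(cells))
        frame = quantify.decisions_frame(decisions)
        assert list(frame.columns) == ["sample", "volatile", "kept_runs", "excluded_runs", "reason"]
        assert frame.iloc[0]["excluded_runs"] == "3"
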