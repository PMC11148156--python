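"""The sequence-function correlation engine."""

import math

import numpy as np
import pandas as pd
import pytest

from sitefunc.profiles import VOLUME
from sitefunc.seqfunc import (
    MIN_N,
    CorrelationResult,
    SequenceFunctionModel,
    combined_property_regression,
    heatmap_from_tsv,
    heatmap_matrix,
    heatmap_to_tsv,
    hotspot_ranking,
    log_activities,
    position_activity_correlation,
)
from sitefunc.seqio import ActivityTable

from test_profiles import states_from


def textbook_pearson(x, y):
    """Independent sum-formula Pearson implementation (the oracle)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def activity_table(values: dict[str, dict[str, float]], floor=1e-3) -> ActivityTable:
    frame = pd.DataFrame(values)
    return ActivityTable(rates=frame, detection_floor=floor)


class TestLogActivities:
    def test_unit_rate_maps_to_zero(self):
        table = activity_table({"S1": {"E1": 1.0, "E2": 10.0, "E3": 4.58}})
        logact = log_activities(table)
        by_enzyme = logact.set_index("enzyme")["value"]
        assert by_enzyme["E1"] == pytest.approx(0.0)
        assert by_enzyme["E2"] == pytest.approx(1.0)
        assert by_enzyme["E3"] == pytest.approx(math.log10(4.58))
        assert by_enzyme["E3"] == pytest.approx(0.6609, abs=1e-4)

    def test_below_detection_excluded_by_default(self):
        table = activity_table({"S1": {"E1": 1.0, "E2": np.nan}})
        logact = log_activities(table)
        assert list(logact["enzyme"]) == ["E1"]

    def test_floor_policy_floors_and_flags(self):
        table = activity_table({"S1": {"E1": 1.0, "E2": np.nan, "E3": 0.0}})
        logact = log_activities(table, "floor").set_index("enzyme")
        assert logact.loc["E2", "value"] == pytest.approx(-3.0)
        assert bool(logact.loc["E2", "floored"])
        assert logact.loc["E3", "value"] == pytest.approx(-3.0)  # 0 == below detection
        assert not bool(logact.loc["E1", "floored"])

    def test_unknown_policy_rejected(self):
        table = activity_table({"S1": {"E1": 1.0, "E2": 2.0}})
        with pytest.raises(ValueError, match="nd_policy"):
            log_activities(table, "drop")


class TestPositionCorrelation:
    def planted_fixture(self, residues="GASVLIFW", slope=-0.01, noise=None):
        rows = {f"e{i}": r for i, r in enumerate(residues)}
        states = states_from(rows, [40])
        log10_v = {
            e: 1.0 + slope * VOLUME[rows[e]] + (0.0 if noise is None else noise[i])
            for i, e in enumerate(rows)
        }
        table = activity_table({"S1": {e: 10.0 ** v for e, v in log10_v.items()}})
        return states, table

    def test_exact_linear_signal_gives_perfect_correlation(self):
        states, table = self.planted_fixture(slope=+0.01)
        (res,) = position_activity_correlation(states, VOLUME,
                                               log_activities(table), "S1")
        assert res.status == "ok"
        assert res.r == pytest.approx(1.0)
        assert res.n_used == 8

    def test_negative_slope_gives_negative_correlation(self):
        states, table = self.planted_fixture(slope=-0.01)
        (res,) = position_activity_correlation(states, VOLUME,
                                               log_activities(table), "S1")
        assert res.r == pytest.approx(-1.0)

    def test_conserved_position_has_no_correlation(self):
        states = states_from({f"e{i}": "G" for i in range(5)}, [40])
        table = activity_table({"S1": {f"e{i}": float(i + 1) for i in range(5)}})
        (res,) = position_activity_correlation(states, VOLUME,
                                               log_activities(table), "S1")
        assert res.status == "conserved"
        assert res.r is None

    def test_too_few_pairs_is_insufficient(self):
        states = states_from({"a": "G", "b": "F", "c": "-", "d": "-"}, [40])
        table = activity_table({"S1": {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}})
        (res,) = position_activity_correlation(states, VOLUME,
                                               log_activities(table), "S1")
        assert res.status == "insufficient"
        assert res.n_used == 2

    def test_random_fixtures_match_textbook_pearson(self, rng):
        from sitefunc.seqio import AMINO_ACIDS

        for _ in range(100):
            n = int(rng.integers(4, 12))
            residues = [AMINO_ACIDS[i] for i in rng.integers(0, 20, n)]
            if len(set(residues)) < 2:
                residues[0] = "G" if residues[1] != "G" else "W"
            rows = {f"e{i}": r for i, r in enumerate(residues)}
            states = states_from(rows, [7])
            rates = {e: float(10 ** rng.normal(0, 1)) for e in rows}
            table = activity_table({"S1": rates})
            (res,) = position_activity_correlation(states, VOLUME,
                                                   log_activities(table), "S1")
            expect = textbook_pearson([VOLUME[rows[e]] for e in rows],
                                      [math.log10(rates[e]) for e in rows])
            assert res.r == pytest.approx(expect, abs=1e-12)

    def test_enzyme_order_does_not_change_r(self, rng):
        states, table = self.planted_fixture(noise=rng.normal(0, 0.3, 8))
        logact = log_activities(table)
        (res,) = position_activity_correlation(states, VOLUME, logact, "S1")
        shuffled = logact.sample(frac=1.0, random_state=7)
        (res2,) = position_activity_correlation(states, VOLUME, shuffled, "S1")
        assert res2.r == pytest.approx(res.r, abs=1e-15)

    def test_missing_substrate_is_an_error(self):
        states, table = self.planted_fixture()
        with pytest.raises(KeyError, match="S9"):
            position_activity_correlation(states, VOLUME, log_activities(table), "S9")

    def test_spearman_option(self):
        states, table = self.planted_fixture(slope=-0.01)
        (res,) = position_activity_correlation(states, VOLUME,
                                               log_activities(table), "S1",
                                               method="spearman")
        assert res.r == pytest.approx(-1.0)

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            CorrelationResult(1, "S1", 0.5, 5, "conserved")
        with pytest.raises(ValueError):
            CorrelationResult(1, "S1", 1.5, 5, "ok")
        with pytest.raises(ValueError):
            CorrelationResult(1, "S1", 0.5, 2, "ok")


class TestHeatmap:
    def grid_results(self):
        return [
            CorrelationResult(40, "S1", 0.9, 5, "ok"),
            CorrelationResult(40, "S2", -0.4, 5, "ok"),
            CorrelationResult(41, "S1", None, 5, "conserved"),
            CorrelationResult(41, "S2", None, 5, "conserved"),
        ]

    def test_conserved_row_is_all_sentinel(self):
        values, status = heatmap_matrix(self.grid_results())
        assert values.loc[41].isna().all()
        assert (status.loc[41] == "conserved").all()

    def test_cells_carry_the_correlation_values(self):
        values, _ = heatmap_matrix(self.grid_results())
        assert values.loc[40, "S1"] == 0.9
        assert values.loc[40, "S2"] == -0.4

    def test_tsv_roundtrip_exact(self, tmp_path):
        values, status = heatmap_matrix(self.grid_results())
        path = tmp_path / "grid.tsv"
        heatmap_to_tsv(values, status, path)
        values2, status2 = heatmap_from_tsv(path)
        pd.testing.assert_frame_equal(values2, values, check_names=False)
        assert (status2.to_numpy() == status.to_numpy()).all()


class TestCombinedRegression:
    def test_noiseless_planted_line_recovered(self):
        rows = {f"e{i}": r * 3 for i, r in enumerate("GASVLIFW")}
        states = states_from(rows, [166, 392, 427],
                             cluster_map={"T": [166, 392, 427]})
        slope, intercept = -0.01, 2.0
        rates = {
            e: 10 ** (intercept + slope * sum(VOLUME[c] for c in rows[e]))
            for e in rows
        }
        table = activity_table({"S1": rates})
        reg = combined_property_regression(states, VOLUME, [166, 392, 427],
                                           log_activities(table), "S1")
        assert reg.status == "ok"
        assert reg.slope == pytest.approx(slope, abs=1e-9)
        assert reg.intercept == pytest.approx(intercept, abs=1e-9)
        assert abs(reg.r) == pytest.approx(1.0, abs=1e-9)

    def test_two_points_flagged_insufficient(self):
        states = states_from({"a": "G", "b": "F"}, [1])
        table = activity_table({"S1": {"a": 1.0, "b": 2.0}})
        reg = combined_property_regression(states, VOLUME, [1],
                                           log_activities(table), "S1")
        assert reg.status == "insufficient"
        assert reg.slope is None

    def test_constant_combined_property_flagged(self):
        states = states_from({"a": "G", "b": "G", "c": "G"}, [1])
        table = activity_table({"S1": {"a": 1.0, "b": 2.0, "c": 3.0}})
        reg = combined_property_regression(states, VOLUME, [1],
                                           log_activities(table), "S1")
        assert reg.status == "conserved"

    def test_random_fixture_matches_normal_equations(self, rng):
        from sitefunc.seqio import AMINO_ACIDS

        for _ in range(50):
            n = int(rng.integers(4, 10))
            rows = {
                f"e{i}": "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 2))
                for i in range(n)
            }
            states = states_from(rows, [1, 2])
            rates = {e: float(10 ** rng.normal(0, 1)) for e in rows}
            table = activity_table({"S1": rates})
            reg = combined_property_regression(states, VOLUME, [1, 2],
                                               log_activities(table), "S1")
            x = np.array([sum(VOLUME[c] for c in rows[e]) for e in rows])
            y = np.array([math.log10(rates[e]) for e in rows])
            if np.ptp(x) == 0:
                assert reg.status == "conserved"
                continue
            design = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(design.T @ design, design.T @ y)
            assert reg.intercept == pytest.approx(beta[0], abs=1e-9)
            assert reg.slope == pytest.approx(beta[1], abs=1e-9)


class TestHotspots:
    def test_strong_planted_position_ranked_first(self):
        results = [
            CorrelationResult(40, "S1", -0.95, 8, "ok"),
            CorrelationResult(41, "S1", 0.2, 8, "ok"),
            CorrelationResult(42, "S1", None, 8, "conserved"),
            CorrelationResult(40, "S2", -0.85, 8, "ok"),
            CorrelationResult(41, "S2", 0.75, 8, "ok"),
        ]
        ranking = hotspot_ranking(results, min_abs_r=0.7)
        assert ranking.iloc[0]["position"] == 40
        assert ranking.iloc[0]["supporting_substrates"] == "S1,S2"
        assert 42 not in set(ranking["position"])

    def test_all_conserved_gives_empty_ranking(self):
        results = [CorrelationResult(p, "S1", None, 8, "conserved") for p in (1, 2)]
        assert hotspot_ranking(results).empty

    def test_raising_threshold_never_adds_positions(self, rng):
        results = [
            CorrelationResult(p, s, float(rng.uniform(-1, 1)), 8, "ok")
            for p in range(1, 11) for s in ("S1", "S2")
        ]
        previous = None
        for threshold in (0.2, 0.4, 0.6, 0.8, 0.95):
            ranked = set(hotspot_ranking(results, min_abs_r=threshold)["position"])
            if previous is not None:
                assert ranked <= previous
            previous = ranked

    def test_min_n_filters_thin_correlations(self):
        results = [
            CorrelationResult(1, "S1", 0.99, 3, "ok"),
            CorrelationResult(2, "S1", 0.9, 8, "ok"),
        ]
        ranking = hotspot_ranking(results, min_abs_r=0.5, min_n=5)
        assert list(ranking["position"]) == [2]

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            hotspot_ranking([], min_abs_r=0.0)
        with pytest.raises(ValueError):
            hotspot_ranking([], min_n=2)


class TestModelResults:
    def test_fit_produces_grid_and_summary(self, rng):
        rows = {f"e{i}": r + "H" for i, r in enumerate("GASVLIFW")}
        states = states_from(rows, [40, 41])
        rates = {
            "S1": {e: 10 ** (1.0 - 0.01 * VOLUME[rows[e][0]]) for e in rows},
            "S2": {e: float(10 ** rng.normal(0, 0.5)) for e in rows},
        }
        table = activity_table(rates)
        model = SequenceFunctionModel(states, table, VOLUME)
        results = model.fit()
        assert results.values.shape == (2, 2)
        assert results.status.loc[41, "S1"] == "conserved"
        assert results.values.loc[40, "S1"] == pytest.approx(-1.0)
        text = results.summary()
        assert "volume" in text and "pearson" in text
        assert not results.hotspots(min_abs_r=0.9).empty

    def test_model_rejects_disjoint_inputs(self):
        states = states_from({"a": "G", "b": "F", "c": "A"}, [1])
        table = activity_table({"S1": {"x": 1.0, "y": 2.0, "z": 3.0}})
        with pytest.raises(ValueError, match="shared"):
            SequenceFunctionModel(states, table)

    def test_all_nd_substrate_reported_insufficient(self):
        states = states_from({"a": "G", "b": "F", "c": "A"}, [1])
        table = activity_table({"S1": {"a": 1.0, "b": 2.0, "c": 3.0},
                                "S2": {"a": np.nan, "b": np.nan, "c": np.nan}})
        results = SequenceFunctionModel(states, table, VOLUME).fit()
        assert (results.status["S2"] == "insufficient").all()
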