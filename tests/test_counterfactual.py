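"""Counterfactual grid engine: eligibility, time shifts, surfaces, best cells."""

import numpy as np
import pandas as pd
import pytest

from ohca_counterfactual import (
    AdjustmentSpec,
    CounterfactualGrid,
    GroundTruthAdapter,
    apply_time_adjustment,
    best_adjustment,
    eligible_subset,
    encode,
    per_prefecture_grids,
    simulate_grid,
)
from conftest import make_record, table_of


@pytest.fixture(scope="module")
def oracle(small_cohort_config, small_schema):
    return GroundTruthAdapter(small_cohort_config, small_schema)


def small_spec(pair="transport_defib"):
    return AdjustmentSpec(factor_pair=pair, delta_transport_range=(-2, 2),
                          delta_intervention_range=(-2, 2))


class TestEligibility:
    def test_defib_pair_keeps_shockable_rhythms(self):
        table = table_of(
            make_record(initial_rhythm="VF"),
            make_record(initial_rhythm="asystole"),
            make_record(initial_rhythm="PEA"),
            make_record(initial_rhythm="pulseless_VT"),
        )
        sub = eligible_subset(table, AdjustmentSpec(factor_pair="transport_defib"))
        assert list(sub["initial_rhythm"]) == ["VF", "pulseless_VT"]

    def test_drug_pair_drops_ems_witnessed(self):
        rows = [make_record(ems_witnessed="yes")] * 2 + [make_record()] * 3
        sub = eligible_subset(table_of(*rows), AdjustmentSpec(factor_pair="transport_drug"))
        assert len(sub) == 3

    def test_eligibility_off_is_identity(self):
        table = table_of(make_record(initial_rhythm="asystole"))
        spec = AdjustmentSpec(factor_pair="transport_defib", apply_eligibility=False)
        assert len(eligible_subset(table, spec)) == 1

    def test_empty_subset_raises(self):
        table = table_of(make_record(initial_rhythm="asystole"))
        with pytest.raises(ValueError, match="transport_defib"):
            eligible_subset(table, AdjustmentSpec(factor_pair="transport_defib"))


class TestApplyTimeAdjustment:
    def test_clip_at_floor(self):
        table = table_of(make_record(n_defib=1, time_contact_to_defib=2.0))
        out = apply_time_adjustment(table, "defib", -5)
        assert out["time_contact_to_defib"].iloc[0] == 1.0

    def test_absent_intervention_stays_absent(self):
        table = table_of(make_record(n_drug_doses=0, time_contact_to_drug=np.nan))
        out = apply_time_adjustment(table, "drug", 3)
        assert np.isnan(out["time_contact_to_drug"].iloc[0])

    def test_integer_shift_and_no_mutation(self):
        table = table_of(make_record(time_contact_to_hospital=23.0))
        out = apply_time_adjustment(table, "transport", 10)
        assert out["time_contact_to_hospital"].iloc[0] == 33.0
        assert table["time_contact_to_hospital"].iloc[0] == 23.0

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown time factor"):
            apply_time_adjustment(table_of(make_record()), "scene", 1)


class TestSimulateGrid:
    def test_baseline_cell_is_exactly_zero(self, small_cohort, small_schema, oracle):
        grid = simulate_grid(oracle, small_schema, small_cohort, small_spec())
        assert grid.pct_change(0, 0) == 0.0

    def test_cells_cover_cartesian_product(self, small_cohort, small_schema, oracle):
        spec = small_spec()
        grid = simulate_grid(oracle, small_schema, small_cohort, spec)
        assert len(grid.cells) == len(spec.transport_deltas) * len(spec.intervention_deltas)
        got = set(zip(grid.cells["delta_transport"], grid.cells["delta_intervention"]))
        assert got == {(dt, di) for dt in spec.transport_deltas
                       for di in spec.intervention_deltas}

    def test_pct_change_definition_holds(self, small_cohort, small_schema, oracle):
        grid = simulate_grid(oracle, small_schema, small_cohort, small_spec())
        recomputed = 100.0 * (grid.cells["mean_pred"] - grid.baseline_mean) / grid.baseline_mean
        assert np.allclose(grid.cells["pct_change"], recomputed, atol=1e-12)

    def test_monotone_decreasing_in_transport_under_negative_beta(
        self, small_cohort, small_schema, oracle
    ):
        grid = simulate_grid(oracle, small_schema, small_cohort, small_spec())
        for di in (-2, 0, 2):
            series = [grid.pct_change(dt, di) for dt in range(-2, 3)]
            assert all(a > b for a, b in zip(series, series[1:]))

    def test_matches_per_record_brute_force(self, small_cohort, small_schema, oracle):
        """Engine mean per cell == a literal per-record loop (adjust, encode,
        predict, average), to within 1e-9."""
        test = small_cohort.head(300)
        spec = AdjustmentSpec(factor_pair="transport_defib",
                              delta_transport_range=(-1, 1),
                              delta_intervention_range=(-1, 1))
        grid = simulate_grid(oracle, small_schema, test, spec)
        eligible = eligible_subset(test, spec)
        for dt in spec.transport_deltas:
            for di in spec.intervention_deltas:
                probs = []
                for _, rec in eligible.iterrows():
                    r = rec.copy()
                    r["time_contact_to_hospital"] = max(1, r["time_contact_to_hospital"] + dt)
                    if not np.isnan(r["time_contact_to_defib"]):
                        r["time_contact_to_defib"] = max(1, r["time_contact_to_defib"] + di)
                    X = encode(r.to_frame().T, small_schema)
                    probs.append(float(oracle.predict_proba(X)[0]))
                engine = grid.cells[
                    (grid.cells["delta_transport"] == dt)
                    & (grid.cells["delta_intervention"] == di)
                ]["mean_pred"].iloc[0]
                assert engine == pytest.approx(np.mean(probs), abs=1e-9)

    def test_thresholded_count_mode(self, small_cohort, small_schema, oracle):
        grid = simulate_grid(oracle, small_schema, small_cohort, small_spec(),
                             count_mode="thresholded", threshold=0.05)
        assert grid.pct_change(0, 0) == 0.0
        n = grid.n_eligible
        assert all(
            abs((m * n) - round(m * n)) < 1e-6 for m in grid.cells["mean_pred"]
        )  # thresholded means are fractions of whole counts

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            AdjustmentSpec(delta_transport_range=(1, 5))
        with pytest.raises(ValueError, match="factor pair"):
            AdjustmentSpec(factor_pair="transport_scene")


class TestPerPrefecture:
    def test_one_grid_per_large_prefecture(self, small_cohort, small_schema, oracle):
        spec = AdjustmentSpec(factor_pair="transport_drug",
                              delta_transport_range=(-1, 1),
                              delta_intervention_range=(-1, 1))
        grids = per_prefecture_grids(oracle, small_schema, small_cohort, spec, n_min=30)
        counts = small_cohort[small_cohort["ems_witnessed"] == "no"]["prefecture"].value_counts()
        assert len(grids) == int((counts >= 30).sum())
        assert all(g.pct_change(0, 0) == 0.0 for g in grids)

    def test_small_prefecture_omitted_with_warning(
        self, small_cohort, small_schema, oracle, caplog
    ):
        spec = AdjustmentSpec(factor_pair="transport_drug",
                              delta_transport_range=(0, 0),
                              delta_intervention_range=(0, 0))
        import logging
        with caplog.at_level(logging.WARNING):
            grids = per_prefecture_grids(
                oracle, small_schema, small_cohort, spec, n_min=10**6
            )
        assert grids == []
        assert "skipped" in caplog.text

    def test_stratum_means_recover_pooled_mean(self, small_cohort, small_schema, oracle):
        """Law of total expectation: size-weighted per-prefecture means equal
        the pooled mean, cell by cell."""
        spec = AdjustmentSpec(factor_pair="transport_drug",
                              delta_transport_range=(-1, 1),
                              delta_intervention_range=(-1, 1))
        pooled = simulate_grid(oracle, small_schema, small_cohort, spec)
        grids = per_prefecture_grids(oracle, small_schema, small_cohort, spec, n_min=1)
        total_n = sum(g.n_eligible for g in grids)
        assert total_n == pooled.n_eligible
        for dt in spec.transport_deltas:
            for di in spec.intervention_deltas:
                weighted = sum(
                    g.n_eligible * float(
                        g.cells[(g.cells["delta_transport"] == dt)
                                & (g.cells["delta_intervention"] == di)]["mean_pred"].iloc[0]
                    )
                    for g in grids
                ) / total_n
                pooled_mean = float(
                    pooled.cells[(pooled.cells["delta_transport"] == dt)
                                 & (pooled.cells["delta_intervention"] == di)]["mean_pred"].iloc[0]
                )
                assert weighted == pytest.approx(pooled_mean, abs=1e-9)


class TestBestAdjustment:
    @staticmethod
    def grid_from(pct: dict[tuple[int, int], float]) -> CounterfactualGrid:
        rows = [
            {"delta_transport": dt, "delta_intervention": di,
             "mean_pred": 0.05 * (1 + p / 100), "pct_change": p}
            for (dt, di), p in pct.items()
        ]
        return CounterfactualGrid(
            spec=small_spec(), stratum="all", n_eligible=100,
            baseline_mean=0.05, cells=pd.DataFrame(rows),
        )

    def test_monotone_surface_corner(self):
        pct = {(dt, di): -(dt + di) for dt in range(-2, 3) for di in range(-2, 3)}
        assert best_adjustment(self.grid_from(pct)) == (-2, -2, 4.0)

    def test_flat_grid_prefers_no_adjustment(self):
        pct = {(dt, di): 0.0 for dt in range(-2, 3) for di in range(-2, 3)}
        assert best_adjustment(self.grid_from(pct)) == (0, 0, 0.0)

    def test_hand_built_maximum(self):
        pct = {(dt, di): 0.0 for dt in range(-2, 3) for di in range(-2, 3)}
        pct[(-2, 1)] = 7.5
        assert best_adjustment(self.grid_from(pct)) == (-2, 1, 7.5)
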