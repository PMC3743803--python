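"""PAF arithmetic, factor ranking and removal projections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mortframe import attribution as at
from mortframe.errors import ParameterError


class TestPaf:
    @pytest.mark.parametrize("rr, p_e, printed", [
        (1.13, 0.52, 0.06),   # male gender
        (1.40, 0.62, 0.20),   # not in a formal union
        (1.70, 0.39, 0.21),   # low socio-economic status
        (3.98, 0.42, 0.56),   # district antenatal HIV >= 30%
    ])
    def test_worked_examples_round_to_printed_values(self, rr, p_e, printed):
        assert round(at.paf(rr, p_e), 2) == pytest.approx(printed)

    def test_null_effect_and_zero_exposure(self):
        assert at.paf(1.0, 0.73) == 0.0
        assert at.paf(2.5, 0.0) == 0.0

    def test_protective_factor_negative(self):
        assert at.paf(0.5, 0.4) < 0.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ParameterError):
            at.paf(0.0, 0.5)

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            at.paf(2.0, 1.5)

    @given(st.floats(min_value=1.01, max_value=50.0),
           st.floats(min_value=0.0, max_value=0.99))
    def test_monotone_in_prevalence(self, rr, p_e):
        assert at.paf(rr, p_e + 0.01) > at.paf(rr, p_e)

    @given(st.floats(min_value=1.0, max_value=49.0),
           st.floats(min_value=0.01, max_value=1.0))
    def test_monotone_in_rr(self, rr, p_e):
        assert at.paf(rr + 0.5, p_e) > at.paf(rr, p_e)

    @given(st.floats(min_value=1.1, max_value=50.0))
    def test_limit_at_full_exposure(self, rr):
        assert at.paf(rr, 1.0) == pytest.approx((rr - 1.0) / rr, abs=1e-12)

    @given(st.floats(min_value=1.01, max_value=20.0),
           st.floats(min_value=0.001, max_value=0.999))
    def test_inversion_recovers_prevalence(self, rr, p_e):
        assert at.invert_paf(at.paf(rr, p_e), rr) == pytest.approx(p_e, abs=1e-12)


class TestPafCi:
    @pytest.mark.parametrize("rr_ci, p_e, printed", [
        ((1.26, 1.56), 0.62, (0.14, 0.26)),   # not in a formal union
        ((1.07, 1.19), 0.52, (0.04, 0.09)),   # male gender
    ])
    def test_substitution_reproduces_printed_intervals(self, rr_ci, p_e, printed):
        low, high = at.paf_ci(rr_ci, p_e)
        assert (round(low, 2), round(high, 2)) == printed

    def test_degenerate_interval(self):
        assert at.paf_ci((1.0, 1.0), 0.4) == (0.0, 0.0)

    def test_bounds_ordered(self):
        low, high = at.paf_ci((1.2, 3.4), 0.5)
        assert low <= high

    def test_invalid_interval_rejected(self):
        with pytest.raises(ParameterError):
            at.paf_ci((1.5, 1.2), 0.5)


class TestRanking:
    def test_zero_prevalence_factor_cannot_lead(self):
        prev = pd.DataFrame({"unit_id": ["u1"], "hiv": [0.0], "ses": [0.5]})
        ranked = at.rank_factors(prev, {"hiv": 3.98, "ses": 1.70})
        lead = ranked[ranked["rank"] == 1]["factor"].iloc[0]
        assert lead == "ses"

    def test_tie_break_is_deterministic(self):
        # identical PAFs: same rr and prevalence -> lexicographic factor order
        prev = pd.DataFrame({"unit_id": ["u1"], "beta": [0.3], "alpha": [0.3]})
        ranked = at.rank_factors(prev, {"beta": 2.0, "alpha": 2.0})
        first = ranked[ranked["rank"] == 1]["factor"].iloc[0]
        assert first == "alpha"

    def test_protective_factor_never_ranked(self):
        prev = pd.DataFrame({"unit_id": ["u1"], "good": [0.8], "bad": [0.2]})
        ranked = at.rank_factors(prev, {"good": 0.6, "bad": 1.5})
        assert ranked.loc[ranked["factor"] == "good", "rank"].isna().all()
        assert ranked.loc[ranked["factor"] == "good", "paf"].iloc[0] < 0

    def test_no_attributable_factor_gives_empty_ranking(self):
        prev = pd.DataFrame({"unit_id": ["u1"], "a": [0.5]})
        ranked = at.rank_factors(prev, {"a": 0.9})
        assert ranked["rank"].isna().all()

    def test_missing_prevalence_column_rejected(self):
        prev = pd.DataFrame({"unit_id": ["u1"], "a": [0.5]})
        with pytest.raises(ParameterError):
            at.rank_factors(prev, {"a": 1.2, "b": 1.5})

    def test_matches_brute_force_resort(self):
        """Rankings agree with an exhaustive re-sort of independently
        computed PAFs across many random units."""
        rng = np.random.default_rng(99)
        rrs = {"male": 1.13, "union": 1.40, "ses": 1.70, "hiv": 3.98}
        prev = pd.DataFrame({
            "unit_id": [f"u{i}" for i in range(40)],
            **{f: rng.uniform(0, 1, 40) for f in rrs},
        })
        ranked = at.rank_factors(prev, rrs)
        for _, row in prev.iterrows():
            # independent oracle: direct formula + python sort
            pafs = {f: row[f] * (rrs[f] - 1) / (1 + row[f] * (rrs[f] - 1)) for f in rrs}
            order = sorted(rrs, key=lambda f: (-pafs[f], -rrs[f], f))[:3]
            got = (ranked[(ranked["unit_id"] == row["unit_id"]) & ranked["rank"].notna()]
                   .sort_values("rank")["factor"].tolist())
            assert got == order

    def test_ranks_distinct_and_ordered_by_paf(self):
        rng = np.random.default_rng(7)
        rrs = {"a": 1.5, "b": 2.0, "c": 3.0}
        prev = pd.DataFrame({"unit_id": ["u1", "u2"],
                             **{f: rng.uniform(0.1, 0.9, 2) for f in rrs}})
        ranked = at.rank_factors(prev, rrs)
        for _, grp in ranked.dropna(subset=["rank"]).groupby("unit_id"):
            grp = grp.sort_values("rank")
            assert grp["rank"].tolist() == [1.0, 2.0, 3.0]
            assert (grp["paf"].diff().dropna() <= 1e-12).all()


def _three_unit_fixture():
    summary = pd.DataFrame({
        "unit_id": ["u1", "u2", "u3"],
        "proportion": [200.0, 150.0, 100.0],
        "population": [1000, 1000, 2000],
    })
    ranked = pd.DataFrame({
        "unit_id": ["u1", "u1", "u2", "u3"],
        "factor": ["hiv", "ses", "hiv", "ses"],
        "rr": [3.98, 1.70, 3.98, 1.70],
        "p_e": [0.5, 0.3, 0.2, 0.1],
        "paf": [0.5, 0.2, 0.35, 0.1],
        "rank": [1.0, 2.0, 1.0, 1.0],
    })
    return summary, ranked


class TestProjection:
    def test_hand_computed_multiplicative(self):
        summary, ranked = _three_unit_fixture()
        out = at.project_removal(summary, ranked, k=2).set_index("unit_id")
        assert out.loc["u1", "projected_k1"] == pytest.approx(100.0)
        assert out.loc["u1", "projected_k2"] == pytest.approx(80.0)
        assert out.loc["u2", "projected_k1"] == pytest.approx(150.0 * 0.65)
        assert out.loc["u2", "projected_k2"] == pytest.approx(150.0 * 0.65)
        assert out.loc["u3", "projected_k1"] == pytest.approx(90.0)

    def test_hand_computed_additive(self):
        summary, ranked = _three_unit_fixture()
        out = at.project_removal(summary, ranked, k=2, rule="additive").set_index("unit_id")
        assert out.loc["u1", "projected_k2"] == pytest.approx(200.0 * (1 - 0.7))

    def test_national_is_population_weighted_mean(self):
        summary, ranked = _three_unit_fixture()
        out = at.project_removal(summary, ranked, k=1).set_index("unit_id")
        expected = (100.0 * 1000 + 150.0 * 0.65 * 1000 + 90.0 * 2000) / 4000
        assert out.loc["national", "projected_k1"] == pytest.approx(expected)
        assert out.loc["national", "observed"] == pytest.approx(
            (200 * 1000 + 150 * 1000 + 100 * 2000) / 4000
        )

    def test_zero_paf_projection_is_identity(self):
        summary, ranked = _three_unit_fixture()
        ranked = ranked.assign(paf=0.0)
        out = at.project_removal(summary, ranked, k=3)
        units = out[out["unit_id"] != "national"]
        for k in (1, 2, 3):
            np.testing.assert_allclose(units[f"projected_k{k}"], units["observed"])

    def test_monotone_nonincreasing_in_depth(self):
        summary, ranked = _three_unit_fixture()
        for rule in ("multiplicative", "additive"):
            out = at.project_removal(summary, ranked, k=3, rule=rule)
            assert (out["projected_k1"] <= out["observed"] + 1e-12).all()
            assert (out["projected_k2"] <= out["projected_k1"] + 1e-12).all()
            assert (out["projected_k3"] <= out["projected_k2"] + 1e-12).all()
            assert (out["projected_k3"] >= 0).all()

    def test_depth_out_of_range_rejected(self):
        summary, ranked = _three_unit_fixture()
        with pytest.raises(ParameterError):
            at.project_removal(summary, ranked, k=4)

    def test_units_ordered_by_descending_observed(self):
        summary, ranked = _three_unit_fixture()
        out = at.project_removal(summary, ranked, k=1)
        units = out[out["unit_id"] != "national"]
        assert units["observed"].is_monotonic_decreasing


class TestPolicyTable:
    def test_single_factor_everywhere(self):
        ranked = pd.DataFrame({
            "unit_id": ["u1", "u2"], "factor": ["hiv", "hiv"],
            "rr": [3.98, 3.98], "p_e": [0.4, 0.5],
            "paf": [0.5, 0.6], "rank": [1.0, 1.0],
        })
        per_unit, tally = at.policy_table(ranked)
        assert len(per_unit) == 2
        assert tally.iloc[0]["share"] == pytest.approx(1.0)

    def test_constructed_55_percent_scenario(self):
        n_hiv, n_ses = 37, 30
        ranked = pd.DataFrame({
            "unit_id": [f"u{i}" for i in range(n_hiv + n_ses)],
            "factor": ["hiv"] * n_hiv + ["ses"] * n_ses,
            "rr": 2.0, "p_e": 0.4, "paf": 0.3, "rank": 1.0,
        })
        _, tally = at.policy_table(ranked)
        hiv_share = tally.set_index("factor").loc["hiv", "share"]
        assert hiv_share == pytest.approx(n_hiv / (n_hiv + n_ses))

    def test_empty_hotspot_set(self):
        ranked = pd.DataFrame(columns=["unit_id", "factor", "rr", "p_e", "paf", "rank"])
        per_unit, tally = at.policy_table(ranked)
        assert per_unit.empty and tally.empty

    def test_plot_writes_file(self, tmp_path):
        summary, ranked = _three_unit_fixture()
        out = at.project_removal(summary, ranked, k=3)
        path = tmp_path / "curves.png"
        at.plot_removal_curves(out, path)
        assert path.stat().st_size > 0
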