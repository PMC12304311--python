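"""Activity harmonization, curation, consensus scoring, candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import statepop as sp
from statepop.errors import InputError
from statepop.screening import IC50_PKD_OFFSET


class TestHarmonization:
    @pytest.mark.parametrize(
        "measure,value,p,harmonized",
        [
            ("IC50", 1e-6, 6.0, 6.35),
            ("Kd", 1e-9, 9.0, 9.0),
            ("Ki", 1e-5, 5.0, 5.0),
        ],
    )
    def test_pkd_equivalents(self, measure, value, p, harmonized):
        rec = sp.harmonize_activity(measure, value, "c1")
        assert rec.p_value == pytest.approx(p)
        assert rec.harmonized_pkd == pytest.approx(harmonized)

    def test_ic50_offset_is_exactly_035(self):
        rec = sp.harmonize_activity("IC50", 3.7e-8)
        assert rec.harmonized_pkd - rec.p_value == pytest.approx(IC50_PKD_OFFSET)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(min_value=1e-12, max_value=1e-2))
    def test_p_value_invertible(self, value):
        rec = sp.harmonize_activity("Kd", value)
        assert 10 ** (-rec.p_value) == pytest.approx(value, rel=1e-9)

    def test_double_harmonization_rejected(self):
        rec = sp.harmonize_activity("IC50", 1e-6)
        with pytest.raises(InputError):
            sp.harmonize_activity("IC50", rec)

    @pytest.mark.parametrize("bad", [0.0, -1e-9, float("nan"), float("inf")])
    def test_nonpositive_values_rejected(self, bad):
        with pytest.raises(InputError):
            sp.harmonize_activity("Kd", bad)

    def test_unknown_measure_rejected(self):
        with pytest.raises(InputError):
            sp.harmonize_activity("EC50", 1e-6)


class TestTruncation:
    @pytest.mark.parametrize("d,expected", [(25.0, 20.0), (0.3, 1.0), (5.0, 5.0)])
    def test_clamp_to_prediction_range(self, d, expected):
        assert sp.truncate_distance_label(d) == expected

    def test_array_input_and_nonfinite(self):
        np.testing.assert_allclose(
            sp.truncate_distance_label([0.0, 10.0, 100.0]), [1.0, 10.0, 20.0]
        )
        with pytest.raises(InputError):
            sp.truncate_distance_label(float("nan"))


class TestCuration:
    def test_boundary_values_inclusive(self):
        recs = [
            sp.ComplexRecord("ok", 384, 128, 1),
            sp.ComplexRecord("long", 385, 100, 1),
            sp.ComplexRecord("fat", 300, 129, 1),
            sp.ComplexRecord("two", 300, 100, 2),
            sp.ComplexRecord("bad", 300, 100, 1, parseable=False),
        ]
        kept, reasons = sp.curate_complexes(recs)
        assert [r.complex_id for r in kept] == ["ok"]
        assert set(reasons) == {"long", "fat", "two", "bad"}
        assert "385 residues > 384" in reasons["long"][0]

    def test_drop_reasons_partition_dropped_set(self):
        rng = np.random.default_rng(14)
        recs = [
            sp.ComplexRecord(
                f"c{i}",
                int(rng.integers(200, 500)),
                int(rng.integers(50, 200)),
                int(rng.integers(1, 3)),
                bool(rng.random() > 0.1),
            )
            for i in range(60)
        ]
        kept, reasons = sp.curate_complexes(recs)
        kept_ids = {r.complex_id for r in kept}
        assert kept_ids.isdisjoint(reasons)
        assert kept_ids | set(reasons) == {r.complex_id for r in recs}
        assert all(reasons[c] for c in reasons)  # every dropped record has a cause


class TestScoring:
    def test_minmax_definition(self):
        df = pd.DataFrame({"m": [4.0, 6.0, 8.0]}, index=list("abc"))
        np.testing.assert_allclose(
            sp.normalize_model_scores(df)["m"], [0.0, 0.5, 1.0]
        )

    def test_constant_column_maps_to_half_with_warning(self):
        df = pd.DataFrame({"m": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = sp.normalize_model_scores(df)
        np.testing.assert_allclose(out["m"], 0.5)

    def test_normalization_preserves_rank_order(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("wxyz"))
        out = sp.normalize_model_scores(df)
        for col in df.columns:
            assert out[col].between(0, 1).all()
            assert (out[col].rank() == df[col].rank()).all()

    def test_overall_score_is_row_minimum(self):
        df = pd.DataFrame([[0.9, 0.4, 0.8]], columns=list("abc"))
        score, eligible = sp.overall_affinity_score(df)
        assert score.iloc[0] == pytest.approx(0.4)
        assert eligible.iloc[0]

    def test_missing_entry_makes_compound_ineligible(self):
        df = pd.DataFrame([[0.9, np.nan, 0.8], [0.2, 0.3, 0.4]], columns=list("abc"))
        score, eligible = sp.overall_affinity_score(df)
        assert not eligible.iloc[0] and np.isnan(score.iloc[0])
        assert eligible.iloc[1]

    def test_overall_matches_brute_force(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.random((5, 3)))
        score, _ = sp.overall_affinity_score(df)
        for i in range(5):
            assert score.iloc[i] == pytest.approx(min(df.iloc[i]))

    def test_competition_rank_ties_share_better_rank(self):
        df = pd.DataFrame({"m": [8.0, 6.0, 8.0]})
        np.testing.assert_allclose(sp.model_ranks(df)["m"], [1, 3, 1])
        dec = pd.DataFrame({"m": [9.0, 8.0, 7.0, 6.0]})
        np.testing.assert_allclose(sp.model_ranks(dec)["m"], [1, 2, 3, 4])

    def test_rank_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=30)
        ranks = sp.model_ranks(pd.DataFrame({"m": col}))["m"].to_numpy()
        oracle = np.array([1 + np.sum(col > x) for x in col])
        np.testing.assert_allclose(ranks, oracle)

    def test_distance_scores_orientation_and_bounds(self):
        df = pd.DataFrame(
            {"K745": [2.0, 10.0, 30.0], "E762": [3.0, 12.0, 25.0], "D855": [2.5, 9.0, 40.0]}
        )
        scores = sp.distance_scores(df, ["K745", "E762", "D855"])
        np.testing.assert_allclose(scores.iloc[0], 0.0)  # closest compound
        assert scores.iloc[2]["K745"] == pytest.approx(1.0)  # farthest on K745
        assert scores.to_numpy().min() >= 0 and scores.to_numpy().max() <= 1

    def test_missing_residue_column_errors(self):
        df = pd.DataFrame({"K745": [2.0, 3.0]})
        with pytest.raises(InputError):
            sp.distance_scores(df, ["K745", "E762"])


class TestSelection:
    def _tables(self, overall, best_rank, dscores):
        idx = ["c"]
        return (
            pd.Series([overall], index=idx),
            pd.Series([True], index=idx),
            pd.DataFrame({"m1": [best_rank], "m2": [500]}, index=idx),
            pd.DataFrame(
                {k: [v] for k, v in zip(["K745", "E762", "D855"], dscores)}, index=idx
            ),
        )

    def test_score_clause_selects(self):
        cands = sp.select_candidates(*self._tables(0.35, 500, (0.1, 0.2, 0.4)))
        assert cands.selected == ["c"]
        assert cands.rationale["c"]["clause"] == "overall_score"

    def test_distance_clause_rejects(self):
        cands = sp.select_candidates(*self._tables(0.1, 3, (0.1, 0.2, 0.6)))
        assert cands.selected == []

    def test_rank_clause_selects_ranks_below_ten(self):
        selected_at = {
            r: sp.select_candidates(*self._tables(0.1, r, (0.1, 0.1, 0.1))).selected
            for r in (9, 10)
        }
        assert selected_at[9] == ["c"] and selected_at[10] == []

    def test_planted_library_selected_exactly(self):
        cfg = sp.ScreeningConfig(seed=77)
        affinity, distances, _, truth = sp.generate_screening_library(cfg)
        cands, summary = sp.screen(affinity, distances)
        assert sorted(cands.selected) == sorted(truth.planted_passers)
        # brute-force clause-by-clause oracle
        normalized = sp.normalize_model_scores(affinity)
        overall, eligible = sp.overall_affinity_score(normalized)
        ranks = sp.model_ranks(affinity)
        dsc = sp.distance_scores(distances, cfg.functional_residues)
        crit = sp.SelectionCriteria(functional_residues=cfg.functional_residues)
        expected = [
            c for c in affinity.index
            if eligible[c]
            and ((overall[c] > crit.overall_score_min)
                 or (ranks.loc[c] < crit.rank_cutoff).any())
            and (dsc.loc[c] < crit.distance_score_max).all()
        ]
        assert cands.selected == expected

    def test_selection_monotone_in_normalized_scores(self):
        """Improving a compound's normalized scores never deselects it;
        worsening its distance scores never selects anyone new."""
        cfg = sp.ScreeningConfig(n_compounds=60, n_passers=8, seed=31)
        affinity, distances, _, _ = sp.generate_screening_library(cfg)
        normalized = sp.normalize_model_scores(affinity)
        overall, eligible = sp.overall_affinity_score(normalized)
        ranks = sp.model_ranks(affinity)
        dsc = sp.distance_scores(distances, cfg.functional_residues)
        base = sp.select_candidates(overall, eligible, ranks, dsc)
        picked = base.selected[0]
        # better overall score keeps it selected
        up = overall.copy()
        up[picked] = min(up[picked] + 0.2, 1.0)
        assert picked in sp.select_candidates(up, eligible, ranks, dsc).selected
        # worse distance scores only ever shrink the candidate set
        far = dsc.copy()
        far.loc[picked] = np.minimum(far.loc[picked] + 0.6, 1.0)
        worse = sp.select_candidates(overall, eligible, ranks, far)
        assert set(worse.selected) <= set(base.selected)
        assert picked not in worse.selected

    def test_pipeline_determinism(self):
        cfg = sp.ScreeningConfig(seed=5)
        affinity, distances, _, _ = sp.generate_screening_library(cfg)
        a, _ = sp.screen(affinity, distances)
        b, _ = sp.screen(affinity.copy(), distances.copy())
        assert a.to_json() == b.to_json()

    def test_zero_distance_threshold_selects_nothing(self):
        cfg = sp.ScreeningConfig(seed=5)
        affinity, distances, _, _ = sp.generate_screening_library(cfg)
        crit = sp.SelectionCriteria(distance_score_max=0.0)
        cands, _ = sp.screen(affinity, distances, crit)
        assert cands.selected == []
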