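"""Pair extraction, transition counting, averaging and prevalence summaries."""

import numpy as np
import pandas as pd
import pytest

import metsmarkov as mm
from metsmarkov.estimation import (
    AnnualMatrix,
    DuplicateVisitError,
    StateNeverObservedError,
    annual_matrix,
    count_transitions,
    estimate_matrix_from_pairs,
)
from metsmarkov.states import STATE_LABELS

from conftest import classified_frame_from_sequences


def panel_from_visits(visits):
    """visits: list of (subject, year, state_label[, sex, age])."""
    rows = []
    for v in visits:
        subject, year, state = v[:3]
        sex = v[3] if len(v) > 3 else "male"
        age = v[4] if len(v) > 4 else 30
        rows.append(dict(subject_id=subject, visit_year=year, sex=sex,
                         age_years=age, state=state))
    return pd.DataFrame(rows)


class TestBuildVisitPairs:
    def test_three_consecutive_visits_give_two_pairs(self):
        panel = panel_from_visits([
            ("a", 2010, "no_components"), ("a", 2011, "iso_obesity"), ("a", 2012, "mets"),
        ])
        pairs = mm.build_visit_pairs(panel)
        assert len(pairs) == 2
        assert list(pairs["from_year"]) == [2010, 2011]

    def test_gap_years_yield_no_pair(self):
        panel = panel_from_visits([("a", 2010, "no_components"), ("a", 2012, "mets")])
        assert len(mm.build_visit_pairs(panel)) == 0

    def test_single_visit_yields_no_pair(self):
        panel = panel_from_visits([("a", 2010, "no_components")])
        assert len(mm.build_visit_pairs(panel)) == 0

    def test_duplicate_subject_year_is_an_error(self):
        panel = panel_from_visits([("a", 2010, "no_components"), ("a", 2010, "mets")])
        with pytest.raises(DuplicateVisitError):
            mm.build_visit_pairs(panel)

    def test_unsorted_input_is_sorted_internally(self):
        panel = panel_from_visits([
            ("a", 2012, "mets"), ("a", 2010, "no_components"), ("a", 2011, "iso_obesity"),
        ])
        pairs = mm.build_visit_pairs(panel)
        assert list(pairs["from_state"]) == [0, 2]
        assert list(pairs["to_state"]) == [2, 6]

    def test_pair_counts_match_brute_force_recount(self):
        """On a synthetic panel, pair counts per year-pair equal the number of
        subjects observed in both years of the pair."""
        cfg = mm.SyntheticConfig(seed=7, n_subjects=400)
        panel = mm.classify_panel(mm.make_panel(cfg))
        pairs = mm.build_visit_pairs(panel)
        by_year = pairs.groupby("from_year").size()
        for year, n in by_year.items():
            in_y = set(panel.loc[panel["visit_year"] == year, "subject_id"])
            in_y1 = set(panel.loc[panel["visit_year"] == year + 1, "subject_id"])
            assert n == len(in_y & in_y1)

    def test_out_of_range_entry_age_drops_subject(self):
        panel = panel_from_visits([
            ("a", 2010, "no_components", "male", 65), ("a", 2011, "mets", "male", 66),
            ("b", 2010, "no_components", "male", 30), ("b", 2011, "mets", "male", 31),
        ])
        pairs = mm.build_visit_pairs(panel)
        assert set(pairs["subject_id"]) == {"b"}


class TestCountTransitions:
    def test_small_tally(self):
        panel = panel_from_visits([
            ("a", 2010, "no_components"), ("a", 2011, "no_components"),
            ("b", 2010, "no_components"), ("b", 2011, "no_components"),
            ("c", 2010, "no_components"), ("c", 2011, "iso_hypertension"),
            ("d", 2010, "no_components"), ("d", 2011, "iso_obesity"),
        ])
        counts = count_transitions(mm.build_visit_pairs(panel))
        assert list(counts[0]) == [2, 1, 1, 0, 0, 0, 0]
        assert counts.sum() == 4

    def test_empty_input_gives_zeros(self):
        pairs = mm.build_visit_pairs(panel_from_visits([("a", 2010, "mets")]))
        assert count_transitions(pairs).sum() == 0

    def test_counts_match_direct_iteration_oracle(self):
        """Tally from the estimator equals a brute-force per-pair loop."""
        cfg = mm.SyntheticConfig(seed=3, n_subjects=300)
        panel = mm.classify_panel(mm.make_panel(cfg))
        pairs = mm.build_visit_pairs(panel)
        got = count_transitions(pairs)
        expected = np.zeros((7, 7), dtype=int)
        for _, row in pairs.iterrows():
            expected[row["from_state"], row["to_state"]] += 1
        assert (got == expected).all()

    def test_conservation(self):
        cfg = mm.SyntheticConfig(seed=5, n_subjects=500)
        panel = mm.classify_panel(mm.make_panel(cfg))
        pairs = mm.build_visit_pairs(panel)
        for group in pairs["group"].unique():
            for y in pairs["from_year"].unique():
                sel = pairs[(pairs["group"] == group) & (pairs["from_year"] == y)]
                counts = count_transitions(pairs, group=group, year_pair=(y, y + 1))
                assert counts.sum() == len(sel)


class TestAnnualMatrix:
    def test_row_normalization(self):
        counts = np.zeros((7, 7), dtype=int)
        counts[0, :3] = [2, 1, 1]
        am = annual_matrix(counts)
        assert np.allclose(am.probs[0, :3], [0.5, 0.25, 0.25])
        assert am.defined[0]

    def test_all_zero_row_flagged_undefined(self):
        am = annual_matrix(np.zeros((7, 7), dtype=int))
        assert not am.defined.any()
        assert np.all(am.probs == 0)

    def test_single_self_count_gives_unit_mass(self):
        counts = np.zeros((7, 7), dtype=int)
        counts[4, 4] = 1
        am = annual_matrix(counts)
        assert am.probs[4, 4] == 1.0


class TestAverageMatrices:
    def _annual(self, probs, defined=None, yp=(2010, 2011)):
        probs = np.asarray(probs, dtype=float)
        defined = np.ones(7, bool) if defined is None else np.asarray(defined)
        return AnnualMatrix(year_pair=yp, probs=probs, defined=defined, n_pairs=1)

    def test_averaging_identical_matrices_is_idempotent(self, men_young):
        annuals = [self._annual(men_young.probs), self._annual(men_young.probs, yp=(2011, 2012))]
        avg = mm.average_matrices(annuals)
        assert np.allclose(avg.probs, men_young.probs, atol=1e-12)
        assert (avg.row_support == 2).all()

    def test_mean_of_two_unit_rows(self):
        a = np.eye(7)
        b = np.eye(7)
        b[0] = 0
        b[0, 1] = 1
        avg = mm.average_matrices([self._annual(a), self._annual(b, yp=(2011, 2012))])
        assert np.allclose(avg.probs[0], [0.5, 0.5, 0, 0, 0, 0, 0])

    def test_undefined_rows_are_excluded_from_the_mean(self):
        a = np.eye(7)
        b = np.eye(7)
        b[0] = 0  # undefined in second year-pair
        defined_b = np.array([False] + [True] * 6)
        avg = mm.average_matrices([self._annual(a), self._annual(b, defined_b, (2011, 2012))])
        assert np.allclose(avg.probs[0], np.eye(7)[0])
        assert avg.row_support[0] == 1 and avg.row_support[1] == 2

    def test_state_never_observed_is_a_hard_error(self):
        a = np.eye(7)
        a[6] = 0
        defined = np.array([True] * 6 + [False])
        with pytest.raises(StateNeverObservedError, match="mets"):
            mm.average_matrices([self._annual(a, defined)])

    def test_permutation_invariance_in_year_pair_order(self):
        rng = np.random.default_rng(11)
        annuals = []
        for k in range(4):
            m = rng.random((7, 7)) + 0.1
            m /= m.sum(axis=1, keepdims=True)
            annuals.append(self._annual(m, yp=(2010 + k, 2011 + k)))
        fwd = mm.average_matrices(annuals).probs
        rev = mm.average_matrices(annuals[::-1]).probs
        assert np.allclose(fwd, rev, atol=1e-15)


class TestEstimation:
    def test_recovers_known_chain_at_moderate_size(self, men_young):
        cfg = mm.SyntheticConfig(
            seed=42, n_subjects=50000, group_fractions={"men_20_40": 1.0},
            visits_pmf=(0, 0, 0, 0, 1.0),
            initial_state={mm.GROUPS[0]: np.full(7, 1 / 7)},
        )
        seqs = mm.sample_state_sequences(cfg)
        frame = classified_frame_from_sequences(seqs)
        est = mm.estimate_matrix(frame, mm.GROUPS[0])
        assert np.max(np.abs(est.probs - men_young.probs)) < 0.01

    def test_pooled_estimator_agrees_with_average_on_one_year_pair(self):
        # every subject has exactly 2 visits in the same calendar years, so
        # there is a single year-pair and the two estimators must coincide
        cfg = mm.SyntheticConfig(
            seed=13, n_subjects=3000, visits_pmf=(1.0, 0, 0, 0, 0),
            entry_year_range=(2010, 2011),
            initial_state={g: np.full(7, 1 / 7) for g in mm.GROUPS},
        )
        panel = mm.classify_panel(mm.make_panel(cfg))
        pairs = mm.build_visit_pairs(panel)
        group = mm.GROUPS[0]
        avg = estimate_matrix_from_pairs(pairs, group, pooled=False)
        pooled = estimate_matrix_from_pairs(pairs, group, pooled=True)
        np.testing.assert_allclose(avg.probs, pooled.probs, atol=1e-12)

    def test_unobserved_origin_state_fails_estimation(self):
        panel = panel_from_visits([
            ("a", 2010, "no_components"), ("a", 2011, "iso_obesity"), ("a", 2012, "mets"),
            ("b", 2010, "iso_obesity"), ("b", 2011, "mets"), ("b", 2012, "mets"),
            ("c", 2010, "iso_hypertension"), ("c", 2011, "iso_hyperglycemia"),
            ("c", 2012, "iso_dyslipidemia"),
            ("d", 2010, "two_components"), ("d", 2011, "two_components"),
            ("d", 2012, "two_components"),
        ])
        pairs = mm.build_visit_pairs(panel)
        with pytest.raises(StateNeverObservedError):
            # dyslipidemia origin appears only as a terminal state
            estimate_matrix_from_pairs(pairs, mm.GROUPS[0])

    def test_every_estimated_matrix_is_row_stochastic(self):
        cfg = mm.SyntheticConfig(seed=9, n_subjects=2000)
        panel = mm.classify_panel(mm.make_panel(cfg))
        for matrix in mm.estimate_group_matrices(panel).values():
            assert mm.validate_matrix(matrix.probs, tol=1e-9)


class TestFollowupPrevalence:
    def test_all_mets_panel_is_100_percent_everywhere(self):
        panel = panel_from_visits([
            ("a", 2010, "mets"), ("a", 2011, "mets"),
            ("b", 2010, "mets"), ("b", 2011, "mets"), ("b", 2012, "mets"),
        ])
        for c in ("obesity", "hyperglycemia", "hypertension", "dyslipidemia"):
            panel[c] = True
        out = mm.followup_prevalence(panel)
        assert (out["mets_pct"] == 100.0).all()

    def test_single_subject_conversion(self):
        panel = panel_from_visits([("a", 2010, "no_components"), ("a", 2011, "mets")])
        for c in ("obesity", "hyperglycemia", "hypertension", "dyslipidemia"):
            panel[c] = [False, True]
        out = mm.followup_prevalence(panel).set_index("followup_years")
        assert out.loc[0, "mets_pct"] == 0.0
        assert out.loc[1, "mets_pct"] == 100.0

    def test_matches_brute_force_recount(self):
        cfg = mm.SyntheticConfig(seed=21, n_subjects=500)
        panel = mm.classify_panel(mm.make_panel(cfg))
        out = mm.followup_prevalence(panel).set_index("followup_years")
        entry = panel.groupby("subject_id")["visit_year"].min()
        for k in out.index:
            sub = panel[panel["visit_year"] - panel["subject_id"].map(entry) == k]
            assert out.loc[k, "n"] == len(sub)
            expected_pct = 100.0 * (sub["state"] == "mets").mean()
            assert out.loc[k, "mets_pct"] == pytest.approx(expected_pct)
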