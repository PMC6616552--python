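"""Discretization, pairing, pooled Somers' D, jackknife SE and the screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from astrobiome import (
    RelAbundanceTable,
    build_within_subject_pairs,
    discretize_abundance,
    jackknife_se,
    screen_combinations,
    somers_d_pooled,
    validate_cytokines,
    validate_metadata,
)
from astrobiome.io import CYTOKINE_SESSIONS
from astrobiome.somers import _round_half_away


def brute_force_somers(series):
    """Independent oracle: series maps subject -> list of (Y, X) tuples.

    Enumerates every within-subject pair with two nested loops and applies
    the conditional definition directly.
    """
    conc = disc = denom = 0
    for obs in series.values():
        for (y1, x1), (y2, x2) in itertools.combinations(obs, 2):
            dy, dx = y2 - y1, x2 - x1
            if dy == 0:
                continue
            denom += 1
            if dy * dx > 0:
                conc += 1
            elif dy * dx < 0:
                disc += 1
    if denom == 0:
        return None
    return (conc - disc) / denom


def pairs_frame(series):
    rows = []
    for subj, obs in series.items():
        for (y1, x1), (y2, x2) in itertools.combinations(obs, 2):
            rows.append({"subject": subj, "session_a": "", "session_b": "",
                         "dY": int(y2 - y1), "dX": float(x2 - x1),
                         "valid_pair": True})
    return pd.DataFrame(rows)


class TestDiscretization:
    def _disc(self, ra_by_sample, otu="o1"):
        sessions = CYTOKINE_SESSIONS[: len(ra_by_sample)]
        rel = RelAbundanceTable(pd.DataFrame(
            {f"s{i}": [v, 1 - v] for i, v in enumerate(ra_by_sample)},
            index=[otu, "rest"]))
        meta = validate_metadata(pd.DataFrame({
            "subject_id": ["AstA"] * len(ra_by_sample),
            "site": ["stool"] * len(ra_by_sample),
            "timepoint": list(sessions),
        }, index=[f"s{i}" for i in range(len(ra_by_sample))]))
        return discretize_abundance(rel, meta)

    def test_level_of_half_is_minus_one(self):
        # log2(0.5) = -1 exactly
        disc = self._disc([0.5, 0.5])
        assert (disc.loc[disc.otu == "o1", "Y"] == -1).all()

    def test_nearest_integer_rule(self):
        # log2(0.3) = -1.737 -> -2
        disc = self._disc([0.3, 0.3])
        assert (disc.loc[disc.otu == "o1", "Y"] == -2).all()

    def test_zero_maps_one_below_minimum_positive_level(self):
        disc = self._disc([0.3, 0.0, 0.3])
        o = disc[disc.otu == "o1"].set_index("session")
        assert o.loc["FD7", "Y"] == -3  # min positive level -2, minus 1
        assert bool(o.loc["FD7", "zero_flag"])

    def test_all_zero_otu_omitted(self):
        rel = RelAbundanceTable(pd.DataFrame(
            {"s0": [0.0, 1.0], "s1": [0.0, 1.0]}, index=["gone", "rest"]))
        meta = validate_metadata(pd.DataFrame({
            "subject_id": ["AstA", "AstA"], "site": ["stool", "stool"],
            "timepoint": ["L-60", "FD7"]}, index=["s0", "s1"]))
        disc = discretize_abundance(rel, meta)
        assert "gone" not in set(disc["otu"])

    def test_round_half_away_from_zero(self):
        assert _round_half_away(np.array([0.5, -0.5, 1.5, -2.5])).tolist() == \
            [1, -1, 2, -3]

    @given(st.floats(min_value=1e-6, max_value=1.0),
           st.floats(min_value=2.0, max_value=64.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_twofold_separation(self, ra, ratio):
        """Abundances differing by >= 2x never share a level."""
        lo, hi = ra, min(ra * ratio, 1.0)
        if hi / lo < 2.0:
            return
        y_lo = _round_half_away(np.array([np.log2(lo)]))[0]
        y_hi = _round_half_away(np.array([np.log2(hi)]))[0]
        assert abs(y_hi - y_lo) >= 1

    @given(st.floats(min_value=1e-6, max_value=0.5),
           st.floats(min_value=0.7072, max_value=1.414))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_same_dyadic_level_merges(self, ra, ratio):
        """Abundances within (1/sqrt 2, sqrt 2) of a common dyadic level
        share the discretized level."""
        level = _round_half_away(np.array([np.log2(ra)]))[0]
        center = 2.0 ** level
        a, b = center * ratio, center / ratio
        # both inside the open dyadic cell around `center`
        if not (2 ** (level - 0.5) < a < 2 ** (level + 0.5)):
            return
        if not (2 ** (level - 0.5) < b < 2 ** (level + 0.5)):
            return
        ya = _round_half_away(np.array([np.log2(a)]))[0]
        yb = _round_half_away(np.array([np.log2(b)]))[0]
        assert ya == yb == level


def _panel_frame(rows):
    return validate_cytokines(pd.DataFrame(rows))


def _disc_frame(entries):
    return pd.DataFrame(entries, columns=["subject", "session", "otu", "Y",
                                          "zero_flag"])


class TestPairing:
    def test_five_sessions_give_ten_pairs(self):
        disc = _disc_frame([("A", s, "o1", i, False)
                            for i, s in enumerate(CYTOKINE_SESSIONS)])
        panel = _panel_frame([
            {"subject_id": "A", "session": s, "analyte": "x",
             "concentration": float(i + 1), "censored": False}
            for i, s in enumerate(CYTOKINE_SESSIONS)])
        pairs, n_valid = build_within_subject_pairs(disc, panel, "x", "o1")
        assert len(pairs) == 10
        assert n_valid == 5

    def test_pairs_never_cross_subjects(self):
        entries = [("A", s, "o1", i, False)
                   for i, s in enumerate(CYTOKINE_SESSIONS)]
        entries += [("B", s, "o1", i, False)
                    for i, s in enumerate(CYTOKINE_SESSIONS[:3])]
        disc = _disc_frame(entries)
        panel_rows = [
            {"subject_id": subj, "session": s, "analyte": "x",
             "concentration": 2.0, "censored": False}
            for subj, s, *_ in entries]
        pairs, _ = build_within_subject_pairs(disc, _panel_frame(panel_rows),
                                              "x", "o1")
        assert len(pairs) == 10 + 3
        counts = pairs.groupby("subject").size()
        assert counts["A"] == 10 and counts["B"] == 3

    def test_valid_comparisons_require_positive_ra_and_uncensored(self):
        disc = _disc_frame([
            ("A", "L-60", "o1", 1, False),
            ("A", "FD7", "o1", -5, True),    # zero abundance
            ("A", "FD180", "o1", 2, False),
        ])
        panel = _panel_frame([
            {"subject_id": "A", "session": "L-60", "analyte": "x",
             "concentration": 2.0, "censored": False},
            {"subject_id": "A", "session": "FD7", "analyte": "x",
             "concentration": 3.0, "censored": False},
            {"subject_id": "A", "session": "FD180", "analyte": "x",
             "concentration": 1.0, "censored": True, "detection_limit": 1.0},
        ])
        pairs, n_valid = build_within_subject_pairs(disc, panel, "x", "o1")
        assert len(pairs) == 3       # sessions with both measurements
        assert n_valid == 1          # only L-60 is RA>0 and uncensored
        _, n_valid_pairs = build_within_subject_pairs(
            disc, panel, "x", "o1", comparison_unit="pairs")
        assert n_valid_pairs == 0


class TestSomersD:
    def test_perfect_concordance_is_plus_one(self):
        series = {"A": [(i, float(i)) for i in range(5)]}
        assert somers_d_pooled(pairs_frame(series))["D"] == 1.0

    def test_perfect_discordance_is_minus_one(self):
        series = {"A": [(i, float(-i)) for i in range(5)]}
        assert somers_d_pooled(pairs_frame(series))["D"] == -1.0

    def test_hand_example_one_third(self):
        series = {"A": [(0, 1.0), (1, 3.0), (2, 2.0)]}
        stat = somers_d_pooled(pairs_frame(series))
        assert stat["concordant"] == 2 and stat["discordant"] == 1
        assert stat["D"] == pytest.approx(1 / 3)

    def test_x_ties_count_in_denominator_only(self):
        series = {"A": [(0, 1.0), (1, 1.0), (2, 2.0)]}
        stat = somers_d_pooled(pairs_frame(series))
        # pairs: (0,1) tied on X, (0,2) concordant, (1,2) concordant
        assert stat["n_untied"] == 3
        assert stat["D"] == pytest.approx(2 / 3)

    def test_all_y_ties_rejected(self):
        series = {"A": [(1, 1.0), (1, 2.0)]}
        with pytest.raises(ValueError, match="tied"):
            somers_d_pooled(pairs_frame(series))

    def test_antisymmetric_under_x_negation(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            series = {f"S{s}": [(int(rng.integers(-3, 4)),
                                 float(rng.normal()))
                                for _ in range(5)] for s in range(3)}
            pf = pairs_frame(series)
            if (pf["dY"] != 0).sum() == 0:
                continue
            d1 = somers_d_pooled(pf)["D"]
            neg = {s: [(y, -x) for y, x in obs] for s, obs in series.items()}
            d2 = somers_d_pooled(pairs_frame(neg))["D"]
            assert d1 == -d2

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n_subj = int(rng.integers(1, 10))
            series = {
                f"S{s}": [(int(rng.integers(-4, 5)), float(rng.normal()))
                          for _ in range(int(rng.integers(2, 6)))]
                for s in range(n_subj)
            }
            expected = brute_force_somers(series)
            pf = pairs_frame(series)
            if expected is None:
                with pytest.raises(ValueError):
                    somers_d_pooled(pf)
                continue
            stat = somers_d_pooled(pf)
            # exact rational agreement (same integer ratio, same float)
            assert stat["D"] == (stat["concordant"]
                                 - stat["discordant"]) / stat["n_untied"]
            assert stat["D"] == expected


class TestJackknife:
    def test_two_subject_closed_formula(self):
        series = {"A": [(0, 1.0), (1, 2.0), (2, 3.0)],
                  "B": [(0, 3.0), (1, 1.0), (2, 2.0)]}
        pf = pairs_frame(series)
        se, g = jackknife_se(pf)
        d_a = brute_force_somers({"A": series["A"]})
        d_b = brute_force_somers({"B": series["B"]})
        mean = (d_a + d_b) / 2
        expected = np.sqrt(0.5 * ((d_b - mean) ** 2 + (d_a - mean) ** 2))
        assert g == 2
        assert se == pytest.approx(expected, abs=1e-12)

    def test_identical_patterns_give_zero_se(self):
        series = {s: [(0, 1.0), (1, 2.0), (2, 3.0)] for s in "ABC"}
        se, g = jackknife_se(pairs_frame(series))
        assert se == 0.0 and g == 3

    def test_single_subject_rejected(self):
        series = {"A": [(0, 1.0), (1, 2.0)]}
        with pytest.raises(ValueError, match="2 subjects"):
            jackknife_se(pairs_frame(series))


def _screen_inputs(n_subjects=3, sessions=CYTOKINE_SESSIONS, ra=0.1,
                   conc=5.0):
    samples, meta_rows, panel_rows = {}, [], []
    k = 0
    for s in range(n_subjects):
        for sess in sessions:
            sid = f"s{k}"; k += 1
            samples[sid] = [ra, 1 - ra]
            meta_rows.append({"sample_id": sid, "subject_id": f"Ast{s}",
                              "site": "stool", "timepoint": sess})
            panel_rows.append({"subject_id": f"Ast{s}", "session": sess,
                               "analyte": "x", "concentration": conc,
                               "censored": False})
    rel = RelAbundanceTable(pd.DataFrame(samples, index=["o1", "rest"]))
    meta = validate_metadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    panel = validate_cytokines(pd.DataFrame(panel_rows))
    return rel, meta, panel


class TestScreen:
    def test_exclusion_boundary_ten_vs_nine(self):
        rel, meta, panel = _screen_inputs(n_subjects=2)
        # 2 subjects x 5 sessions = 10 valid observations -> included path
        res = screen_combinations(rel, meta, panel, ["o1"], analytes=["x"],
                                  min_comparisons=10)
        assert res.iloc[0]["n_valid"] == 10
        assert "fewer than 10" not in res.iloc[0]["reason"]
        # censor one observation -> 9 valid -> excluded
        panel9 = panel.copy()
        panel9.loc[0, "censored"] = True
        panel9.loc[0, "detection_limit"] = panel9.loc[0, "concentration"]
        res9 = screen_combinations(rel, meta, validate_cytokines(panel9),
                                   ["o1"], analytes=["x"],
                                   min_comparisons=10)
        assert res9.iloc[0]["excluded"]
        assert "fewer than 10" in res9.iloc[0]["reason"]

    def test_constant_abundance_excluded_as_all_tied(self):
        rel, meta, panel = _screen_inputs()
        res = screen_combinations(rel, meta, panel, ["o1"], analytes=["x"])
        assert res.iloc[0]["excluded"]
        assert "tied" in res.iloc[0]["reason"]

    def test_grid_size_is_candidates_times_analytes(self, small_cohort):
        from astrobiome import (CohortSpec, generate_cohort,
                                generate_cytokine_panel, OtuTable,
                                to_relative_abundance)
        spec, cohort = small_cohort
        panel = generate_cytokine_panel(spec, cohort)
        stool = [s for s in cohort.metadata.index[cohort.metadata.site == "stool"]
                 if s in cohort.table.counts.columns]
        sub = OtuTable(cohort.table.counts[stool], cohort.table.taxonomy)
        rel = to_relative_abundance(
            OtuTable(sub.counts[sub.counts.sum(axis=1) > 0],
                     cohort.table.taxonomy))
        cands = rel.otu_ids[:4]
        analytes = list(spec.analytes[:5])
        res = screen_combinations(rel, cohort.metadata, panel, cands,
                                  analytes=analytes)
        assert len(res) == 20
        assert res["D"].dropna().between(-1, 1).all()
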