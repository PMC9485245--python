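"""Psychometric constructions, cumulative-Gaussian fits, probit stimulation
tests, PSE-shift measures, CCI and correct rates."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import statsmodels.api as sm

from spiralflow.behavior import DecisionModelParams, TaskDesign, TrialTable, simulate_session
from spiralflow.psychometrics import (
    PsychometricFit,
    bin_dpse_by_preference,
    build_counts,
    cci,
    correct_rate,
    delta_pse,
    fit_cumgauss,
    probit_stim_test,
    psychometric_flowpattern,
    psychometric_general,
    psychometric_normal,
)


def table_from_rows(rows, design=None):
    df = pd.DataFrame(rows)
    for col, default in [
        ("session_id", "s"), ("trial", 0), ("paradigm", "AFC4"),
        ("version", "fine"), ("rewarded", False),
    ]:
        if col not in df:
            df[col] = default
    design = design or TaskDesign.fine(reps_per_level=1)
    return TrialTable(df=df, design=design, params=None, seed=None)


def counts_cell(plane, value, microstim, cw=0, ccw=0, left=0, right=0):
    rows = []
    for choice, k in (("CW", cw), ("CCW", ccw), ("LEFT", left), ("RIGHT", right)):
        rows += [
            dict(plane_shown=plane, stim_value=value, microstim=microstim, choice=choice)
        ] * k
    return rows


class TestCountsAndConstructions:
    def test_counting_one_of_each(self):
        t = table_from_rows(counts_cell("ambiguous", 0.0, False, 1, 1, 1, 1))
        c = build_counts(t)
        row = c.df.iloc[0]
        assert (row[["CW", "CCW", "LEFT", "RIGHT"]] == 1).all()
        assert c.total == 4

    def test_empty_table_gives_empty_counts(self):
        t = table_from_rows(counts_cell("roll", 1.15, False, cw=1))
        t.df = t.df.iloc[0:0]
        assert build_counts(t).total == 0

    def test_order_invariance(self, rng):
        rows = (
            counts_cell("roll", 1.15, False, 3, 2, 1, 0)
            + counts_cell("roll", -1.15, True, 1, 4, 0, 2)
        )
        t1 = table_from_rows(rows)
        t2 = table_from_rows([rows[i] for i in rng.permutation(len(rows))])
        a = build_counts(t1).df.sort_values(["plane_shown", "stim_value", "microstim"])
        b = build_counts(t2).df.sort_values(["plane_shown", "stim_value", "microstim"])
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def test_unknown_choice_label_rejected(self):
        t = table_from_rows([dict(plane_shown="roll", stim_value=1.0,
                                  microstim=False, choice="UP")])
        with pytest.raises(ValueError, match="unknown choice"):
            build_counts(t)

    def test_normal_proportion_arithmetic(self):
        c = build_counts(table_from_rows(counts_cell("roll", 1.15, False, cw=30, ccw=10)))
        d = psychometric_normal(c, "roll")
        assert d.prop[0] == pytest.approx(0.75)
        assert d.n[0] == 40

    def test_equal_counts_give_half(self):
        c = build_counts(table_from_rows(counts_cell("roll", 0.0, False, cw=7, ccw=7)))
        assert psychometric_normal(c, "roll").prop[0] == 0.5

    def test_empty_denominator_is_missing_not_zero(self):
        c = build_counts(
            table_from_rows(counts_cell("roll", 1.15, False, left=5, right=5))
        )
        d = psychometric_normal(c, "roll")
        assert np.isnan(d.prop[0]) and d.n[0] == 0

    def test_general_error_arithmetic(self):
        c = build_counts(
            table_from_rows(counts_cell("roll", 1.15, False, 30, 10, 5, 5))
        )
        assert psychometric_general(c, "roll").prop[0] == pytest.approx(0.6)

    def test_general_never_exceeds_normal(self):
        c = build_counts(
            table_from_rows(
                counts_cell("roll", 1.15, False, 12, 4, 3, 1)
                + counts_cell("roll", -1.15, False, 2, 9, 1, 0)
            )
        )
        dn = psychometric_normal(c, "roll")
        dg = psychometric_general(c, "roll")
        assert (dg.prop <= dn.prop + 1e-12).all()

    def test_flowpattern_axis_and_proportions(self):
        rows = (
            counts_cell("roll", 2.87, False, cw=10, ccw=10)  # no L/R choices
            + counts_cell("ambiguous", 0.0, False, 10, 10, 30, 30)
            + counts_cell("translation", 1.15, False, left=5, right=5)
        )
        d = psychometric_flowpattern(build_counts(table_from_rows(rows)))
        np.testing.assert_array_equal(d.levels, [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(d.prop, [0.0, 0.75, 1.0])


class TestCumGaussFit:
    def make_exact_data(self, mu, sigma, levels, n=10**6):
        p = norm.cdf((levels - mu) / sigma)
        return levels, p * n, np.full(len(levels), float(n))

    def test_exact_proportions_recover_parameters(self):
        levels = np.array([-8.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, 8.0])
        x, k, n = self.make_exact_data(0.75, 3.0, levels)
        fit = fit_cumgauss(x, k, n)
        assert fit.mu == pytest.approx(0.75, abs=1e-6)
        assert fit.sigma == pytest.approx(3.0, abs=1e-6)

    def test_curve_passes_half_at_pse_and_84_at_threshold(self):
        fit = PsychometricFit(mu=0.5, sigma=2.0, construction="normal",
                              loglik=0.0, n_trials=100, converged=True)
        assert fit.predict(0.5) == pytest.approx(0.5)
        assert fit.predict(0.5 + 2.0) == pytest.approx(norm.cdf(1.0))

    def test_degenerate_data_flagged_not_converged(self):
        levels = np.array([-2.0, 0.0, 2.0])
        fit = fit_cumgauss(levels, np.zeros(3), np.full(3, 20.0))
        assert not fit.converged

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="three"):
            fit_cumgauss([0.0, 1.0], [1, 5], [10, 10])

    def test_recovery_within_ci_across_replicates(self, rng):
        """Seeded replicates at 9 levels x 200 trials: the fitted PSE falls in
        its own 95% CI in about 95% of runs (coverage check at small scale;
        the full 500-replicate version runs in the acceptance suite)."""
        levels = np.array([-8.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, 8.0])
        mu_true, sigma_true = 0.75, 3.0
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            k = rng.binomial(200, norm.cdf((levels - mu_true) / sigma_true))
            fit = fit_cumgauss(levels, k, np.full(9, 200.0))
            lo, hi = fit.mu_ci95
            hits += lo <= mu_true <= hi
        assert hits / n_rep >= 0.90


class TestProbitStimTest:
    def test_null_model_usually_not_significant(self):
        params = DecisionModelParams()
        table = simulate_session(TaskDesign.fine(), params, 2)
        res = probit_stim_test(table, "roll")
        assert res.converged
        assert 0.0 <= res.p_pse <= 1.0

    def test_control_only_probit_matches_cumgauss(self):
        """With no stimulation terms, -b0/b1 and 1/b1 are the ML PSE and
        threshold; cross-check the custom fit against statsmodels probit."""
        design = TaskDesign.fine(reps_per_level=100)
        table = simulate_session(design, DecisionModelParams(lapse=0.0), 3)
        df = table.df
        sub = df[df["plane_shown"].isin(["roll", "ambiguous"])]
        sub = sub[sub["choice"].isin(["CW", "CCW"])]
        y = (sub["choice"] == "CW").astype(int).to_numpy()
        x = sub["stim_value"].to_numpy()
        fitp = sm.Probit(y, np.column_stack([np.ones_like(x), x])).fit(disp=0)
        b0, b1 = fitp.params
        counts = build_counts(table)
        d = psychometric_normal(counts, "roll")
        ok = d.informative
        fit = fit_cumgauss(d.levels[ok], d.successes()[ok], d.n[ok])
        assert fit.mu == pytest.approx(-b0 / b1, abs=1e-3)
        assert fit.sigma == pytest.approx(1.0 / b1, rel=1e-3)

    def test_duplicating_trials_preserves_point_estimates(self, small_design):
        table = simulate_session(
            small_design, DecisionModelParams(delta_roll=1.0), 4
        )
        doubled = TrialTable(
            df=pd.concat([table.df, table.df], ignore_index=True),
            design=table.design, params=table.params, seed=table.seed,
        )
        a = probit_stim_test(table, "roll")
        b = probit_stim_test(doubled, "roll")
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-5)

    def test_power_grows_with_injected_shift(self):
        """Rejection frequency for the PSE term increases with delta."""
        design = TaskDesign.fine(reps_per_level=15)
        rates = []
        for delta in (0.0, 2.0):
            rej = 0
            for s in range(30):
                t = simulate_session(
                    design, DecisionModelParams(delta_roll=delta), 100 + s
                )
                res = probit_stim_test(t, "roll")
                rej += res.converged and res.p_pse < 0.05
            rates.append(rej / 30)
        assert rates[1] > rates[0]


class TestDeltaPSE:
    def fit(self, mu, sigma=4.0):
        return PsychometricFit(mu=mu, sigma=sigma, construction="normal",
                               loglik=0.0, n_trials=100, converged=True)

    def test_no_shift_gives_zero(self):
        d = delta_pse(self.fit(1.0), self.fit(1.0), +1)
        assert d.signed == 0.0 and d.normalized == 0.0

    def test_normalization_arithmetic(self):
        d = delta_pse(self.fit(2.0, sigma=4.0), self.fit(0.0), +1)
        assert d.signed == pytest.approx(2.0)
        assert d.normalized == pytest.approx(0.5)

    def test_preferred_sign_orients_shift(self):
        dp = delta_pse(self.fit(0.0), self.fit(-2.0), +1)
        dm = delta_pse(self.fit(0.0), self.fit(-2.0), -1)
        assert dp.signed == 2.0 and dm.signed == -2.0

    def test_simulated_shift_matches_injected_offset(self):
        """Variant-2 sessions with a known labeled-line offset: the median
        signed PSE shift across sessions matches the injected value (in this
        model the stimulated curve's mean shifts by exactly delta)."""
        design = TaskDesign.fine(reps_per_level=20)
        delta = 1.0
        shifts = []
        for s in range(40):
            t = simulate_session(
                design, DecisionModelParams(delta_roll=delta, delta_trans=0.5), 200 + s
            )
            counts = build_counts(t)
            fits = {}
            for flag, tag in ((False, "ctrl"), (True, "stim")):
                d = psychometric_normal(counts, "roll", microstim=flag)
                ok = d.informative
                fits[tag] = fit_cumgauss(d.levels[ok], d.successes()[ok], d.n[ok])
            shifts.append(delta_pse(fits["ctrl"], fits["stim"], +1).signed)
        med = np.median(shifts)
        sem = np.std(shifts) / np.sqrt(len(shifts))
        assert med == pytest.approx(delta, abs=4 * sem + 0.1)

    def test_unconverged_fit_rejected(self):
        bad = PsychometricFit(mu=0, sigma=1, construction="normal",
                              loglik=0, n_trials=10, converged=False)
        with pytest.raises(ValueError, match="converged"):
            delta_pse(bad, self.fit(0.0), +1)


class TestCCI:
    def test_equal_frequencies_give_zero(self):
        rows = counts_cell("ambiguous", 0.0, False, 5, 5, 5, 5) + counts_cell(
            "ambiguous", 0.0, True, 5, 5, 5, 5
        )
        r = cci(table_from_rows(rows), cr_gate=0.0)
        assert r.included and r.value == 0.0

    def test_doubling_translation_choices_gives_one(self):
        rows = counts_cell("ambiguous", 0.0, False, 6, 6, 2, 2) + counts_cell(
            "ambiguous", 0.0, True, 4, 4, 4, 4
        )
        r = cci(table_from_rows(rows), cr_gate=0.0)
        assert r.value == pytest.approx(1.0)  # 0.5 vs 0.25

    def test_gate_excludes_poor_sessions(self):
        # all pattern choices wrong -> control CR 0 < gate
        rows = (
            counts_cell("roll", 2.87, False, left=10)
            + counts_cell("roll", 2.87, True, cw=10)
            + counts_cell("ambiguous", 0.0, False, 2, 2, 2, 2)
            + counts_cell("ambiguous", 0.0, True, 2, 2, 2, 2)
        )
        r = cci(table_from_rows(rows), cr_gate=0.65)
        assert not r.included and np.isnan(r.value)

    def test_no_control_translation_choices_is_missing(self):
        rows = counts_cell("ambiguous", 0.0, False, cw=8) + counts_cell(
            "ambiguous", 0.0, True, left=8
        )
        r = cci(table_from_rows(rows), cr_gate=0.0)
        assert not r.included and np.isnan(r.value)

    def test_cci_lower_bound(self):
        rows = counts_cell("ambiguous", 0.0, False, 0, 0, 8, 8) + counts_cell(
            "ambiguous", 0.0, True, 8, 8, 0, 0
        )
        r = cci(table_from_rows(rows), cr_gate=0.0)
        assert r.value == -1.0

    def test_variant3_shift_direction_recovered(self):
        """Pattern shift toward translation gives CCI > 0, toward roll < 0."""
        design = TaskDesign.fine(reps_per_level=15)
        for shift, expect_pos in ((2.0, True), (-2.0, False)):
            vals = []
            for s in range(20):
                t = simulate_session(
                    design,
                    DecisionModelParams(model_variant=3, pattern_shift=shift,
                                        delta_roll=0.5, delta_trans=0.25),
                    300 + s,
                )
                r = cci(t, cr_gate=0.0)
                if r.included:
                    vals.append(r.value)
            frac_pos = np.mean(np.array(vals) > 0)
            assert (frac_pos > 0.8) if expect_pos else (frac_pos < 0.2)


class TestCorrectRate:
    def test_perfect_chooser(self):
        rows = counts_cell("roll", 2.87, False, cw=10) + counts_cell(
            "translation", -1.15, False, right=10
        )
        t = table_from_rows(rows)
        for mode in ("intra", "general", "flow_pattern"):
            assert correct_rate(t, mode=mode) == 1.0

    def test_uniform_chooser_chance_levels(self, rng):
        choices = rng.choice(["CW", "CCW", "LEFT", "RIGHT"], 40_000)
        rows = [
            dict(plane_shown="roll", stim_value=2.87, microstim=False, choice=c)
            for c in choices
        ]
        t = table_from_rows(rows)
        assert correct_rate(t, mode="general") == pytest.approx(0.25, abs=0.01)
        assert correct_rate(t, mode="intra") == pytest.approx(0.5, abs=0.02)
        assert correct_rate(t, mode="flow_pattern") == pytest.approx(0.5, abs=0.01)

    def test_noise_injection_reduces_stimulated_cr(self):
        """Stimulation that only degrades the signal (variant-3 pattern shift
        with no within-plane help) lowers the stimulated flow-pattern CR."""
        design = TaskDesign.fine(reps_per_level=40)
        t = simulate_session(
            design,
            DecisionModelParams(model_variant=3, pattern_shift=3.0),
            7,
        )
        res = correct_rate(t, mode="flow_pattern", by_stim=True, plane="roll")
        assert res["delta_cr_pp"] < 0

    def test_ambiguous_trials_excluded(self):
        rows = counts_cell("ambiguous", 0.0, False, 4, 4, 4, 4) + counts_cell(
            "roll", 1.15, False, cw=5
        )
        assert correct_rate(table_from_rows(rows), mode="general") == 1.0


class TestBinByPreference:
    def test_flat_profile(self):
        prefs = np.array([-170.0, -90.0, 0.1, 45.0, 90.0, 170.0])
        vals = np.full(6, 0.4)
        out = bin_dpse_by_preference(prefs, vals)
        np.testing.assert_allclose(out["mean"].to_numpy(), 0.4)

    def test_single_site(self):
        out = bin_dpse_by_preference(np.array([90.0]), np.array([1.2]))
        assert (out["mean"] == 1.2).all()
        assert out["n"].max() == 1

    def test_sine_magnitude_profile_peaks_at_poles(self, rng):
        prefs = rng.uniform(-180, 180, 400)
        vals = np.abs(np.sin(np.deg2rad(prefs))) + rng.normal(0, 0.05, 400)
        out = bin_dpse_by_preference(prefs, vals)
        peak = out.loc[out["mean"].idxmax(), "center_deg"]
        assert min(abs(abs(peak) - 90.0), abs(abs(peak) - 90.0) % 360) <= 20.0
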