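"""Weighted survival estimators and their classical-form reductions."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from colonsurv import survival as surv
from colonsurv.survival import OutcomeSpec


def _random_survival(rng, n, hr=1.0, censor_rate=0.5):
    group = rng.integers(0, 2, size=n)  # 1 = More Adherent
    rate = 0.3 * np.exp(np.log(hr) * (1 - group))
    t = rng.exponential(1 / rate)
    c = rng.exponential(1 / censor_rate, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "group": group,
            "weight": 1.0,
        }
    )


class TestOutcomeSpec:
    def test_presets(self):
        assert OutcomeSpec.cancer_specific().event_causes == frozenset({"cancer"})
        assert OutcomeSpec.noncancer_specific().entry_day == 365
        assert OutcomeSpec.overall().horizon_day == 5 * 365

    def test_entry_must_precede_horizon(self):
        with pytest.raises(ValueError):
            OutcomeSpec("bad", frozenset({"cancer"}), entry_day=2000, horizon_day=1825)


class TestBuildOutcome:
    @pytest.fixture()
    def toy(self):
        patients = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C"],
                "death_day": pd.array([900, 900, 2100], dtype="Int64"),
                "death_cause": ["cancer", "noncancer", "cancer"],
            }
        )
        counts = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C"],
                "final_treatment_day": [0, 0, 0],
                "last_followup_day": [900, 900, 2100],
            }
        )
        weights = pd.DataFrame(
            {"patient_id": ["A", "B", "C"], "treatment": [1, 0, 1], "weight": [1.0, 1.0, 1.0]}
        )
        return patients, counts, weights

    def test_overall_event_passes_through(self, toy):
        tab = surv.build_outcome(*toy, OutcomeSpec.overall())
        a = tab.set_index("patient_id")
        assert a.loc["A", "time"] == 900 and a.loc["A", "event"] == 1

    def test_cause_specific_censors_other_causes(self, toy):
        tab = surv.build_outcome(*toy, OutcomeSpec.cancer_specific())
        a = tab.set_index("patient_id")
        assert a.loc["B", "time"] == 900 and a.loc["B", "event"] == 0

    def test_horizon_censors_late_deaths(self, toy):
        tab = surv.build_outcome(*toy, OutcomeSpec.overall())
        a = tab.set_index("patient_id")
        assert a.loc["C", "time"] == 1825 and a.loc["C", "event"] == 0

    def test_delayed_entry_drops_first_year_followup(self, toy):
        patients, counts, weights = toy
        counts.loc[0, "last_followup_day"] = 200  # follow-up ends inside year 1
        patients.loc[0, "death_day"] = 200
        tab = surv.build_outcome(patients, counts, weights, OutcomeSpec.noncancer_specific())
        assert "A" not in set(tab["patient_id"])
        assert (tab["entry"] == 365).all()


class TestWeightedKM:
    def test_matches_hand_computed_table(self):
        """Classical KM on six patients, worked by hand.

        Events at t=2 (1 of 6 at risk), t=4 (1 of 4), t=7 (1 of 2):
        S = 5/6, then 5/6 * 3/4, then 5/8 * 1/2.
        """
        time = np.array([2, 3, 4, 5, 7, 8])
        event = np.array([1, 0, 1, 0, 1, 0])
        curve = surv.weighted_km(time, event)
        np.testing.assert_allclose(curve["time"], [2, 4, 7])
        np.testing.assert_allclose(curve["survival"], [5 / 6, 5 / 6 * 3 / 4, 5 / 16])

    def test_matches_lifelines_at_unit_weights(self):
        rng = np.random.default_rng(10)
        df = _random_survival(rng, 150)
        curve = surv.weighted_km(df["time"], df["event"])
        kmf = KaplanMeierFitter().fit(df["time"], df["event"])
        ours = curve.set_index("time")["survival"]
        theirs = kmf.survival_function_.iloc[:, 0]
        for t, s in ours.items():
            assert s == pytest.approx(theirs.loc[t], abs=1e-10)

    def test_scale_invariance_of_weights(self):
        rng = np.random.default_rng(11)
        df = _random_survival(rng, 80)
        c1 = surv.weighted_km(df["time"], df["event"], np.ones(80))
        c2 = surv.weighted_km(df["time"], df["event"], np.full(80, 2.0))
        np.testing.assert_allclose(c1["survival"], c2["survival"])

    def test_single_patient_steps_to_zero(self):
        curve = surv.weighted_km(np.array([5.0]), np.array([1]))
        assert curve["survival"].tolist() == [0.0]

    def test_curves_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(12)
        df = _random_survival(rng, 200)
        w = rng.uniform(0.5, 3.0, size=200)
        curve = surv.weighted_km(df["time"], df["event"], w)
        s = curve["survival"].to_numpy()
        assert ((s >= -1e-12) & (s <= 1 + 1e-12)).all()
        assert (np.diff(s) <= 1e-12).all()

    def test_delayed_entry_shrinks_early_risk_sets(self):
        time = np.array([10.0, 10.0, 20.0])
        event = np.array([1, 1, 1])
        entry = np.array([0.0, 15.0, 0.0])
        curve = surv.weighted_km(time, event, entry=entry)
        # at t=10 only two subjects entered
        assert curve.set_index("time").loc[10.0, "at_risk"] == 2


class TestWeightedLogrank:
    def test_identical_groups_null(self):
        time = np.tile(np.arange(1, 21, dtype=float), 2)
        event = np.tile(np.array([1, 0] * 10), 2)
        group = np.repeat([0, 1], 20)
        chi2, p = surv.weighted_logrank(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_at_unit_weights(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            df = _random_survival(rng, 120, hr=1.5)
            chi2, p = surv.weighted_logrank(df["time"], df["event"], df["group"])
            ref = logrank_test(
                df.loc[df["group"] == 0, "time"], df.loc[df["group"] == 1, "time"],
                df.loc[df["group"] == 0, "event"], df.loc[df["group"] == 1, "event"],
            )
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_power_against_doubled_hazard(self):
        rng = np.random.default_rng(14)
        rejections = sum(
            surv.weighted_logrank(*(lambda d: (d["time"], d["event"], d["group"]))(
                _random_survival(rng, 2000, hr=2.0)
            ))[1] < 0.05
            for _ in range(25)
        )
        assert rejections >= 24  # power well above 0.9 at this n

    def test_refuses_single_group(self):
        with pytest.raises(ValueError):
            surv.weighted_logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array([1, 1]))


class TestWeightedCox:
    def test_matches_phreg_at_unit_weights(self):
        """Unit-weight fit equals an independent classical implementation."""
        rng = np.random.default_rng(15)
        df = _random_survival(rng, 180, hr=1.7)
        fit = surv.weighted_cox(df)
        ref = PHReg(
            df["time"], (1 - df["group"]).to_numpy()[:, None], status=df["event"], ties="efron"
        ).fit()
        assert np.log(fit.hr) == pytest.approx(ref.params[0], abs=1e-6)

    def test_group_swap_inverts_hr(self):
        rng = np.random.default_rng(16)
        df = _random_survival(rng, 150, hr=1.5)
        fit = surv.weighted_cox(df)
        swapped = df.assign(group=1 - df["group"])
        fit_sw = surv.weighted_cox(swapped)
        assert fit_sw.hr == pytest.approx(1 / fit.hr, rel=1e-6)

    def test_fit_contract(self):
        rng = np.random.default_rng(17)
        df = _random_survival(rng, 200, hr=1.4)
        df["weight"] = rng.uniform(0.5, 3.0, size=200)
        fit = surv.weighted_cox(df, "demo")
        assert fit.ci_lower <= fit.hr <= fit.ci_upper
        assert fit.n_events == int(df["event"].sum())
        for curve in fit.curves.values():
            assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_refuses_eventless_group(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 0],
             "group": [1, 1, 0, 0], "weight": 1.0}
        )
        with pytest.raises(ValueError, match="event"):
            surv.weighted_cox(df)


class TestPHCheck:
    def test_null_interaction_p_uniform(self):
        """Under proportional hazards the interaction p-value is uniform."""
        rng = np.random.default_rng(18)
        pvals = []
        for _ in range(200):
            df = _random_survival(rng, 150, hr=1.0)
            pvals.append(surv.ph_check(df)["interaction_p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_crossing_hazards(self):
        """Strongly time-varying group effect is flagged with high power."""
        rng = np.random.default_rng(19)
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 2000
            group = rng.integers(0, 2, size=n)
            shape = np.where(group == 1, 0.6, 1.6)  # early vs late hazard
            t = rng.weibull(shape) * 1.2
            c = rng.uniform(0.1, 2.5, size=n)
            df = pd.DataFrame(
                {"time": np.minimum(t, c), "event": (t <= c).astype(int),
                 "group": group, "weight": 1.0}
            )
            hits += surv.ph_check(df)["interaction_p"] < 0.05
        assert hits / reps > 0.8

    def test_loglog_offset_equals_log_hr_under_ph(self):
        """Exponential groups with HR=2: log(-log S) curves differ by log 2."""
        t = np.linspace(0.1, 3, 200)
        s1, s2 = np.exp(-t), np.exp(-2 * t)
        offset = np.log(-np.log(s2)) - np.log(-np.log(s1))
        np.testing.assert_allclose(offset, np.log(2), atol=1e-10)


class TestQuantiles:
    def test_direct_readoff(self):
        curve = pd.DataFrame({"time": [5.3, 8.0], "survival": [0.74, 0.5]})
        assert surv.km_quantile(curve, 0.25) == 5.3

    def test_not_reached(self):
        curve = pd.DataFrame({"time": [5.0], "survival": [0.9]})
        assert surv.km_quantile(curve, 0.25) is None

    def test_rejects_bad_q(self):
        curve = pd.DataFrame({"time": [1.0], "survival": [0.5]})
        with pytest.raises(ValueError):
            surv.km_quantile(curve, 1.5)

    def test_reverse_km_on_fully_followed_cohort(self):
        """Everyone administratively censored at 10: median follow-up = 10."""
        time = np.full(30, 10.0)
        death = np.zeros(30, dtype=int)
        assert surv.reverse_km_median(time, death) == 10.0
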