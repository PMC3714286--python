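import numpy as np
import pandas as pd
import pytest

from ymrsig import (
    DegenerateAnalysisError,
    EvaluationConfig,
    ModelType,
    SurvivalError,
    cox_multivariate,
    cox_univariate,
    evaluate_signature,
    km_logrank,
    read_clinical,
    restrict_followup,
)


def surv_table(times, events, **covariates):
    df = pd.DataFrame(
        {"time": times, "event": [bool(e) for e in events], **covariates},
        index=[f"s{i}" for i in range(len(times))],
    )
    df.index.name = "sample_id"
    return df


# ---- independent product-limit / log-rank oracles (pure python) ----

def km_oracle(times, events):
    data = sorted(zip(times, events))
    s, out = 1.0, []
    for t in sorted({t for t, e in data if e}):
        n = sum(1 for tt, _ in data if tt >= t)
        d = sum(1 for tt, ee in data if tt == t and ee)
        s *= 1 - d / n
        out.append((t, s))
    return out


def logrank_oracle(times, events, groups):
    data = list(zip(times, events, groups))
    O1 = E1 = V = 0.0
    for t in sorted({t for t, e, _ in data if e}):
        at_risk = [x for x in data if x[0] >= t]
        n = len(at_risk)
        n1 = sum(1 for x in at_risk if x[2] == "A")
        d = sum(1 for tt, ee, _ in data if tt == t and ee)
        d1 = sum(1 for tt, ee, gg in data if tt == t and ee and gg == "A")
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestKaplanMeierLogrank:
    def test_curve_steps_at_event_times(self):
        surv = surv_table([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["A", "A", "B", "B"], index=surv.index)
        est = km_logrank(surv, groups)
        assert list(est.curves["A"]["time"]) == [0.0, 1.0, 2.0]
        np.testing.assert_allclose(est.curves["A"]["survival"], [1.0, 0.5, 0.0])
        assert list(est.curves["B"]["time"]) == [0.0, 3.0, 4.0]

    def test_textbook_logrank_example(self):
        # two 6-patient arms; statistic hand-computed via observed-vs-expected
        times = [6, 7, 10, 15, 19, 25, 1, 3, 5, 8, 12, 14]
        events = [1, 0, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1]
        labels = ["A"] * 6 + ["B"] * 6
        surv = surv_table(times, events)
        est = km_logrank(surv, pd.Series(labels, index=surv.index))
        assert est.logrank_stat == pytest.approx(4.534916427852959, rel=1e-9)
        assert est.logrank_p == pytest.approx(0.033210078391645, rel=1e-9)
        assert est.logrank_stat == pytest.approx(
            logrank_oracle(times, events, labels), rel=1e-9
        )

    def test_km_matches_product_limit_oracle(self, rng):
        times = rng.integers(1, 30, size=9).astype(float)
        events = rng.integers(0, 2, size=9)
        surv = surv_table(times, events)
        groups = pd.Series(["A"] * 9, index=surv.index)
        groups.iloc[0] = "B"  # second arm so the call is well-formed
        est = km_logrank(surv, groups)
        curve = est.curves["A"].set_index("time")["survival"]
        for t, s in km_oracle(times[1:], events[1:]):
            assert curve.loc[t] == pytest.approx(s, rel=1e-12)

    def test_identical_groups_p_near_one(self):
        times = [3, 6, 9, 12, 3, 6, 9, 12]
        events = [1, 1, 0, 1] * 2
        surv = surv_table(times, events)
        est = km_logrank(surv, pd.Series(["A"] * 4 + ["B"] * 4, index=surv.index))
        assert est.logrank_p > 0.9

    def test_order_and_label_invariance(self, rng):
        times = rng.exponential(20, size=20)
        events = rng.integers(0, 2, size=20)
        labels = ["A"] * 10 + ["B"] * 10
        surv = surv_table(times, events)
        est1 = km_logrank(surv, pd.Series(labels, index=surv.index))
        perm = rng.permutation(surv.index)
        est2 = km_logrank(
            surv.loc[perm],
            pd.Series(labels, index=surv.index).loc[perm].map({"A": "X", "B": "Y"}),
        )
        assert est1.logrank_p == pytest.approx(est2.logrank_p, rel=1e-12)

    def test_empty_group_is_error(self):
        surv = surv_table([1, 2], [1, 1])
        groups = pd.Series(["A", "A"], index=surv.index)
        with pytest.raises((SurvivalError, DegenerateAnalysisError)):
            km_logrank(surv, groups)

    def test_all_censored_flagged_not_fatal(self):
        surv = surv_table([5, 6, 7, 8], [0, 0, 0, 0])
        est = km_logrank(surv, pd.Series(["A", "A", "B", "B"], index=surv.index))
        assert np.isnan(est.logrank_p)


class TestCoxUnivariate:
    def test_identical_outcome_distributions_hr_near_one(self):
        times = list(range(1, 21)) * 2
        events = [1] * 40
        surv = surv_table(times, events)
        label = pd.Series(["HIGH"] * 20 + ["LOW"] * 20, index=surv.index)
        res = cox_univariate(surv, label, ModelType.DICHOTOMOUS)
        assert res.hr == pytest.approx(1.0, abs=0.05)

    def test_exponential_two_group_recovery(self):
        # closed-form generator: group B hazard exactly 2x group A
        rng = np.random.default_rng(2024)
        n = 1000
        t_a = rng.exponential(1 / 0.01, size=n)
        t_b = rng.exponential(1 / 0.02, size=n)
        surv = surv_table(np.concatenate([t_a, t_b]), [1] * (2 * n))
        x = pd.Series([0.0] * n + [1.0] * n, index=surv.index)
        res = cox_univariate(surv, x, ModelType.DICHOTOMOUS)
        assert 1.8 <= res.hr <= 2.2
        assert res.ci_low <= res.hr <= res.ci_high

    def test_label_and_numeric_encoding_agree(self, rng):
        times = rng.exponential(30, size=60)
        events = rng.integers(0, 2, size=60)
        surv = surv_table(times, events)
        label = pd.Series(["HIGH" if i < 30 else "LOW" for i in range(60)], index=surv.index)
        numeric = (label == "HIGH").astype(float)
        r1 = cox_univariate(surv, label, ModelType.DICHOTOMOUS)
        r2 = cox_univariate(surv, numeric, ModelType.DICHOTOMOUS)
        assert r1.hr == pytest.approx(r2.hr, rel=1e-10)
        assert r1.p == pytest.approx(r2.p, rel=1e-10)

    def test_zero_events_is_diagnostic_error(self):
        surv = surv_table([1, 2, 3, 4], [0, 0, 0, 0])
        x = pd.Series([0.0, 1.0, 0.0, 1.0], index=surv.index)
        with pytest.raises(DegenerateAnalysisError):
            cox_univariate(surv, x)

    def test_constant_covariate_is_error(self):
        surv = surv_table([1, 2, 3, 4], [1, 1, 1, 1])
        x = pd.Series([1.0] * 4, index=surv.index)
        with pytest.raises(DegenerateAnalysisError):
            cox_univariate(surv, x)


class TestCoxMultivariate:
    def _simulated(self, seed=7, n=400):
        # hazard depends only on the binary 'stage-like' covariate (log HR = 1)
        rng = np.random.default_rng(seed)
        z = rng.integers(0, 2, size=n).astype(float)
        score = rng.normal(0, 1, size=n)  # independent of outcome
        hazard = 0.01 * np.exp(1.0 * z)
        times = rng.exponential(1 / hazard)
        cens = rng.uniform(0, 150, size=n)
        surv = surv_table(np.minimum(times, cens), times <= cens, z=z)
        return surv, pd.Series(score, index=surv.index)

    def test_recovers_known_coefficients(self):
        surv, score = self._simulated()
        results = {r.covariate_name: r for r in cox_multivariate(surv, score, ["z"])}
        assert results["score"].hr == pytest.approx(1.0, abs=0.15)
        assert results["z"].ci_low <= np.exp(1.0) <= results["z"].ci_high

    def test_duplicate_covariate_collinearity_error(self):
        surv, score = self._simulated(n=100)
        surv["z2"] = surv["z"]
        with pytest.raises(SurvivalError, match="collinear"):
            cox_multivariate(surv, score, ["z", "z2"])

    def test_single_covariate_matches_univariate(self):
        surv, score = self._simulated(n=200)
        multi = cox_multivariate(surv, score, [])[0]
        uni = cox_univariate(surv, score, ModelType.CONTINUOUS, name="score")
        assert multi.hr == pytest.approx(uni.hr, rel=1e-8)
        assert multi.p == pytest.approx(uni.p, rel=1e-6)

    def test_stage_ordinal_encoding(self):
        rng = np.random.default_rng(3)
        n = 150
        stage = rng.choice(["I", "II", "III"], size=n)
        surv = surv_table(
            rng.exponential(50, size=n), rng.integers(0, 2, size=n), stage=stage
        )
        score = pd.Series(rng.normal(0, 1, size=n), index=surv.index)
        results = cox_multivariate(surv, score, ["stage"])
        assert {r.covariate_name for r in results} == {"score", "stage"}


class TestRestrictFollowup:
    def test_event_beyond_horizon_censored(self):
        surv = surv_table([80.0], [1])
        out = restrict_followup(surv, 72)
        assert out["time"].iloc[0] == 72
        assert not out["event"].iloc[0]

    def test_event_within_horizon_unchanged(self):
        surv = surv_table([50.0], [1])
        out = restrict_followup(surv, 72)
        pd.testing.assert_frame_equal(out, surv)

    def test_infinite_horizon_identity(self):
        surv = surv_table([80.0, 10.0], [1, 0])
        pd.testing.assert_frame_equal(restrict_followup(surv, np.inf), surv)

    def test_idempotent(self):
        surv = surv_table([80.0, 60.0, 90.0], [1, 1, 0])
        once = restrict_followup(surv, 72)
        twice = restrict_followup(once, 72)
        pd.testing.assert_frame_equal(once, twice)


class TestReadClinical:
    def test_parses_encodings(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text(
            "sample_id\ttime\tevent\tstage\tchemo\n"
            "s1\t12.5\t1\tI\ttrue\n"
            "s2\t30\tfalse\tii\t0\n"
        )
        df = read_clinical(path)
        assert df.loc["s1", "event"] and not df.loc["s2", "event"]
        assert df.loc["s2", "stage"] == "II"
        assert not df.loc["s2", "chemo"]

    def test_negative_time_rejected(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("sample_id\ttime\tevent\ns1\t-3\t1\n")
        with pytest.raises(SurvivalError):
            read_clinical(path)


class TestEvaluateSignature:
    def test_subgroup_sizes_match_filters(self, small_cohort, default_sig):
        expr, clinical, _ = small_cohort
        report = evaluate_signature(
            expr, clinical, default_sig,
            subgroup_specs={"stage_I": {"stages": ("I",)}},
        )
        assert report.subgroups["stage_I"].n == int((clinical["stage"] == "I").sum())

    def test_small_arm_subgroup_skipped_with_warning(self, small_cohort, default_sig):
        expr, clinical, _ = small_cohort
        config = EvaluationConfig(min_arm_size=10_000)
        with pytest.warns(UserWarning, match="skipped"):
            report = evaluate_signature(expr, clinical, default_sig, config=config)
        assert report.overall.skipped is not None

    def test_planted_effect_detected(self, default_sig):
        # n=400 tumors: the scale at which the dichotomous test is well powered
        from ymrsig import SimulationConfig, simulate_cohort

        expr, clinical, truth = simulate_cohort(
            SimulationConfig(n_normal=0, n_tumor=400, n_background_features=100, seed=11)
        )
        report = evaluate_signature(expr, clinical, default_sig)
        assert report.overall.km.logrank_p < 0.05
        assert report.overall.cox_dichotomous.hr > 1.0
        # analysis groups coincide with the generator's true groups
        labels = report.scores.loc[clinical.index, "risk_label"]
        truth_labels = truth.table.loc[clinical.index, "risk_group"]
        assert (labels == truth_labels).all()
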