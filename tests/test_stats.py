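import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spineqct.errors import ReportError, ValidationError
from spineqct.stats import (METRICS, build_report, linear_regression,
                            monthly_rate, one_sample_ttest,
                            one_sample_ttest_from_summary, paired_ttest,
                            percent_change, sample_with_moments)


class TestElementaryOps:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(200.0, 190.0, -5.0), (123.4, 123.4, 0.0), (182.3, 173.97, -4.5694)],
    )
    def test_percent_change(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected, abs=1e-3)

    def test_percent_change_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(0.0, 5.0)

    @pytest.mark.parametrize(
        "pct,months,expected", [(-5.0, 5.0, -1.0), (-6.48, 6.0, -1.08), (0.0, 3.0, 0.0)]
    )
    def test_monthly_rate(self, pct, months, expected):
        assert monthly_rate(pct, months) == pytest.approx(expected)

    def test_monthly_rate_nonpositive_months_rejected(self):
        with pytest.raises(ValidationError):
            monthly_rate(-5.0, 0.0)


class TestOneSampleTTest:
    def test_closed_form_agreement(self):
        # textbook formula vs implementation to 1e-9
        rng = np.random.default_rng(8)
        x = rng.normal(0.4, 1.1, 17)
        r = one_sample_ttest(x)
        t_manual = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        p_manual = 2 * sps.t.sf(abs(t_manual), len(x) - 1)
        assert r.t_statistic == pytest.approx(t_manual, abs=1e-9)
        assert r.p_two_sided == pytest.approx(p_manual, abs=1e-9)
        assert r.df == 16

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(9)
        x = rng.normal(-1.0, 1.2, 15)
        r = one_sample_ttest(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert r.t_statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_sample_with_moments_reproduces_summary_test(self):
        x = sample_with_moments(-1.08, 1.13, 17)
        assert x.mean() == pytest.approx(-1.08, abs=1e-12)
        assert x.std(ddof=1) == pytest.approx(1.13, abs=1e-12)
        assert one_sample_ttest(x).p_two_sided == pytest.approx(
            one_sample_ttest_from_summary(-1.08, 1.13, 17).p_two_sided, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            one_sample_ttest([1.0, 1.0, 1.0])


class TestPairedTTest:
    def test_identical_pairs(self):
        r = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0 and r.p_two_sided == 1.0

    def test_constant_shift_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_closed_form_and_scipy(self):
        rng = np.random.default_rng(10)
        pre = rng.normal(180, 25, 17)
        post = pre * (1 - rng.normal(0.045, 0.05, 17))
        r = paired_ttest(pre, post)
        d = post - pre
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert r.t_statistic == pytest.approx(t_manual, abs=1e-9)
        ref = sps.ttest_rel(post, pre)
        assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_incomplete_pairs_dropped_pairwise(self):
        pre = [1.0, 2.0, 3.0, 4.0]
        post = [1.2, np.nan, 3.4, 4.1]
        assert paired_ttest(pre, post).n == 3


class TestLinearRegression:
    def test_perfectly_collinear(self):
        x = np.arange(10.0)
        r = linear_regression(x, 2.5 * x - 1.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.5, abs=1e-12)

    def test_constant_response_gives_zero_r2(self):
        r = linear_regression(np.arange(10.0), np.full(10, 3.3))
        assert r.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValidationError):
            linear_regression(np.full(10, 2.0), np.arange(10.0))

    def test_recovers_designed_r2_within_2se(self):
        # simulation oracle: y = bx + e designed for population R^2 = 0.38
        rng = np.random.default_rng(11)
        r2s = []
        for _ in range(200):
            x = rng.normal(0, 1, 17)
            y = np.sqrt(0.38) * x + np.sqrt(0.62) * rng.normal(0, 1, 17)
            r2s.append(linear_regression(x, y).r_squared)
        se = np.std(r2s, ddof=1) / np.sqrt(len(r2s))
        # sample r^2 at small n is upward-biased by ~(1-R^2)^2/n
        expected = 0.38 + (1 - 0.38) ** 2 / 17
        assert np.mean(r2s) == pytest.approx(expected, abs=2 * se + 0.02)


def _synthetic_table(n=6, n_fu=5, zero_rates=False, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    months = rng.choice([4, 5, 6, 7], n)
    for i in range(n):
        base = {m: v for m, v in zip(
            METRICS, [182.0, 179.0, 177.0, 196.0, 780.0, 50.0])}
        base = {m: v * (1 + rng.normal(0, 0.05)) for m, v in base.items()}
        scale_post = 1.0 if zero_rates else 1 + rng.normal(-0.05, 0.02)
        scale_fu = 1.0 if zero_rates else 1 + rng.normal(-0.02, 0.02)
        for sess, scale in (("preflight", 1.0), ("postflight", scale_post),
                            ("followup", scale_fu)):
            if sess == "followup" and i >= n_fu:
                continue
            rows.append({
                "subject_id": f"S{i:02d}", "session": sess,
                "mission_months": float(months[i]), "readapt_months": 12.0,
                **{m: base[m] * scale for m in METRICS},
            })
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_report_structure_and_n(self):
        report = build_report(_synthetic_table())
        rates = report["monthly_rates"]
        flight = rates[rates.period == "flight"]
        readapt = rates[rates.period == "readapt"]
        assert set(flight.metric) == set(METRICS)
        assert (flight.n == 6).all()
        assert (readapt.n == 5).all()  # followup-less subject never contributes

    def test_zero_rate_cohort_has_no_signals(self):
        # all sessions identical: percent changes 0, no significance flags;
        # the degenerate zero-variance tests surface as NaN p-values
        report = build_report(_synthetic_table(zero_rates=True))
        pc = report["percent_change"]
        assert np.allclose(pc.mean_percent, 0.0)
        assert not pc.significant.any()
        rates = report["monthly_rates"]
        assert np.allclose(rates.mean_rate, 0.0)
        assert not rates.significant.any()
        assert rates.p_vs_zero.isna().all()

    def test_missing_preflight_rejected(self):
        table = _synthetic_table()
        table = table[~((table.subject_id == "S00") & (table.session == "preflight"))]
        with pytest.raises(ReportError, match="S00"):
            build_report(table)

    def test_readapt_denominator_switch(self):
        table = _synthetic_table(seed=3)
        by_readapt = build_report(table, readapt_denominator="readapt_months")
        by_mission = build_report(table, readapt_denominator="mission_months")
        r1 = by_readapt["monthly_rates"]
        r2 = by_mission["monthly_rates"]
        a = r1[(r1.period == "readapt")].set_index("metric").mean_rate
        b = r2[(r2.period == "readapt")].set_index("metric").mean_rate
        # dividing by ~6-month missions instead of 12-month readaptation
        # roughly doubles the magnitude
        assert (b.abs() > a.abs()).all()

    def test_regressions_per_session(self):
        report = build_report(_synthetic_table(seed=5))
        regs = report["regressions"]
        assert set(regs.session) == {"preflight", "postflight", "followup"}
        assert set(regs.predictor) == {"total_muscle_density", "total_muscle_csa"}
        assert ((regs.r_squared >= 0) & (regs.r_squared <= 1)).all()

    def test_report_write_round_trip(self, tmp_path):
        from spineqct.stats import write_report

        report = build_report(_synthetic_table(seed=5))
        write_report(report, tmp_path)
        assert (tmp_path / "monthly_rates.csv").exists()
        assert (tmp_path / "report.json").exists()
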