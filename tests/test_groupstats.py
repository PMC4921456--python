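"""Repeated-measures ANOVA and the AR(1) mixed model."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from igtnet.groupstats import (
    behavioral_anova,
    fit_lmm_ar1,
    fit_performance_model,
    rm_anova_2x4,
    rm_anova_oneway,
)


def oracle_two_way_within(data):
    """Textbook sums-of-squares decomposition, written with explicit loops.

    data has shape (subjects, a_levels, b_levels); each within-subject effect
    is tested against its subject-by-effect interaction.
    """
    n, a, b = data.shape
    grand = data.mean()
    out = {}
    ss = {"A": 0.0, "B": 0.0, "AB": 0.0, "SA": 0.0, "SB": 0.0, "SAB": 0.0}
    for i in range(a):
        ss["A"] += n * b * (data[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (data[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                data[:, i, j].mean() - data[:, i, :].mean()
                - data[:, :, j].mean() + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["SA"] += b * (
                data[s, i, :].mean() - data[s].mean()
                - data[:, i, :].mean() + grand
            ) ** 2
        for j in range(b):
            ss["SB"] += a * (
                data[s, :, j].mean() - data[s].mean()
                - data[:, :, j].mean() + grand
            ) ** 2
        for i in range(a):
            for j in range(b):
                ss["SAB"] += (
                    data[s, i, j]
                    - data[s, i, :].mean() - data[s, :, j].mean()
                    - data[:, i, j].mean() + data[s].mean()
                    + data[:, i, :].mean() + data[:, :, j].mean() - grand
                ) ** 2
    for eff, err, dfe, dferr in (
        ("A", "SA", a - 1, (a - 1) * (n - 1)),
        ("B", "SB", b - 1, (b - 1) * (n - 1)),
        ("AB", "SAB", (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    ):
        F = (ss[eff] / dfe) / (ss[err] / dferr)
        out[eff] = {
            "F": F,
            "p": stats.f.sf(F, dfe, dferr),
            "eta": ss[eff] / (ss[eff] + ss[err]),
        }
    return out


def long_table(data):
    n, a, b = data.shape
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append(
                    {"subject": s + 1, "condition": f"c{i}", "session": j + 1,
                     "value": data[s, i, j]}
                )
    return pd.DataFrame(rows)


class TestTwoWayRmAnova:
    def test_matches_loop_oracle_on_crafted_3_subject_data(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(3, 2, 4)) + np.array([0.0, 1.0])[None, :, None]
        res = rm_anova_2x4(long_table(data))
        oracle = oracle_two_way_within(data)
        for effect, key in (("condition", "A"), ("session", "B"),
                            ("condition:session", "AB")):
            row = res.effect(effect)
            assert row["F"] == pytest.approx(oracle[key]["F"], abs=1e-10)
            assert row["p"] == pytest.approx(oracle[key]["p"], abs=1e-10)
            assert row["partial_eta_sq"] == pytest.approx(
                oracle[key]["eta"], abs=1e-10
            )

    def test_matches_pingouin(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(9, 2, 4))
        tbl = long_table(data)
        res = rm_anova_2x4(tbl)
        pg_res = pg.rm_anova(
            data=tbl, dv="value", within=["condition", "session"],
            subject="subject", detailed=True,
        ).set_index("Source")
        assert res.effect("condition")["F"] == pytest.approx(
            pg_res.loc["condition", "F"], rel=1e-9
        )
        assert res.effect("session")["F"] == pytest.approx(
            pg_res.loc["session", "F"], rel=1e-9
        )
        assert res.effect("condition:session")["F"] == pytest.approx(
            pg_res.loc["condition * session", "F"], rel=1e-9
        )

    def test_constant_data_gives_zero_f(self):
        data = np.full((4, 2, 4), 3.7)
        res = rm_anova_2x4(long_table(data))
        assert (res.effects["F"] == 0.0).all()
        assert (res.effects["p"] == 1.0).all()

    def test_invariance_to_relabeling_and_shift(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(5, 2, 4))
        tbl = long_table(data)
        base = rm_anova_2x4(tbl)
        shifted = tbl.assign(value=tbl["value"] + 100.0)
        relabeled = shifted.assign(subject=shifted["subject"].map(
            {1: 9, 2: 3, 3: 7, 4: 1, 5: 5}
        ))
        res = rm_anova_2x4(relabeled)
        np.testing.assert_allclose(res.effects["F"], base.effects["F"], atol=1e-9)

    def test_planted_task_effect_detected_session_null(self):
        rng = np.random.default_rng(7)
        data = rng.normal(scale=0.5, size=(9, 2, 4))
        data[:, 1, :] += 2.0  # strong condition effect, no session effect
        res = rm_anova_2x4(long_table(data))
        assert res.effect("condition")["p"] < 0.001
        assert res.effect("session")["p"] > 0.05

    def test_missing_cell_rejected_with_location(self):
        tbl = long_table(np.zeros((3, 2, 4))).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x4(tbl)

    def test_gg_correction_reported(self):
        rng = np.random.default_rng(9)
        res = rm_anova_2x4(long_table(rng.normal(size=(6, 2, 4))),
                           gg_correction=True)
        assert "gg_epsilon" in res.effects.columns
        eps = res.effect("session")["gg_epsilon"]
        assert 1 / 3 <= eps <= 1.0
        assert res.effect("session")["p_gg"] >= res.effect("session")["p"] - 1e-12


class TestOneWayRmAnova:
    def test_identical_scores_give_zero_f(self):
        tbl = pd.DataFrame(
            {"subject": np.repeat(np.arange(5), 4),
             "session": np.tile(np.arange(4), 5),
             "igt_score": 12.0}
        )
        res = behavioral_anova(tbl)
        assert res.effects["F"].iloc[0] == 0.0

    def test_matches_pingouin(self):
        rng = np.random.default_rng(13)
        tbl = pd.DataFrame(
            {"subject": np.repeat(np.arange(9), 4),
             "session": np.tile(np.arange(4), 9),
             "igt_score": rng.normal(10, 5, 36)}
        )
        res = behavioral_anova(tbl)
        pg_res = pg.rm_anova(data=tbl, dv="igt_score", within="session",
                             subject="subject")
        assert res.effects["F"].iloc[0] == pytest.approx(
            pg_res["F"].iloc[0], rel=1e-9
        )
        assert res.effects["p"].iloc[0] == pytest.approx(
            pg_res["p_unc"].iloc[0], rel=1e-9
        )

    def test_null_calibration(self):
        # rejection rate at alpha = .05 under the null, 9 subjects x 4 blocks
        rng = np.random.default_rng(17)
        n_sim, rejections = 400, 0
        for _ in range(n_sim):
            tbl = pd.DataFrame(
                {"subject": np.repeat(np.arange(9), 4),
                 "session": np.tile(np.arange(4), 9),
                 "igt_score": rng.normal(size=36)}
            )
            if behavioral_anova(tbl).effects["p"].iloc[0] < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert 0.02 < rate < 0.08  # binomial 95% band around 0.05 is ~ +/-0.02


def simulate_lmm(rng, n_sub=9, n_ses=4, beta_k=10.0, rho=0.4,
                 sigma_b=3.0, sigma_e=2.0):
    rows = []
    for s in range(n_sub):
        b = rng.normal(0, sigma_b)
        e = np.zeros(n_ses)
        e[0] = rng.normal(0, sigma_e)
        for t in range(1, n_ses):
            e[t] = rho * e[t - 1] + rng.normal(0, sigma_e * np.sqrt(1 - rho**2))
        for t in range(n_ses):
            K = rng.normal(10, 2)
            rows.append(
                {"subject": s + 1, "session": t + 1, "K": K,
                 "E_loc": rng.normal(0.5, 0.05),
                 "E_glob": rng.normal(0.2, 0.03),
                 "igt_score": 2.0 + beta_k * K + b + e[t]}
            )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_planted_fixed_effect_recovered(self):
        df = simulate_lmm(np.random.default_rng(21))
        fit = fit_performance_model(df, network="whole")
        k = fit.coef("K")
        assert abs(k["B"] - 10.0) < 3 * k["SE"]
        assert k["p"] < 1e-6

    def test_zero_ar1_recovered_on_average(self):
        rhos = []
        for seed in range(8):
            df = simulate_lmm(np.random.default_rng(100 + seed), rho=0.0,
                              sigma_b=0.5, sigma_e=2.0)
            fit = fit_performance_model(df, network="whole")
            rhos.append(fit.ar1_rho)
        assert abs(np.mean(rhos)) < 0.25

    def test_null_covariates_not_systematically_significant(self):
        pvals = []
        for seed in range(10):
            df = simulate_lmm(np.random.default_rng(200 + seed), beta_k=0.0)
            fit = fit_performance_model(df, network="whole")
            pvals.append(fit.coef("E_loc")["p"])
        assert np.mean(pvals) > 0.2  # roughly uniform, not piled near 0

    def test_matches_r_nlme_reference(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the nlme cross-check")
        df = simulate_lmm(np.random.default_rng(42), beta_k=1.5)
        csv = tmp_path / "lmm.csv"
        df.rename(columns={"igt_score": "y"}).to_csv(csv, index=False)
        rcode = (
            "suppressMessages(library(nlme));"
            f"d <- read.csv('{csv}');"
            "m <- lme(y ~ K + E_loc + E_glob, random = ~1|subject,"
            " correlation = corAR1(form = ~session|subject), data = d,"
            " method = 'REML');"
            "s <- summary(m)$tTable;"
            "cat(s[,'Value'], s[,'Std.Error'],"
            " coef(m$modelStruct$corStruct, unconstrained=FALSE), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        r_beta, r_se, r_rho = vals[:4], vals[4:8], vals[8]
        fit = fit_performance_model(df, network="whole")
        np.testing.assert_allclose(fit.fixed_effects["B"], r_beta, rtol=1e-4)
        np.testing.assert_allclose(fit.fixed_effects["SE"], r_se, rtol=1e-3)
        assert fit.ar1_rho == pytest.approx(r_rho, abs=1e-3)

    def test_nonconvergence_raises_not_silent(self):
        df = simulate_lmm(np.random.default_rng(3), n_sub=2, n_ses=2)
        # collinear design triggers an explicit error
        df["E_glob"] = 2.0 * df["K"]
        with pytest.raises((ValueError, RuntimeError)):
            fit_performance_model(df, network="whole")

    def test_single_observation_subject_rejected(self):
        df = simulate_lmm(np.random.default_rng(4))
        df = df[~((df.subject == 1) & (df.session > 1))]
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_performance_model(df, network="whole")
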