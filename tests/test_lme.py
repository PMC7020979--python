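"""Mixed-effects model: degenerate limits, cross-checks, recovery, inference."""

import numpy as np
import pandas as pd
import pytest

from dirprop.lme import (
    LMESpec,
    compare_algorithms,
    fit_lme,
    simulate_longitudinal,
    subfactor_analysis,
    summarize_estimates,
)


def two_algo_data(rng, n_subjects=10, n_fractions=10, beta_algo=0.05,
                  sigma_subject=0.1, sigma_resid=0.08, rho=0.5):
    df = simulate_longitudinal(
        n_subjects, range(1, n_fractions + 1), 0.8, beta_algo, -0.002,
        sigma_subject, sigma_resid, rho, rng,
    )
    df["is_B"] = (df["algorithm"] == "B").astype(float)
    return df


SPEC = LMESpec("value", ("is_B", "fraction"), series="algorithm")


class TestFitting:
    def test_fixed_degenerate_limit_matches_ols_exactly(self, rng):
        df = two_algo_data(rng, sigma_subject=0.0, rho=0.0)
        fit = fit_lme(df, LMESpec("value", ("is_B", "fraction"), series="algorithm",
                                  fix_rho=0.0, fix_gamma=0.0))
        x = np.stack(
            [np.ones(len(df)), df["is_B"],
             df["fraction"] - df["fraction"].mean()], axis=1
        )
        ols = np.linalg.lstsq(x, df["value"].to_numpy(), rcond=None)[0]
        assert np.abs(fit.beta - ols).max() < 1e-6

    def test_matches_statsmodels_random_intercept_ml(self, rng):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        df = two_algo_data(rng, n_subjects=12, n_fractions=8, rho=0.0)
        df["fc"] = df["fraction"] - df["fraction"].mean()
        ref = statsmodels.mixedlm(
            "value ~ is_B + fc", df, groups=df["patient_id"]
        ).fit(reml=False)
        fit = fit_lme(df, LMESpec("value", ("is_B", "fraction"),
                                  series="algorithm", fix_rho=0.0))
        ref_beta = ref.params.to_numpy()[:3]
        assert np.abs((fit.beta - ref_beta) / ref_beta).max() < 1e-3
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_recovers_known_parameters(self):
        # moderate replication; the full calibration lives in the acceptance suite
        betas, rhos = [], []
        for r in range(20):
            rng = np.random.default_rng(300 + r)
            df = two_algo_data(rng, n_subjects=20, n_fractions=23,
                               beta_algo=0.06, rho=0.5)
            fit = fit_lme(df, SPEC)
            betas.append(fit.coefficient("is_B")["estimate"])
            rhos.append(fit.rho)
        assert np.mean(betas) == pytest.approx(0.06, abs=0.01)
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.08)

    def test_ar1_nesting_improves_likelihood(self, rng):
        df = two_algo_data(rng, rho=0.6)
        free = fit_lme(df, SPEC)
        fixed0 = fit_lme(df, LMESpec("value", ("is_B", "fraction"),
                                     series="algorithm", fix_rho=0.0))
        assert free.loglik >= fixed0.loglik - 1e-8

    def test_wald_pieces_are_consistent(self, rng):
        df = two_algo_data(rng)
        fit = fit_lme(df, SPEC)
        coef = fit.coefficient("is_B")
        assert coef["z"] == pytest.approx(coef["estimate"] / coef["se"])
        assert coef["ci_low"] == pytest.approx(coef["estimate"] - 1.959963984540054 * coef["se"])
        i = fit.names.index("is_B")
        from scipy import stats

        assert fit.p_values[i] == pytest.approx(2 * stats.norm.sf(abs(fit.z[i])))

    def test_requires_multiple_subjects(self, rng):
        df = two_algo_data(rng, n_subjects=1)
        with pytest.raises(ValueError):
            fit_lme(df, SPEC)


class TestComparisons:
    def test_identical_algorithm_records_are_not_significant(self, rng):
        df = two_algo_data(rng, beta_algo=0.0)
        # make B literally identical to A
        a = df[df["algorithm"] == "A"].copy()
        b = a.copy()
        b["algorithm"] = "B"
        dup = pd.concat([a, b], ignore_index=True)
        res = compare_algorithms(dup, "A", "B", "value")
        assert res.effect["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_large_effect_is_significant(self, rng):
        df = two_algo_data(rng, n_subjects=8, beta_algo=0.3,
                           sigma_subject=0.05, sigma_resid=0.03)
        res = compare_algorithms(df, "A", "B", "value")
        assert res.significant
        assert res.effect["estimate"] == pytest.approx(0.3, abs=0.05)

    def test_subfactor_grid_shape(self, rng):
        rows = []
        for pid in range(4):
            modality = "CTOR" if pid < 2 else "CBCT"
            for fr in range(1, 5):
                for algo in ("nib", "shadowed_nib"):
                    for organ in ("bladder", "rectum"):
                        rows.append({
                            "patient_id": f"P{pid}", "fraction": fr,
                            "modality": modality, "organ": organ,
                            "algorithm": algo,
                            "dsc": rng.uniform(0.7, 0.95),
                            "jaccard": rng.uniform(0.5, 0.9),
                            "hd_mm": rng.uniform(5, 20),
                            "mda_mm": rng.uniform(0.5, 4),
                        })
        records = pd.DataFrame(rows)
        grid = subfactor_analysis(records, algorithms=["nib", "shadowed_nib"])
        # 2 algorithms x 2 organs x 4 metrics
        assert len(grid) == 16
        assert {"p_modality", "p_fraction"} <= set(grid.columns)
        assert grid["p_modality"].between(0, 1).all()


class TestSummaries:
    def test_constant_response_has_zero_width_ci(self):
        rows = []
        for pid in ("P1", "P2", "P3"):
            for fr in (1, 2, 3):
                rows.append({"patient_id": pid, "fraction": fr, "organ": "bladder",
                             "algorithm": "nib", "dsc": 0.9, "jaccard": 0.8,
                             "hd_mm": 5.0, "mda_mm": 1.0})
        out = summarize_estimates(pd.DataFrame(rows))
        row = out[out["metric"] == "dsc"].iloc[0]
        assert row["estimate"] == pytest.approx(0.9)
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-9)

    def test_estimates_track_simulated_means(self, rng):
        df = two_algo_data(rng, n_subjects=12, beta_algo=0.1, sigma_resid=0.02,
                           sigma_subject=0.02)
        df["organ"] = "bladder"
        out = summarize_estimates(df, grouping=("organ", "algorithm"),
                                  metrics=("value",))
        est = out.set_index("algorithm")["estimate"]
        assert est["B"] - est["A"] == pytest.approx(0.1, abs=0.04)
        assert est["B"] > est["A"]

    def test_six_comparison_sets_structure(self, rng):
        rows = []
        for pid in ("P1", "P2"):
            for fr in (1, 2):
                for organ in ("bladder", "rectum"):
                    for algo in ("dir_profile", "nib", "shadowed_nib"):
                        rows.append({
                            "patient_id": pid, "fraction": fr, "organ": organ,
                            "algorithm": algo, "dsc": rng.uniform(0.7, 1.0),
                            "jaccard": rng.uniform(0.6, 0.9),
                            "hd_mm": rng.uniform(2, 20), "mda_mm": rng.uniform(0.3, 4),
                        })
        out = summarize_estimates(pd.DataFrame(rows), metrics=("dsc",))
        assert len(out) == 6  # 2 organs x 3 algorithms
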