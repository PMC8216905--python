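"""Statistical stage: oracles, printed-value checks, invariants."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from phenobee.phenostats import (
    EMMGrid,
    days_to_weeks,
    emmeans_ols,
    fit_brood_proportion_glm,
    fit_cross_species_cox,
    fit_flowering_cox,
    fit_flowering_proportion_glm,
    fit_height_lmm,
    fit_onset_cox,
    fit_weight_model,
    pairwise_contrasts,
    round_half_away,
    summarize_proportions,
)


class TestProportionSummaries:
    def test_printed_study_proportions(self):
        # 15 of 16 across 4 pots of 4 (one pot at 3/4): 0.94 +- 0.13
        assert summarize_proportions([(4, 4), (4, 4), (4, 4), (3, 4)]) == (0.94, 0.13)
        # 14 of 16: 0.88 +- 0.14
        assert summarize_proportions([(4, 4), (4, 4), (3, 4), (3, 4)]) == (0.88, 0.14)
        # 7 of 16: mean 0.44
        mean, _ = summarize_proportions([(2, 4), (2, 4), (2, 4), (1, 4)])
        assert mean == 0.44

    def test_all_full_pots(self):
        assert summarize_proportions([(4, 4)] * 4) == (1.00, 0.00)

    def test_mean_over_equal_pots_equals_pooled(self):
        counts = [(3, 4), (1, 4), (4, 4), (2, 4)]
        mean, _ = summarize_proportions(counts)
        pooled = sum(k for k, _ in counts) / sum(n for _, n in counts)
        assert mean == round_half_away(pooled, 2)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(0.4375, 2) == 0.44

    def test_single_pot_rejected(self):
        with pytest.raises(ValueError):
            summarize_proportions([(4, 4)])


def _toy_survival(n_per_group=3):
    # two groups, no ties: hand-checkable partial likelihood
    return pd.DataFrame(
        {
            "week": [1, 3, 5, 2, 4, 6],
            "event": [1, 1, 0, 1, 1, 1],
            "temp_regime": ["current"] * 3 + ["future"] * 3,
            "light_regime": "CEP",
            "arena_id": ["a1", "a2", "a3", "a4", "a5", "a6"],
        }
    )


def _hand_partial_loglik(beta: float, df: pd.DataFrame) -> float:
    """Breslow=Efron here (no ties): direct sum over event times."""
    x = (df["temp_regime"] == "future").to_numpy(dtype=float)
    t = df["week"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=bool)
    ll = 0.0
    for i in np.where(e)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCoxAgainstHandOracle:
    def test_beta_matches_hand_maximized_partial_likelihood(self):
        df = _toy_survival()
        res = fit_flowering_cox(df)
        beta_hat = float(
            res.coefficients.set_index("term").loc["temp_regime[future]", "estimate"]
        )
        opt = optimize.minimize_scalar(
            lambda b: -_hand_partial_loglik(b, df), bounds=(-5, 5), method="bounded"
        )
        assert beta_hat == pytest.approx(opt.x, abs=1e-3)

    def test_lrt_statistic_matches_hand_oracle(self):
        df = _toy_survival()
        res = fit_flowering_cox(df)
        opt = optimize.minimize_scalar(
            lambda b: -_hand_partial_loglik(b, df), bounds=(-5, 5), method="bounded"
        )
        chi2_oracle = 2.0 * (-opt.fun - _hand_partial_loglik(0.0, df))
        assert res.anova.iloc[0]["statistic"] == pytest.approx(chi2_oracle, abs=1e-4)

    def test_no_events_is_an_error(self):
        df = _toy_survival().assign(event=0)
        with pytest.raises(ValueError, match="events"):
            fit_flowering_cox(df)


class TestCoxAgainstRSurvival:
    def test_sequential_lrt_matches_r_anova(self, tmp_path, study_bundle):
        """R's anova(coxph(...)) is the independent oracle for the Efron-tie
        sequential analysis of deviance on a realistic tied dataset."""
        df = study_bundle.flowering[
            ["week", "event", "temp_regime", "light_regime", "arena_id"]
        ]
        csv = tmp_path / "flowering.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "anova.csv"
        script = f"""
        suppressMessages(library(survival))
        d <- read.csv("{csv}")
        d$temp_regime <- factor(d$temp_regime)
        d$light_regime <- factor(d$light_regime)
        m <- coxph(Surv(week, event) ~ temp_regime * light_regime, data = d,
                   ties = "efron")
        a <- as.data.frame(anova(m))
        write.csv(a, "{out}")
        """
        r = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert r.returncode == 0, r.stderr
        r_anova = pd.read_csv(out)
        r_chisq = r_anova["Chisq"].dropna().to_numpy()

        res = fit_flowering_cox(df)
        ours = res.anova["statistic"].to_numpy()
        assert np.allclose(ours, r_chisq, atol=1e-3)


class TestCoxInvariants:
    def test_lrt_nonnegative_and_recoding_invariant(self, study_bundle):
        df = study_bundle.flowering
        res = fit_flowering_cox(df)
        assert (res.anova["statistic"] >= 0).all()
        # relabel so the reference levels change; LR statistics are unchanged
        relabeled = df.assign(
            temp_regime=df["temp_regime"].map({"current": "z-ctrl", "future": "a-warm"}),
            light_regime=df["light_regime"].map({"CD": "z-dark", "CEP": "m-ce", "NEP": "a-ne"}),
        )
        res2 = fit_flowering_cox(relabeled)
        assert np.allclose(
            res.anova["statistic"].to_numpy(), res2.anova["statistic"].to_numpy(),
            atol=1e-6,
        )

    def test_cluster_robust_fit_keeps_plain_estimates(self):
        # the frailty fallback changes variances, never point estimates
        from lifelines import CoxPHFitter

        df = _toy_survival()
        res = fit_flowering_cox(df)
        plain = CoxPHFitter().fit(
            df.assign(x=(df["temp_regime"] == "future").astype(float))[
                ["week", "event", "x"]
            ],
            duration_col="week",
            event_col="event",
        )
        beta_hat = float(
            res.coefficients.set_index("term").loc["temp_regime[future]", "estimate"]
        )
        assert beta_hat == pytest.approx(float(plain.params_.iloc[0]), abs=1e-8)
        assert any("cluster-robust" in n for n in res.notes)


class TestOnsetCox:
    def test_all_censored_is_an_error(self, study_bundle):
        recs = pd.DataFrame(
            {
                "colony_id": [f"c{i}" for i in range(8)],
                "time": 154,
                "event": 0,
                "temp_regime": ["current", "future"] * 4,
                "light_regime": ["CD", "CEP", "NEP", "CD"] * 2,
                "origin_swarm": [True, False] * 4,
                "brood_at_start": False,
            }
        )
        with pytest.raises(ValueError, match="events"):
            fit_onset_cox(recs)

    def test_terms_present(self, study_bundle):
        from phenobee.detect import analyze_colony, build_survival_records
        from phenobee.scenario import EXPERIMENT_END, EXPERIMENT_START

        onsets, deaths = {}, {}
        for cid, samples in study_bundle.telemetry.groupby("colony_id"):
            r = analyze_colony(samples)
            onsets[cid], deaths[cid] = r["onset"], r["death"]
        recs = build_survival_records(
            onsets, deaths, EXPERIMENT_START, EXPERIMENT_END, study_bundle.colonies
        )
        res = fit_onset_cox(recs)
        assert list(res.anova["term"]) == [
            "temperature", "photoperiod", "temperature:photoperiod",
            "origin", "brood_at_start",
        ]
        assert res.anova["p"].between(0, 1).all()


class TestFloweringProportionGLM:
    def test_single_cell_intercept_only_recovers_observed(self):
        counts = pd.DataFrame(
            {
                "flowered": [3, 4, 2, 3],
                "total": [4, 4, 4, 4],
                "temp_regime": "current",
                "light_regime": "CEP",
            }
        )
        res = fit_flowering_proportion_glm(counts)
        assert res.anova.empty  # no varying factor -> intercept only
        intercept = float(res.coefficients["estimate"].iloc[0])
        assert 1 / (1 + np.exp(-intercept)) == pytest.approx(12 / 16)

    def test_detects_low_cell_from_study_counts(self):
        # the printed per-cell totals: FT-CD 7/16 vs ~15/16 elsewhere
        cells = {
            ("current", "CD"): 15, ("current", "CEP"): 16, ("current", "NEP"): 14,
            ("future", "CD"): 7, ("future", "CEP"): 15, ("future", "NEP"): 14,
        }
        rows = []
        for (t, l), total in cells.items():
            per_pot = [total // 4 + (1 if i < total % 4 else 0) for i in range(4)]
            rows += [
                {"flowered": k, "total": 4, "temp_regime": t, "light_regime": l}
                for k in per_pot
            ]
        res = fit_flowering_proportion_glm(pd.DataFrame(rows))
        coefs = res.coefficients.set_index("term")["estimate"]
        # additive model contribution: the FT-CD cell has the smallest
        # linear predictor among all six cells
        def eta(t, l):
            v = coefs["Intercept"]
            if t == "future":
                v += coefs.get("temp_regime[future]", 0.0)
            for lev in ("CEP", "NEP"):
                if l == lev:
                    v += coefs.get(f"light_regime[{lev}]", 0.0)
                    if t == "future":
                        v += coefs.get(
                            f"temperature:photoperiod[future:{lev}]", 0.0
                        )
            return float(v)

        etas = {(t, l): eta(t, l) for (t, l) in cells}
        assert min(etas, key=etas.get) == ("future", "CD")


class TestBroodProportionGLM:
    def test_dispersion_near_one_for_binomial_truth(self):
        rng = np.random.default_rng(42)
        n = 200
        recs = pd.DataFrame(
            {
                "colony_id": [f"c{i}" for i in range(n)],
                "n_days": 100,
                "n_brood_days": rng.binomial(100, 0.3, size=n),
                "temp_regime": rng.choice(["current", "future"], size=n),
                "light_regime": rng.choice(["CD", "CEP", "NEP"], size=n),
                "origin_swarm": rng.choice([True, False], size=n),
                "brood_at_start": rng.choice([True, False], size=n),
            }
        )
        res = fit_brood_proportion_glm(recs)
        note = next(n for n in res.notes if "dispersion" in n)
        phi = float(note.split("=")[1])
        assert phi == pytest.approx(1.0, abs=0.25)

    def test_zero_denominator_excluded_with_note(self):
        recs = pd.DataFrame(
            {
                "colony_id": ["a", "b", "c", "d"],
                "n_days": [0, 50, 60, 70],
                "n_brood_days": [0, 10, 20, 30],
                "temp_regime": ["current", "current", "future", "future"],
                "light_regime": "CEP",
                "origin_swarm": [True, False, True, False],
                "brood_at_start": False,
            }
        )
        res = fit_brood_proportion_glm(recs)
        assert any("excluded 1" in n for n in res.notes)


class TestHeightLMM:
    def test_random_effect_variance_reported(self, study_bundle):
        res = fit_height_lmm(study_bundle.heights)
        assert res.random_effect is not None
        assert res.random_effect["arena_variance"] >= 0.0
        assert set(res.anova["term"]) == {
            "temperature", "photoperiod", "temperature:photoperiod"
        }

    def test_darkness_rows_excluded(self, study_bundle):
        res = fit_height_lmm(study_bundle.heights)
        # CD inflates heights by etiolation; if included, the photoperiod
        # term would carry 2 df. With CD excluded it has exactly 1.
        assert int(res.anova.set_index("term").loc["photoperiod", "df"]) == 1

    def test_identical_heights_flagged_degenerate(self):
        df = pd.DataFrame(
            {
                "height_cm": 10.0,
                "temp_regime": ["current", "future"] * 8,
                "light_regime": ["CEP", "NEP"] * 8,
                "arena_id": [f"a{i % 4}" for i in range(16)],
            }
        )
        res = fit_height_lmm(df)
        assert not res.converged
        assert any("zero variance" in n for n in res.notes)


class TestWeightModel:
    def _status_means(self, brood_loss, nobrood_loss):
        rows = []
        for i in range(12):
            for brood, loss in [(True, brood_loss), (False, nobrood_loss)]:
                rows.append(
                    {
                        "colony_id": f"c{i}",
                        "brood": brood,
                        "mean_change_g": -loss,
                        "temp_regime": "current" if i < 6 else "future",
                        "light_regime": "CEP",
                        "origin_swarm": i % 2 == 0,
                    }
                )
        return pd.DataFrame(rows)

    def test_noiseless_status_effect_is_log_ratio(self):
        res = fit_weight_model(self._status_means(28.84, 20.15))
        coefs = res.coefficients.set_index("term")["estimate"]
        status = coefs[[t for t in coefs.index if "brood" in t and ":" not in t][0]]
        assert float(status) == pytest.approx(np.log(28.84) - np.log(20.15), abs=1e-9)
        assert float(status) == pytest.approx(0.3585, abs=1e-3)

    def test_equal_losses_zero_effect(self):
        res = fit_weight_model(self._status_means(25.0, 25.0))
        coefs = res.coefficients.set_index("term")["estimate"]
        status = coefs[[t for t in coefs.index if "brood" in t and ":" not in t][0]]
        assert float(status) == pytest.approx(0.0, abs=1e-9)

    def test_zero_mean_change_excluded(self):
        df = self._status_means(28.84, 20.15)
        df.loc[0, "mean_change_g"] = 0.0
        res = fit_weight_model(df)
        assert any("zero mean-change" in n for n in res.notes)


class TestCrossSpecies:
    @staticmethod
    def _onsets(week_by_cell, temp="current"):
        rows = []
        for (light, week), n in week_by_cell.items():
            for i in range(n):
                rows.append(
                    {
                        "colony_id": f"{light}-{i}",
                        "time": week * 7,
                        "event": 1,
                        "temp_regime": temp,
                        "light_regime": light,
                        "origin_swarm": i % 2 == 0,
                        "brood_at_start": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_day_to_week_ceiling(self):
        assert list(days_to_weeks(pd.Series([1, 7, 8, 14, 15]))) == [1, 1, 2, 2, 3]

    def test_interaction_dropped_for_single_photoperiod(self, study_bundle):
        fl = study_bundle.flowering
        fl_cep = fl[fl["light_regime"] == "CEP"]
        onsets = self._onsets({("CEP", 5): 8})
        res = fit_cross_species_cox(fl_cep, onsets, "current")
        assert list(res.anova["term"]) == ["species"]

    def test_recovers_early_bee_onset_in_one_cell(self, current_regime, cep_schedule,
                                                  nep_schedule, cd_schedule):
        from phenobee.synthetic import SimulationConfig, simulate_flowering

        cfg = SimulationConfig(seed=21)
        frames = []
        for sched in (cd_schedule, cep_schedule, nep_schedule):
            frames.append(
                simulate_flowering(cfg, current_regime, sched, n_pots=6)
            )
        flowering = pd.concat(frames, ignore_index=True)
        # colonies onset ~9 weeks before the plants' typical flowering in
        # CEP only; elsewhere they match the plants
        med = int(flowering[flowering["event"] == 1]["week"].median())
        onsets = self._onsets(
            {("CEP", max(med - 9, 1)): 6, ("CD", med): 6, ("NEP", med): 6}
        )
        res = fit_cross_species_cox(flowering, onsets, "current")
        assert res.contrasts is not None
        c = res.contrasts.set_index(["cell_a", "cell_b"])

        def species_p(light):
            for a, b in ((f"bee|{light}", f"plant|{light}"),
                         (f"plant|{light}", f"bee|{light}")):
                if (a, b) in c.index:
                    return float(c.loc[(a, b), "p_tukey"])
            raise KeyError(light)

        assert species_p("CEP") < 0.05
        assert species_p("CD") > 0.05 and species_p("NEP") > 0.05


class TestContrasts:
    def test_identical_cells_zero_difference_p_one(self):
        emm = EMMGrid(
            cells=["a", "b"],
            estimate=np.array([1.0, 1.0]),
            cov=np.eye(2) * 0.04,
            df=20.0,
        )
        tab = pairwise_contrasts(emm)
        assert tab.iloc[0]["estimate"] == 0.0
        assert tab.iloc[0]["p_tukey"] == pytest.approx(1.0)

    def test_antisymmetry_by_construction(self):
        rng = np.random.default_rng(3)
        est = rng.normal(size=4)
        emm = EMMGrid(cells=list("abcd"), estimate=est, cov=np.eye(4) * 0.1, df=12.0)
        tab = pairwise_contrasts(emm).set_index(["cell_a", "cell_b"])
        assert tab.loc[("a", "b"), "estimate"] == pytest.approx(est[0] - est[1])
        # pairs are listed once; the reverse contrast is the negation
        assert ("b", "a") not in tab.index

    def test_tukey_p_at_least_unadjusted(self, study_bundle):
        df = study_bundle.heights.assign(
            cell=study_bundle.heights["temp_regime"]
            + "-"
            + study_bundle.heights["light_regime"]
        )
        emm = emmeans_ols(df, "height_cm", "cell")
        tab = pairwise_contrasts(emm)
        assert (tab["p_tukey"] >= tab["p_unadjusted"] - 1e-12).all()
        assert len(tab) == 15  # C(6, 2)

    def test_emmeans_cell_means_match_group_means(self, study_bundle):
        df = study_bundle.heights.assign(
            cell=study_bundle.heights["temp_regime"]
            + "-"
            + study_bundle.heights["light_regime"]
        )
        emm = emmeans_ols(df, "height_cm", "cell")
        means = df.groupby("cell")["height_cm"].mean()
        assert np.allclose(emm.estimate, means[emm.cells].to_numpy())
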