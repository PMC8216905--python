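"""Event-time and proportion statistics for the chamber phenology study.

The analysis stage mirrors an R survival/GLM workflow:

* Cox proportional-hazards models (Efron tie handling) for flowering week
  and brood-onset day, with term-wise sequential analysis of deviance
  (likelihood-ratio chi-square tests, R ``anova`` style);
* a binomial GLM for per-pot open-flower proportions and a quasibinomial
  GLM (Pearson-estimated dispersion, F tests) for per-colony brood-day
  proportions;
* a linear mixed model for final plant height (random arena intercept);
* a linear model for ln|mean daily weight change|;
* two cross-species Cox models comparing flowering and brood-onset weeks
  within each temperature regime;
* Tukey-adjusted pairwise contrasts of estimated marginal means.

Shared-frailty terms are handled by the documented fallback: a plain
partial-likelihood fit with cluster-robust variance on the grouping unit,
recorded in each result's notes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

__all__ = [
    "ModelResult",
    "EMMGrid",
    "round_half_away",
    "summarize_proportions",
    "fit_flowering_cox",
    "fit_flowering_proportion_glm",
    "fit_height_lmm",
    "fit_onset_cox",
    "fit_brood_proportion_glm",
    "fit_cross_species_cox",
    "fit_weight_model",
    "weight_status_means",
    "pairwise_contrasts",
    "emmeans_ols",
    "days_to_weeks",
]

FRAILTY_NOTE = (
    "shared frailty approximated by cluster-robust variance on the grouping unit "
    "(plain Cox partial likelihood, Efron ties)"
)


@dataclass
class ModelResult:
    """Tidy summary of one fitted model.

    ``anova`` holds the term-wise tests (term, statistic, df, p, test);
    ``coefficients`` the estimates and standard errors of the full fit.
    """

    name: str
    anova: pd.DataFrame
    coefficients: pd.DataFrame | None = None
    random_effect: dict | None = None
    contrasts: pd.DataFrame | None = None
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def p_value(self, term: str) -> float:
        row = self.anova.loc[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in {self.name}")
        return float(row["p"].iloc[0])


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (0.125 -> 0.13), as printed summaries do."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def summarize_proportions(counts: list[tuple[int, int]]) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-pot proportions, to two decimals.

    *counts* is a list of (flowered, total) per pot.
    """
    if len(counts) < 2:
        raise ValueError("need at least two pots")
    props = np.array([k / n for k, n in counts], dtype=float)
    return (
        round_half_away(float(props.mean()), 2),
        round_half_away(float(props.std(ddof=1)), 2),
    )


# --------------------------------------------------------------------------
# design-matrix helpers


def _dummies(df: pd.DataFrame, col: str, levels: list | None = None) -> pd.DataFrame:
    """k-1 indicator columns for *col*, reference = first level (sorted)."""
    if levels is None:
        levels = sorted(df[col].astype(str).unique())
    out = pd.DataFrame(index=df.index)
    for lev in levels[1:]:
        out[f"{col}[{lev}]"] = (df[col].astype(str) == str(lev)).astype(float)
    return out


def _interaction(a: pd.DataFrame, b: pd.DataFrame, name: str) -> pd.DataFrame:
    out = pd.DataFrame(index=a.index)
    for ca in a.columns:
        for cb in b.columns:
            la = ca.split("[", 1)[1][:-1]
            lb = cb.split("[", 1)[1][:-1]
            out[f"{name}[{la}:{lb}]"] = a[ca] * b[cb]
    return out


def _drop_constant(groups: list[tuple[str, pd.DataFrame]]) -> list[tuple[str, pd.DataFrame]]:
    """Drop terms whose columns are all constant (single-level factors)."""
    kept = []
    for name, cols in groups:
        cols = cols.loc[:, cols.nunique() > 1]
        if cols.shape[1] > 0:
            kept.append((name, cols))
    return kept


# --------------------------------------------------------------------------
# Cox machinery


def _null_partial_loglik(durations: np.ndarray, events: np.ndarray) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    At beta = 0 every subject has unit risk weight, so each of the d tied
    events at a time with risk-set size n contributes -log(n - j),
    j = 0..d-1.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    ll = 0.0
    for ti in np.unique(t[e]):
        n_risk = int((t >= ti).sum())
        d = int(((t == ti) & e).sum())
        ll -= sum(math.log(n_risk - j) for j in range(d))
    return ll


def _fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    cols: list[str],
    cluster_col: str | None = None,
) -> tuple[CoxPHFitter, float]:
    cf = CoxPHFitter()
    use = df[cols + [duration_col, event_col] + ([cluster_col] if cluster_col else [])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cluster_col:
            cf.fit(use, duration_col=duration_col, event_col=event_col,
                   cluster_col=cluster_col, robust=True)
        else:
            cf.fit(use, duration_col=duration_col, event_col=event_col)
    return cf, float(cf.log_likelihood_)


def _cox_sequential_anova(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    groups: list[tuple[str, pd.DataFrame]],
    name: str,
    cluster_col: str | None = None,
    extra_notes: list[str] | None = None,
) -> ModelResult:
    """Sequential (type-I) likelihood-ratio analysis of deviance for a Cox fit."""
    data = df[[duration_col, event_col] + ([cluster_col] if cluster_col else [])].copy()
    if int(data[event_col].sum()) == 0:
        raise ValueError("no events: cannot fit a Cox model")

    rows = []
    ll_prev = _null_partial_loglik(data[duration_col].to_numpy(), data[event_col].to_numpy())
    cum_cols: list[str] = []
    notes = list(extra_notes or [])
    converged = True
    full_fit = None
    try:
        for term, cols in groups:
            for c in cols.columns:
                data[c] = cols[c].to_numpy()
            cum_cols = cum_cols + list(cols.columns)
            full_fit, ll = _fit_cox(data, duration_col, event_col, cum_cols, cluster_col)
            chi2 = max(2.0 * (ll - ll_prev), 0.0)
            df_term = cols.shape[1]
            rows.append(
                {
                    "term": term,
                    "statistic": chi2,
                    "df": df_term,
                    "p": float(sps.chi2.sf(chi2, df_term)),
                    "test": "LR chi2",
                }
            )
            ll_prev = ll
    except ConvergenceError as err:
        notes.append(f"non-convergence: {err}")
        converged = False

    coef = None
    if full_fit is not None:
        coef = pd.DataFrame(
            {
                "term": full_fit.params_.index,
                "estimate": full_fit.params_.to_numpy(),
                "se": full_fit.standard_errors_.to_numpy(),
            }
        )
    return ModelResult(
        name=name,
        anova=pd.DataFrame(rows, columns=["term", "statistic", "df", "p", "test"]),
        coefficients=coef,
        random_effect=None,
        converged=converged,
        notes=notes,
    )


def fit_flowering_cox(records: pd.DataFrame) -> ModelResult:
    """Cox model for flowering week ~ temperature * photoperiod with the
    flying-arena grouping handled by cluster-robust variance.

    *records* needs columns ``week, event, temp_regime, light_regime,
    arena_id``.
    """
    t = _dummies(records, "temp_regime")
    p = _dummies(records, "light_regime")
    groups = _drop_constant(
        [
            ("temperature", t),
            ("photoperiod", p),
            ("temperature:photoperiod", _interaction(t, p, "temperature:photoperiod")),
        ]
    )
    return _cox_sequential_anova(
        records, "week", "event", groups, "flowering_cox",
        cluster_col="arena_id", extra_notes=[FRAILTY_NOTE],
    )


def fit_onset_cox(records: pd.DataFrame) -> ModelResult:
    """Cox model for brood-onset day with temperature, photoperiod, their
    interaction, colony origin, and brood-at-start as covariates."""
    t = _dummies(records, "temp_regime")
    p = _dummies(records, "light_regime")
    groups = _drop_constant(
        [
            ("temperature", t),
            ("photoperiod", p),
            ("temperature:photoperiod", _interaction(t, p, "temperature:photoperiod")),
            ("origin", records[["origin_swarm"]].astype(float).rename(
                columns={"origin_swarm": "origin[swarm]"})),
            ("brood_at_start", records[["brood_at_start"]].astype(float).rename(
                columns={"brood_at_start": "brood_at_start[yes]"})),
        ]
    )
    return _cox_sequential_anova(records, "time", "event", groups, "onset_cox")


def days_to_weeks(days: pd.Series | np.ndarray) -> np.ndarray:
    """Colony onset days to the plants' weekly scale: week = ceil(day/7)."""
    return np.ceil(np.asarray(days, dtype=float) / 7.0).astype(int)


def fit_cross_species_cox(
    flowering: pd.DataFrame,
    onsets: pd.DataFrame,
    temp_regime: str,
    origin_grouping: str = "separate",
) -> ModelResult:
    """Cross-species synchrony model for one temperature regime.

    Combines flowering weeks (plants) with brood-onset weeks (colonies,
    ``week = ceil(day/7)``) and fits species, photoperiod and their
    interaction; the grouping unit behind the robust variance is the
    flying arena for plants and the swarm-origin class for colonies
    (``origin_grouping="shared"`` pools both species into one factor).
    Tukey-adjusted species-by-photoperiod cell contrasts are attached.
    """
    fl = flowering[flowering["temp_regime"] == temp_regime]
    on = onsets[onsets["temp_regime"] == temp_regime]
    plants = pd.DataFrame(
        {
            "week": fl["week"].to_numpy(),
            "event": fl["event"].to_numpy(),
            "species": "plant",
            "light_regime": fl["light_regime"].to_numpy(),
            "unit": fl["arena_id"].to_numpy(),
        }
    )
    bees = pd.DataFrame(
        {
            "week": days_to_weeks(on["time"]),
            "event": on["event"].to_numpy(),
            "species": "bee",
            "light_regime": on["light_regime"].to_numpy(),
            "unit": np.where(on["origin_swarm"], "bee-swarm", "bee-lwg"),
        }
    )
    if origin_grouping == "shared":
        plants = plants.assign(unit="plant-arena")
    data = pd.concat([plants, bees], ignore_index=True)
    notes = [FRAILTY_NOTE]
    for species, sub in data.groupby("species"):
        if int(sub["event"].sum()) == 0:
            notes.append(f"species {species!r} has zero events")

    s = _dummies(data, "species")
    p = _dummies(data, "light_regime")
    groups = _drop_constant(
        [
            ("photoperiod", p),
            ("species", s),
            ("photoperiod:species", _interaction(p, s, "photoperiod:species")),
        ]
    )
    result = _cox_sequential_anova(
        data, "week", "event", groups, f"cross_species_cox[{temp_regime}]",
        cluster_col="unit", extra_notes=notes,
    )

    if result.converged and result.coefficients is not None:
        result.contrasts = _cox_cell_contrasts(data, result, groups)
    return result


def _cox_cell_contrasts(
    data: pd.DataFrame, result: ModelResult, groups: list[tuple[str, pd.DataFrame]]
) -> pd.DataFrame:
    """Tukey contrasts of cell linear predictors from the full Cox fit."""
    # Rebuild the full design and refit once to get the covariance matrix.
    design = pd.concat([cols for _, cols in groups], axis=1)
    full = pd.concat(
        [design, data[["week", "event"]].reset_index(drop=True)], axis=1
    )
    cf = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cf.fit(full, duration_col="week", event_col="event")
    beta = cf.params_
    cov = cf.variance_matrix_

    cells = (
        data[["species", "light_regime"]].drop_duplicates().sort_values(
            ["species", "light_regime"]
        )
    )
    names, X = [], []
    for _, row in cells.iterrows():
        x = np.zeros(len(beta))
        for i, col in enumerate(beta.index):
            x[i] = _cell_indicator(col, row["species"], row["light_regime"])
        names.append(f"{row['species']}|{row['light_regime']}")
        X.append(x)
    X = np.array(X)
    emm = EMMGrid(
        cells=names,
        estimate=X @ beta.to_numpy(),
        cov=X @ cov.to_numpy() @ X.T,
        df=np.inf,
    )
    return pairwise_contrasts(emm)


def _cell_indicator(col: str, species: str, light: str) -> float:
    """Value of dummy column *col* for a (species, light) cell."""
    inside = col.split("[", 1)[1][:-1]
    if col.startswith("species["):
        return float(inside == species)
    if col.startswith("light_regime["):
        return float(inside == light)
    # interaction photoperiod:species[light:species]
    lev_l, lev_s = inside.split(":")
    return float(lev_l == light and lev_s == species)


# --------------------------------------------------------------------------
# GLMs


def _glm_sequential_deviance(
    endog: np.ndarray,
    groups: list[tuple[str, pd.DataFrame]],
    name: str,
    dispersion: str = "none",
    notes: list[str] | None = None,
) -> ModelResult:
    """Sequential analysis of deviance for a binomial GLM.

    ``dispersion="pearson"`` gives quasibinomial behaviour: the Pearson
    dispersion of the full model scales the deviance drops into F
    statistics (R ``anova(..., test="F")``).
    """
    n = endog.shape[0]
    notes = list(notes or [])

    def fit(exog: np.ndarray):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(endog, exog, family=sm.families.Binomial()).fit()

    exog0 = np.ones((n, 1))
    res_prev = fit(exog0)
    fits = [(None, res_prev)]
    exog = exog0
    for term, cols in groups:
        exog = np.column_stack([exog, cols.to_numpy(dtype=float)])
        res = fit(exog)
        fits.append(((term, cols.shape[1]), res))

    full = fits[-1][1]
    mu = full.fittedvalues
    if np.any(mu < 1e-8) or np.any(mu > 1 - 1e-8):
        notes.append("possible separation: fitted proportions at the boundary")

    rows = []
    if dispersion == "pearson":
        df_resid = full.df_resid
        phi = float(full.pearson_chi2 / df_resid) if df_resid > 0 else float("nan")
        notes.append(f"quasibinomial dispersion (Pearson) = {phi:.3f}")
    for (meta, res), (_, res_prev) in zip(fits[1:], fits[:-1]):
        term, df_term = meta
        drop = max(float(res_prev.deviance - res.deviance), 0.0)
        if dispersion == "pearson":
            stat = (drop / df_term) / phi
            p = float(sps.f.sf(stat, df_term, df_resid)) if df_resid > 0 else float("nan")
            rows.append({"term": term, "statistic": stat, "df": df_term, "p": p, "test": "F"})
        else:
            rows.append(
                {
                    "term": term,
                    "statistic": drop,
                    "df": df_term,
                    "p": float(sps.chi2.sf(drop, df_term)),
                    "test": "LR chi2",
                }
            )

    coef_names = ["Intercept"] + [c for _, cols in groups for c in cols.columns]
    coef = pd.DataFrame(
        {"term": coef_names, "estimate": full.params, "se": full.bse}
    )
    return ModelResult(
        name=name,
        anova=pd.DataFrame(rows, columns=["term", "statistic", "df", "p", "test"]),
        coefficients=coef,
        notes=notes,
    )


def fit_flowering_proportion_glm(counts: pd.DataFrame) -> ModelResult:
    """Binomial GLM for per-pot (flowered, total) counts with temperature,
    photoperiod and their interaction; chi-square analysis of deviance.

    *counts* needs columns ``flowered, total, temp_regime, light_regime``.
    """
    endog = np.column_stack(
        [counts["flowered"].to_numpy(), (counts["total"] - counts["flowered"]).to_numpy()]
    )
    t = _dummies(counts, "temp_regime")
    p = _dummies(counts, "light_regime")
    groups = _drop_constant(
        [
            ("temperature", t),
            ("photoperiod", p),
            ("temperature:photoperiod", _interaction(t, p, "temperature:photoperiod")),
        ]
    )
    return _glm_sequential_deviance(endog, groups, "flowering_proportion_glm")


def fit_brood_proportion_glm(records: pd.DataFrame) -> ModelResult:
    """Quasibinomial GLM for per-colony brood-day proportions.

    *records* needs ``n_brood_days, n_days, temp_regime, light_regime,
    origin_swarm, brood_at_start``; zero-denominator colonies are dropped
    with a note. Term tests are F tests on Pearson-scaled deviance drops.
    """
    df = records.copy()
    n_zero = int((df["n_days"] == 0).sum())
    notes = []
    if n_zero:
        notes.append(f"excluded {n_zero} colony(ies) with zero observed days")
        df = df[df["n_days"] > 0]
    endog = np.column_stack(
        [df["n_brood_days"].to_numpy(), (df["n_days"] - df["n_brood_days"]).to_numpy()]
    )
    t = _dummies(df, "temp_regime")
    p = _dummies(df, "light_regime")
    groups = _drop_constant(
        [
            ("temperature", t),
            ("photoperiod", p),
            ("temperature:photoperiod", _interaction(t, p, "temperature:photoperiod")),
            ("origin", df[["origin_swarm"]].astype(float).rename(
                columns={"origin_swarm": "origin[swarm]"})),
            ("brood_at_start", df[["brood_at_start"]].astype(float).rename(
                columns={"brood_at_start": "brood_at_start[yes]"})),
        ]
    )
    return _glm_sequential_deviance(
        endog, groups, "brood_proportion_glm", dispersion="pearson", notes=notes
    )


# --------------------------------------------------------------------------
# linear (mixed) models


def fit_height_lmm(heights: pd.DataFrame) -> ModelResult:
    """Linear mixed model for final plant height (darkness excluded).

    Fixed effects: temperature, photoperiod (CEP vs NEP), interaction;
    random intercept per flying arena. Term tests are ML likelihood-ratio
    chi-squares; a singular random effect triggers an OLS fallback.
    """
    df = heights[heights["light_regime"] != "CD"].copy()
    if df.empty:
        raise ValueError("no non-darkness rows")
    t = _dummies(df, "temp_regime")
    p = _dummies(df, "light_regime")
    groups = _drop_constant(
        [
            ("temperature", t),
            ("photoperiod", p),
            ("temperature:photoperiod", _interaction(t, p, "temperature:photoperiod")),
        ]
    )
    y = df["height_cm"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return ModelResult(
            name="height_lmm",
            anova=pd.DataFrame(columns=["term", "statistic", "df", "p", "test"]),
            converged=False,
            notes=["degenerate: zero variance in heights"],
        )
    notes = ["term tests: ML likelihood-ratio chi-square (small-sample F "
             "approximation unavailable in this backend)"]

    def ml_loglik(exog: np.ndarray) -> tuple[float, object]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(y, exog, groups=df["arena_id"].to_numpy())
            res = mod.fit(reml=False)
        return float(res.llf), res

    try:
        exog = np.ones((len(df), 1))
        ll_prev, _ = ml_loglik(exog)
        rows = []
        res_full = None
        for term, cols in groups:
            exog = np.column_stack([exog, cols.to_numpy(dtype=float)])
            ll, res_full = ml_loglik(exog)
            chi2 = max(2.0 * (ll - ll_prev), 0.0)
            rows.append(
                {
                    "term": term,
                    "statistic": chi2,
                    "df": cols.shape[1],
                    "p": float(sps.chi2.sf(chi2, cols.shape[1])),
                    "test": "LR chi2",
                }
            )
            ll_prev = ll
        re_var = float(np.asarray(res_full.cov_re)[0, 0])
        resid_var = float(res_full.scale)
        coef_names = ["Intercept"] + [c for _, cols in groups for c in cols.columns]
        coef = pd.DataFrame(
            {
                "term": coef_names,
                "estimate": np.asarray(res_full.fe_params),
                "se": np.asarray(res_full.bse_fe),
            }
        )
        return ModelResult(
            name="height_lmm",
            anova=pd.DataFrame(rows, columns=["term", "statistic", "df", "p", "test"]),
            coefficients=coef,
            random_effect={"arena_variance": re_var, "residual_variance": resid_var},
            notes=notes,
        )
    except (np.linalg.LinAlgError, ValueError) as err:
        notes.append(f"mixed model failed ({err}); OLS fallback with fixed arenas")
        return _height_ols_fallback(df, groups, notes)


def _height_ols_fallback(df, groups, notes) -> ModelResult:
    y = df["height_cm"].to_numpy(dtype=float)
    exog = np.ones((len(df), 1))
    res_prev = sm.OLS(y, exog).fit()
    rows = []
    for term, cols in groups:
        exog = np.column_stack([exog, cols.to_numpy(dtype=float)])
        res = sm.OLS(y, exog).fit()
        df_term = cols.shape[1]
        f = ((res_prev.ssr - res.ssr) / df_term) / res.mse_resid
        rows.append(
            {
                "term": term,
                "statistic": float(f),
                "df": df_term,
                "p": float(sps.f.sf(f, df_term, res.df_resid)),
                "test": "F",
            }
        )
        res_prev = res
    return ModelResult(
        name="height_lmm",
        anova=pd.DataFrame(rows, columns=["term", "statistic", "df", "p", "test"]),
        notes=notes,
    )


def weight_status_means(weights: pd.DataFrame, colonies: pd.DataFrame) -> pd.DataFrame:
    """Mean daily weight change per colony x brood status, joined with
    covariates; input columns ``colony_id, brood, weight_change_g``."""
    agg = (
        weights.groupby(["colony_id", "brood"])["weight_change_g"]
        .mean()
        .reset_index(name="mean_change_g")
    )
    return agg.merge(
        colonies[["colony_id", "temp_regime", "light_regime", "origin_swarm"]],
        on="colony_id",
    )


def fit_weight_model(status_means: pd.DataFrame) -> ModelResult:
    """Linear model for ln|mean daily weight change|.

    Explanatory factors: brood status, temperature, their interaction, and
    colony origin; sequential ANOVA F tests. Zero mean changes are excluded
    (their logarithm is undefined).
    """
    df = status_means.copy()
    notes = []
    zero = df["mean_change_g"] == 0
    if zero.any():
        notes.append(f"excluded {int(zero.sum())} zero mean-change row(s)")
        df = df[~zero].copy()
    df["ln_abs_change"] = np.log(np.abs(df["mean_change_g"]))
    df["brood"] = df["brood"].map({True: "yes", False: "no"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.ols(
            "ln_abs_change ~ C(brood) * C(temp_regime) + C(origin_swarm)", data=df
        ).fit()
        table = sm.stats.anova_lm(res, typ=1)
    rename = {
        "C(brood)": "brood_status",
        "C(temp_regime)": "temperature",
        "C(brood):C(temp_regime)": "brood_status:temperature",
        "C(origin_swarm)": "origin",
    }
    rows = [
        {
            "term": rename.get(idx, idx),
            "statistic": float(row["F"]),
            "df": int(row["df"]),
            "p": float(row["PR(>F)"]),
            "test": "F",
        }
        for idx, row in table.iterrows()
        if idx != "Residual"
    ]
    coef = pd.DataFrame(
        {"term": res.params.index, "estimate": res.params.to_numpy(), "se": res.bse.to_numpy()}
    )
    return ModelResult(
        name="weight_model",
        anova=pd.DataFrame(rows, columns=["term", "statistic", "df", "p", "test"]),
        coefficients=coef,
        notes=notes,
    )


# --------------------------------------------------------------------------
# estimated marginal means and Tukey contrasts


@dataclass
class EMMGrid:
    """Estimated marginal means over treatment cells with their covariance."""

    cells: list[str]
    estimate: np.ndarray
    cov: np.ndarray
    df: float  # residual df; np.inf for asymptotic (Cox) scales


def emmeans_ols(data: pd.DataFrame, response: str, cell_col: str) -> EMMGrid:
    """Cell means of a factorial OLS fit (cell-means parameterization)."""
    cells = sorted(data[cell_col].astype(str).unique())
    X = np.column_stack(
        [(data[cell_col].astype(str) == c).to_numpy(dtype=float) for c in cells]
    )
    y = data[response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return EMMGrid(
        cells=cells,
        estimate=res.params,
        cov=res.cov_params(),
        df=float(res.df_resid),
    )


def pairwise_contrasts(emm: EMMGrid) -> pd.DataFrame:
    """All pairwise cell differences with Tukey (studentized-range) adjusted
    p-values; ``contrast(A,B) = -contrast(B,A)`` by construction."""
    k = len(emm.cells)
    df = emm.df if np.isfinite(emm.df) else 1e7
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(emm.estimate[i] - emm.estimate[j])
            var = float(emm.cov[i, i] + emm.cov[j, j] - 2.0 * emm.cov[i, j])
            se = math.sqrt(max(var, 0.0))
            t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p_un = 2.0 * float(sps.t.sf(abs(t), df))
            p_tk = float(sps.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
            rows.append(
                {
                    "cell_a": emm.cells[i],
                    "cell_b": emm.cells[j],
                    "estimate": diff,
                    "se": se,
                    "statistic": t,
                    "p_unadjusted": min(p_un, 1.0),
                    "p_tukey": min(p_tk, 1.0),
                }
            )
    return pd.DataFrame(rows)
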