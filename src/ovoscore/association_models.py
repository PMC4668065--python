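"""Regression stages linking oocyte scores to embryo and pregnancy outcomes.

Oocyte-level outcomes are clustered within patient, so embryo models are
fit as marginal (population-averaged) GEE models with cluster-robust
sandwich standard errors:

* binary >=8-cell outcome -- logit GEE, exchangeable working correlation
  by default, univariate or multivariate (all six characteristics),
  unadjusted or age-adjusted;
* ordinal day-3 grade -- proportional-odds cumulative-logit GEE with
  independence working correlation, one odds ratio per predictor.

Cycle-level outcomes are one row per patient and use ordinary ML fits:

* clinical pregnancy ~ PTOS (+ age) -- binary logistic regression, with an
  optional restriction to cycles in which only >=8-cell embryos were
  transferred;
* mean embryo grade ~ PTOS + age -- OLS;
* implantation rate across PTOS tertiles -- per-category sacs/transferred
  rates plus an age-adjusted binomial GLM comparison.

Categorical oocyte characteristics are always referenced to the worst
level (-1), so each odds ratio compares level 0 or +1 against -1.
All intervals are 95% Wald intervals on the log-odds (or slope) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.families import Binomial
from statsmodels.genmod.generalized_estimating_equations import GEE, OrdinalGEE

from .oocyte_scoring import ValidationError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "DegenerateOutcomeError",
    "fit_gee_binary",
    "fit_gee_ordinal",
    "fit_pregnancy_logistic",
    "fit_mean_grade_linear",
    "tertile_implantation",
    "TertileResult",
    "or_to_percent",
]

Z95 = stats.norm.ppf(0.975)


class DegenerateOutcomeError(ValueError):
    """Outcome (or a predictor pattern) admits no informative fit."""


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    predictors: column names; names listed in `categorical` are coded with
    reference level -1, everything else enters as a continuous term.
    """

    outcome: str
    predictors: Sequence[str]
    categorical: Sequence[str] = ()
    adjust_age: bool = False
    cluster_by: str | None = "patient_id"
    working_correlation: str = "exchangeable"
    reference_level: int = -1


@dataclass
class ModelFit:
    """Tidy per-term results plus model metadata.

    `terms` columns: term, level, estimate, se, or (exp(estimate) where a
    log-odds scale applies, else NaN), ci_low, ci_high, p.
    """

    terms: pd.DataFrame
    n_obs: int
    n_clusters: int
    converged: bool
    model: str
    adjustment: str = "none"
    extras: dict = field(default_factory=dict)

    def term(self, name: str, level=None) -> pd.Series:
        t = self.terms
        mask = t["term"] == name
        if level is not None:
            mask &= t["level"] == level
        sel = t[mask]
        if len(sel) != 1:
            raise KeyError(f"term {name!r} (level={level}) not uniquely found")
        return sel.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out["model"] = self.model
        out["adjustment"] = self.adjustment
        return out


def or_to_percent(odds_ratio: float) -> str:
    """Phrase an odds ratio as a percent change in odds per unit predictor
    (OR 1.12 -> '+12% odds per point')."""
    pct = (odds_ratio - 1.0) * 100.0
    return f"{pct:+.0f}% odds per point"


def _formula(spec: ModelSpec) -> str:
    parts = []
    for name in spec.predictors:
        if name in set(spec.categorical):
            parts.append(f"C({name}, Treatment({spec.reference_level}))")
        else:
            parts.append(name)
    if spec.adjust_age:
        parts.append("age")
    return f"{spec.outcome} ~ " + " + ".join(parts)


def _parse_term(raw: str) -> tuple[str, object]:
    """Split a patsy term name into (term, level); level NaN for continuous."""
    if raw.startswith("C(") and "[T." in raw:
        name = raw[2:raw.index(",")]
        level = raw[raw.index("[T.") + 3 : -1]
        try:
            level = int(level)
        except ValueError:
            pass
        return name, level
    return raw, np.nan


def _tidy(params, bse, keep_odds: bool = True, drop=()) -> pd.DataFrame:
    rows = []
    for raw in params.index:
        if raw in drop or raw.startswith("I("):
            continue
        name, level = _parse_term(raw)
        est, se = float(params[raw]), float(bse[raw])
        ci_low, ci_high = est - Z95 * se, est + Z95 * se
        p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        rows.append({
            "term": name, "level": level, "estimate": est, "se": se,
            "or": np.exp(est) if keep_odds else np.nan,
            "ci_low": ci_low, "ci_high": ci_high, "p": min(p, 1.0) if np.isfinite(p) else p,
        })
    return pd.DataFrame(rows)


def _check_binary_outcome(y: pd.Series, name: str):
    vals = pd.unique(y.dropna())
    if len(vals) < 2:
        raise DegenerateOutcomeError(
            f"outcome {name!r} is constant ({vals.tolist()}); cannot fit"
        )


def _check_separation(params: pd.Series, threshold: float = 15.0):
    bad = params[np.abs(params) > threshold]
    if len(bad):
        raise DegenerateOutcomeError(
            f"apparent separation: diverging coefficient(s) for {list(bad.index)}"
        )


def _cov_struct(name: str):
    return {"exchangeable": Exchangeable, "independence": Independence}[name]()


def fit_gee_binary(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Logit GEE for a binary embryo outcome with cluster-robust SEs."""
    df = data.dropna(subset=[spec.outcome, *spec.predictors]).copy()
    df[spec.outcome] = df[spec.outcome].astype(int)
    _check_binary_outcome(df[spec.outcome], spec.outcome)
    if spec.cluster_by is None:
        raise ValidationError("oocyte-level outcomes require cluster_by")
    if df[spec.cluster_by].nunique() < 2:
        raise ValidationError("at least 2 clusters required")
    model = GEE.from_formula(
        _formula(spec), groups=spec.cluster_by, data=df,
        family=Binomial(), cov_struct=_cov_struct(spec.working_correlation),
    )
    res = model.fit(maxiter=200)
    _check_separation(res.params)
    return ModelFit(
        terms=_tidy(res.params, res.bse, drop=("Intercept",)),
        n_obs=int(res.nobs),
        n_clusters=df[spec.cluster_by].nunique(),
        converged=bool(getattr(res, "converged", True)),
        model=f"gee_binary:{spec.outcome}",
        adjustment="age" if spec.adjust_age else "none",
        extras={"intercept": float(res.params["Intercept"])},
    )


def fit_gee_ordinal(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Proportional-odds cumulative-logit GEE for the 5-level grade.

    Independence working correlation with cluster-robust sandwich SEs; a
    positive coefficient means higher (better) grades, so the reported OR
    is the odds ratio of exceeding any grade cutoff per unit predictor.
    """
    from patsy import dmatrix

    df = data.dropna(subset=[spec.outcome, *spec.predictors]).copy()
    df[spec.outcome] = df[spec.outcome].astype(int)
    if df[spec.outcome].nunique() < 2:
        raise DegenerateOutcomeError(
            f"ordinal outcome {spec.outcome!r} has fewer than 2 observed levels"
        )
    # the cutpoint parameters play the intercept's role, so the design must
    # not contain one; an explicit intercept (or any constant predictor)
    # would be collinear with the cutpoints
    rhs = _formula(spec).split("~", 1)[1]
    exog = dmatrix(rhs, df, return_type="dataframe").drop(columns="Intercept")
    constant = [c for c in exog.columns if exog[c].nunique() <= 1]
    exog = exog.drop(columns=constant)

    if exog.shape[1] == 0:
        res_params = pd.Series(dtype=float)
        res_bse = pd.Series(dtype=float)
        converged = True
    else:
        model = OrdinalGEE(
            df[spec.outcome].to_numpy(), exog, groups=df[spec.cluster_by],
            cov_struct=Independence(),
        )
        res = model.fit(maxiter=200)
        keep = [i for i, name in enumerate(res.model.exog_names)
                if not name.startswith("I(")]
        res_params = pd.Series(np.asarray(res.params)[keep],
                               index=np.asarray(res.model.exog_names)[keep])
        _check_separation(res_params)
        with np.errstate(invalid="ignore"):
            bse_all = np.sqrt(np.diag(res.cov_robust))
        res_bse = pd.Series(bse_all[keep], index=res_params.index)
        converged = bool(getattr(res, "converged", True))

    terms = _tidy(res_params, res_bse)
    # unidentifiable (constant) predictors: slope 0 with infinite SE
    for name in constant:
        term, level = _parse_term(name)
        terms = pd.concat([terms, pd.DataFrame([{
            "term": term, "level": level, "estimate": 0.0, "se": np.inf,
            "or": 1.0, "ci_low": -np.inf, "ci_high": np.inf, "p": 1.0,
        }])], ignore_index=True)
    return ModelFit(
        terms=terms,
        n_obs=len(df),
        n_clusters=df[spec.cluster_by].nunique(),
        converged=converged,
        model=f"gee_ordinal:{spec.outcome}",
        adjustment="age" if spec.adjust_age else "none",
    )


def fit_pregnancy_logistic(
    cycles: pd.DataFrame,
    adjust_age: bool = True,
    eight_cell_transfers_only: bool = False,
) -> ModelFit:
    """Binary logistic regression of clinical pregnancy on PTOS (+ age).

    With `eight_cell_transfers_only`, the fit is restricted to cycles in
    which every transferred embryo reached >= 8 cells (requires a boolean
    `all_transferred_eight_cell` column).
    """
    df = cycles.copy()
    subset = "all"
    if eight_cell_transfers_only:
        if "all_transferred_eight_cell" not in df.columns:
            raise ValidationError(
                "restriction requires an 'all_transferred_eight_cell' column"
            )
        df = df[df["all_transferred_eight_cell"].astype(bool)]
        subset = "eight_cell_transfers"
    df = df.dropna(subset=["pregnancy", "ptos"] + (["age"] if adjust_age else []))
    df["pregnancy"] = df["pregnancy"].astype(int)
    _check_binary_outcome(df["pregnancy"], "pregnancy")
    formula = "pregnancy ~ ptos" + (" + age" if adjust_age else "")
    res = sm.Logit.from_formula(formula, data=df).fit(disp=0, maxiter=200)
    _check_separation(res.params)
    return ModelFit(
        terms=_tidy(res.params, res.bse, drop=("Intercept",)),
        n_obs=int(res.nobs),
        n_clusters=int(res.nobs),
        converged=bool(res.mle_retvals.get("converged", True)),
        model="pregnancy_logistic",
        adjustment="age" if adjust_age else "none",
        extras={"subset": subset},
    )


def fit_mean_grade_linear(cycles: pd.DataFrame, outcome: str = "mean_grade_available",
                          adjust_age: bool = True) -> ModelFit:
    """OLS of per-cycle mean embryo grade on PTOS (+ age)."""
    df = cycles.dropna(subset=[outcome, "ptos"] + (["age"] if adjust_age else []))
    if len(df) < 3:
        raise ValidationError("at least 3 cycles required for the linear model")
    formula = f"{outcome} ~ ptos" + (" + age" if adjust_age else "")
    res = sm.OLS.from_formula(formula, data=df).fit()
    fit = ModelFit(
        terms=_tidy(res.params, res.bse, keep_odds=False, drop=("Intercept",)),
        n_obs=int(res.nobs),
        n_clusters=int(res.nobs),
        converged=True,
        model="mean_grade_linear",
        adjustment="age" if adjust_age else "none",
        extras={"intercept": float(res.params["Intercept"])},
    )
    slope = fit.term("ptos")
    fit.extras["z"] = float(slope["estimate"] / slope["se"]) if slope["se"] > 0 else np.nan
    return fit


@dataclass
class TertileResult:
    """Implantation rates by PTOS tertile and their age-adjusted comparison."""

    rates: pd.DataFrame  # tertile, n_cycles, sacs, transferred, implantation_rate
    p_overall: float
    degenerate: bool = False


def assign_tertiles(cycles: pd.DataFrame, mode: str = "rank") -> pd.Series:
    """Equal-count PTOS tertiles (low=1, mid=2, high=3).

    mode='rank' (default): stable sort on (ptos, patient_id), split into
    three near-equal groups. mode='quantile': cut at the 1/3 and 2/3
    empirical quantiles (counts may be unequal under ties).
    """
    if mode == "rank":
        order = cycles.sort_values(["ptos", "patient_id"], kind="stable").index
        n = len(order)
        sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
        labels = np.repeat([1, 2, 3], sizes)
        return pd.Series(labels, index=order).reindex(cycles.index)
    if mode == "quantile":
        q1, q2 = cycles["ptos"].quantile([1 / 3, 2 / 3])
        return pd.Series(
            np.select([cycles["ptos"] <= q1, cycles["ptos"] <= q2], [1, 2], default=3),
            index=cycles.index,
        )
    raise ValidationError(f"unknown tertile mode {mode!r}")


def tertile_implantation(cycles: pd.DataFrame, mode: str = "rank") -> TertileResult:
    """Implantation rate (total sacs / total embryos transferred) per PTOS
    tertile, with an age-adjusted binomial GLM comparison across tertiles."""
    required = {"ptos", "sacs", "n_transferred", "age", "patient_id"}
    missing = required - set(cycles.columns)
    if missing:
        raise ValidationError(f"cycle table missing columns: {sorted(missing)}")
    if len(cycles) < 3:
        raise ValidationError("at least 3 cycles required for tertiles")
    df = cycles.copy()
    df["tertile"] = assign_tertiles(df, mode=mode)
    agg = df.groupby("tertile").agg(
        n_cycles=("patient_id", "size"), sacs=("sacs", "sum"),
        transferred=("n_transferred", "sum"),
    ).reindex([1, 2, 3], fill_value=0).reset_index()
    agg["implantation_rate"] = agg["sacs"] / agg["transferred"].replace(0, np.nan)

    total_sacs = df["sacs"].sum()
    if total_sacs == 0 or total_sacs == df["n_transferred"].sum():
        return TertileResult(rates=agg, p_overall=1.0, degenerate=True)

    endog = np.column_stack([df["sacs"], df["n_transferred"] - df["sacs"]])
    exog = pd.get_dummies(df["tertile"], prefix="tertile", drop_first=True).astype(float)
    exog["age"] = df["age"].to_numpy()
    exog = sm.add_constant(exog)
    res = sm.GLM(endog, exog, family=Binomial()).fit()
    names = [c for c in exog.columns if c.startswith("tertile_")]
    constraint = ", ".join(f"{c} = 0" for c in names)
    wald = res.wald_test(constraint, scalar=True)
    return TertileResult(rates=agg, p_overall=float(wald.pvalue))
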