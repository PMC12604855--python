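"""Group summaries, mixed-model contrasts and stepwise-AIC influence.

Three layers sit on top of the partition table:

* factor-level means of the climatic/phenological variables (one row per
  level of a grouping factor, per budburst event);
* linear mixed-effects contrasts of observed response or phenological lag
  between factor levels, with location and species as random effects,
  least-square means ± SE and compact significance letters;
* stepwise OLS selection over the nine site/phenology predictors by AIC
  (combined forward/backward, R ``step()`` style) with a per-variable
  influence share computed from single-term-deletion ΔAIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GroupSummary",
    "ModelReport",
    "GROUPING_FACTORS",
    "SUMMARY_VARIABLES",
    "STEPWISE_CANDIDATES",
    "summarize_groups",
    "summaries_to_frame",
    "GroupContrastModel",
    "fit_group_contrast",
    "StepwiseAICRegressor",
    "stepwise_aic",
    "variable_influence",
    "compact_letters",
]

logger = logging.getLogger(__name__)

GROUPING_FACTORS = ("approach", "origin", "region", "growth_form")

#: variables averaged in group summaries: display name -> column
SUMMARY_VARIABLES = {
    "spring_phenology_julian": "o_ci",
    "budburst_temperature_c": "t_b",
    "altitude_m": "altitude_m",
    "latitude_deg": "latitude",
    "mat_c": "mat_c",
    "forcing_change_dd": "f_c",
    "spring_warming_c": "s_w",
    "phenological_lag_d": "n_c",
}

#: the nine candidate predictors of the observed response
STEPWISE_CANDIDATES = (
    "altitude_m",
    "latitude",
    "mat_c",
    "map_mm",
    "o_ci",
    "t_b",
    "f_c",
    "s_w",
    "n_c",
)


@dataclass(frozen=True)
class GroupSummary:
    """Means of the climatic/phenological variables at one factor level."""

    factor: str
    level: str
    means: dict
    sample_size: int


@dataclass
class ModelReport:
    """Fitted-model output: coefficients, lsmeans/letters or influence."""

    kind: str
    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: Optional[float] = None
    n: int = 0
    aic: Optional[float] = None
    lsmeans: Optional[pd.DataFrame] = None
    letters: Optional[dict] = None
    influence: Optional[pd.DataFrame] = None
    selected: Optional[list] = None
    notes: list = field(default_factory=list)


def summarize_groups(
    records: pd.DataFrame, factor: str, event: Optional[str] = None
) -> list[GroupSummary]:
    """Arithmetic means per factor level, NaN-aware per variable.

    Records with an undefined budburst temperature contribute to every mean
    except the temperature itself. ``event`` restricts to one budburst event
    (leafing or flowering); sample sizes over the levels of one factor then
    sum to the event total.
    """
    if factor not in GROUPING_FACTORS:
        raise ValueError(
            f"unknown grouping factor {factor!r}; expected one of {GROUPING_FACTORS}"
        )
    df = records if event is None else records[records["event"] == event]
    out = []
    for level, sub in df.groupby(factor, observed=True, sort=True):
        means = {
            name: float(sub[col].mean())
            for name, col in SUMMARY_VARIABLES.items()
            if col in sub.columns
        }
        out.append(GroupSummary(factor, str(level), means, len(sub)))
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary], decimals: int = 1) -> pd.DataFrame:
    """Tabulate summaries, rounded to display precision (one decimal)."""
    rows = []
    for s in summaries:
        row = {"factor": s.factor, "level": s.level}
        row.update({k: round(v, decimals) for k, v in s.means.items()})
        row["sample_size"] = s.sample_size
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-model group contrasts


class GroupContrastModel(BaseEstimator):
    """Mixed-effects contrast of one response between factor levels.

    Fits ``response ~ C(factor)`` with a random intercept per location and a
    species variance component; estimation is by REML for the reported
    standard errors, with a parallel maximum-likelihood fit for AIC. When the
    random structure is singular or fails to converge the model falls back
    to ordinary least squares with a logged warning.

    Fitted attributes: ``lsmeans_`` (level, estimate, se), ``pairwise_``
    (level pair, difference, se, p), ``letters_`` (level -> letter string;
    levels sharing a letter do not differ at ``alpha``), ``used_mixed_``.
    """

    def __init__(
        self,
        response: str = "n_o",
        factor: str = "region",
        alpha: float = 0.05,
        location_col: str = "location",
        species_col: str = "species",
    ):
        self.response = response
        self.factor = factor
        self.alpha = alpha
        self.location_col = location_col
        self.species_col = species_col

    def fit(self, X: pd.DataFrame, y=None):
        df = X.dropna(subset=[self.response, self.factor]).copy()
        counts = df[self.factor].value_counts()
        if (counts >= 2).sum() < 2:
            raise ValueError(
                f"need >=2 levels of {self.factor!r} with >=2 records each"
            )
        df[self.factor] = df[self.factor].astype(str)
        levels = sorted(df[self.factor].unique())
        formula = f"{self.response} ~ C({self.factor})"

        result, used_mixed, notes = self._fit_with_fallback(formula, df)
        self.result_ = result
        self.used_mixed_ = used_mixed
        self.notes_ = notes
        self.levels_ = levels

        k = len(levels)
        fe_names = list(result.params.index[: k] if used_mixed else result.params.index)
        params = np.asarray(result.params)[:k]
        cov = np.asarray(result.cov_params())[:k, :k]

        # treatment coding: level j mean = intercept + coef_j (coef_0 = 0)
        L = np.zeros((k, k))
        L[:, 0] = 1.0
        for j in range(1, k):
            L[j, j] = 1.0
        means = L @ params
        ses = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
        self.lsmeans_ = pd.DataFrame(
            {"level": levels, "estimate": means, "se": ses}
        )

        pairs = []
        # z-based inference for the mixed model, t with residual df for OLS
        df_resid = None if used_mixed else float(result.df_resid)
        pmat = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
        for i in range(k):
            for j in range(i + 1, k):
                c = L[i] - L[j]
                diff = float(c @ params)
                se = float(np.sqrt(c @ cov @ c))
                z = diff / se if se > 0 else np.inf
                p = (
                    2.0 * sps.norm.sf(abs(z))
                    if df_resid is None
                    else 2.0 * sps.t.sf(abs(z), df_resid)
                )
                pairs.append(
                    {
                        "level_a": levels[i],
                        "level_b": levels[j],
                        "difference": diff,
                        "se": se,
                        "p_value": p,
                    }
                )
                pmat.iloc[i, j] = pmat.iloc[j, i] = p
        self.pairwise_ = pd.DataFrame(pairs)
        self.letters_ = compact_letters(levels, pmat, self.alpha)
        return self

    def _fit_with_fallback(self, formula, df):
        notes = []
        replicated = (
            df[self.location_col].duplicated().any()
            or df[self.species_col].duplicated().any()
        )
        if not replicated:
            # singleton locations and species: random effects are confounded
            # with the residual and unidentifiable
            notes.append("no replication within locations or species")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model = smf.mixedlm(
                        formula,
                        df,
                        groups=df[self.location_col],
                        vc_formula={"species": f"0 + C({self.species_col})"},
                    )
                    res = model.fit(reml=True)
                    if res.converged and np.all(
                        np.isfinite(np.asarray(res.bse_fe))
                    ):
                        return res, True, notes
                    notes.append("singular random-effects structure")
                except Exception as exc:  # singular / convergence failure
                    notes.append(f"mixed model failed: {exc}")
        logger.warning(
            "mixed model for %s ~ %s fell back to OLS (%s)",
            self.response,
            self.factor,
            "; ".join(notes) or "non-finite SEs",
        )
        res = smf.ols(formula, df).fit()
        return res, False, notes

    def report(self) -> ModelReport:
        res = self.result_
        params = res.fe_params if self.used_mixed_ else res.params
        bse = res.bse_fe if self.used_mixed_ else res.bse
        k = len(self.levels_)
        coef_names = ["Intercept"] + [f"{self.factor}[{lv}]" for lv in self.levels_[1:]]
        return ModelReport(
            kind="group_contrast",
            response=self.response,
            params=pd.Series(np.asarray(params)[:k], index=coef_names),
            bse=pd.Series(np.asarray(bse)[:k], index=coef_names),
            pvalues=self.pairwise_.set_index(["level_a", "level_b"])["p_value"],
            n=int(res.nobs),
            lsmeans=self.lsmeans_,
            letters=self.letters_,
            notes=self.notes_,
        )


def fit_group_contrast(
    records: pd.DataFrame,
    response: str = "n_o",
    factor: str = "region",
    alpha: float = 0.05,
) -> ModelReport:
    """One mixed-model contrast fit (one factor, one response)."""
    return GroupContrastModel(response=response, factor=factor, alpha=alpha).fit(
        records
    ).report()


def compact_letters(
    levels: Sequence[str], pmatrix: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display: levels share a letter iff p >= alpha.

    Insert-and-absorb construction: start from one group holding every
    level, split a group whenever it contains a significantly different
    pair, then drop groups contained in others.
    """
    groups: list[set] = [set(levels)]
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if pmatrix.loc[a, b] < alpha:
                new_groups = []
                for g in groups:
                    if a in g and b in g:
                        new_groups.extend([g - {a}, g - {b}])
                    else:
                        new_groups.append(g)
                # absorb subsets
                groups = [
                    g
                    for g in new_groups
                    if g and not any(g < h for h in new_groups)
                ]
                # deduplicate
                seen, uniq = [], []
                for g in groups:
                    if g not in seen:
                        seen.append(g)
                        uniq.append(g)
                groups = uniq
    order = sorted(groups, key=lambda g: min(levels.index(x) for x in g))
    letters = {lv: "" for lv in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", order):
        for lv in g:
            letters[lv] += letter
    return letters


# ---------------------------------------------------------------------------
# stepwise AIC selection


class StepwiseAICRegressor(BaseEstimator, RegressorMixin):
    """OLS with combined forward/backward term selection by AIC.

    Starts from the full model over ``candidates`` (or all columns of X) and
    at each step applies whichever single-term addition or deletion lowers
    the AIC most, until the AIC is stationary — the automated ``both``
    direction of R's ``step()``. Predictors enter untransformed and
    unstandardized. Selection is deterministic given the data.

    Fitted attributes: ``selected_features_``, ``coef_`` (Series over the
    selected terms), ``intercept_``, ``aic_``, ``rsquared_``, ``n_obs_``,
    ``results_`` (the statsmodels fit of the final model), ``trace_``
    (list of (move, term, aic) steps).
    """

    def __init__(self, candidates: Optional[Sequence[str]] = None, start: str = "full"):
        self.candidates = candidates
        self.start = start

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        candidates = list(self.candidates) if self.candidates is not None else list(X.columns)
        missing = [c for c in candidates if c not in X.columns]
        if missing:
            raise ValueError(f"candidates absent from X: {missing}")
        y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
        data = pd.concat([X[candidates].astype(float), y], axis=1).dropna()
        n, p = len(data), len(candidates)
        if n <= p + 1:
            raise ValueError(
                f"too few complete cases (n={n}) for {p} candidates"
            )
        self.n_dropped_ = len(X) - n
        yv = data["y"].to_numpy()

        def fit_terms(terms: tuple) -> sm.regression.linear_model.RegressionResultsWrapper:
            M = sm.add_constant(data[list(terms)].to_numpy(), has_constant="add")
            return sm.OLS(yv, M).fit()

        current = tuple(candidates) if self.start == "full" else tuple()
        res = fit_terms(current)
        trace = [("start", None, res.aic)]
        while True:
            # deletions accept AIC ties (parsimony: an exactly redundant
            # term, e.g. a perfectly collinear duplicate, is dropped);
            # additions must strictly lower the AIC
            best_move, best_aic, best_res = None, res.aic + 1e-10, None
            for t in current:
                trial = tuple(c for c in current if c != t)
                r = fit_terms(trial)
                if r.aic < best_aic:
                    best_move, best_aic, best_res = ("drop", t, trial), r.aic, r
            for t in candidates:
                if t in current:
                    continue
                trial = current + (t,)
                r = fit_terms(trial)
                if r.aic < min(best_aic, res.aic - 1e-10):
                    best_move, best_aic, best_res = ("add", t, trial), r.aic, r
            if best_move is None:
                break
            current, res = best_move[2], best_res
            trace.append((best_move[0], best_move[1], best_aic))

        self.selected_features_ = list(current)
        self.results_ = res
        self.trace_ = trace
        self.intercept_ = float(res.params[0])
        self.coef_ = pd.Series(res.params[1:], index=self.selected_features_)
        self.aic_ = float(res.aic)
        self.rsquared_ = float(res.rsquared)
        self.n_obs_ = n
        self._data_ = data
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        vals = pd.DataFrame(X)[self.selected_features_].astype(float).to_numpy()
        return self.intercept_ + vals @ self.coef_.to_numpy()


def variable_influence(reg: StepwiseAICRegressor) -> pd.DataFrame:
    """Per-term influence shares from single-term-deletion ΔAIC.

    For each retained term, ΔAIC is the AIC increase when that term alone is
    removed from the final model; the intercept row takes the residual of
    the intercept-only ΔAIC not accounted for by single deletions (floored
    at zero). Shares normalize the ΔAIC column to 100%.
    """
    data = reg._data_
    yv = data["y"].to_numpy()

    def aic_of(terms):
        M = sm.add_constant(
            data[list(terms)].to_numpy() if terms else np.empty((len(data), 0)),
            has_constant="add",
        )
        return sm.OLS(yv, M).fit().aic

    final_aic = reg.aic_
    deltas = {}
    for t in reg.selected_features_:
        others = [c for c in reg.selected_features_ if c != t]
        deltas[t] = aic_of(others) - final_aic
    total_delta = aic_of([]) - final_aic
    deltas["Intercept"] = max(total_delta - sum(deltas.values()), 0.0)
    total = sum(deltas.values())
    share = {t: (100.0 * d / total if total > 0 else np.nan) for t, d in deltas.items()}
    out = pd.DataFrame(
        {"delta_aic": pd.Series(deltas), "influence_pct": pd.Series(share).round(1)}
    )
    return out.loc[["Intercept"] + reg.selected_features_]


def stepwise_aic(
    records: pd.DataFrame,
    response: str = "n_o",
    candidates: Sequence[str] = STEPWISE_CANDIDATES,
) -> ModelReport:
    """Stepwise-AIC regression of the observed response on the nine
    site/phenology predictors, with the influence decomposition."""
    reg = StepwiseAICRegressor(candidates=list(candidates)).fit(
        records, records[response]
    )
    infl = variable_influence(reg)
    names = ["Intercept"] + reg.selected_features_
    return ModelReport(
        kind="stepwise",
        response=response,
        params=pd.Series(np.asarray(reg.results_.params), index=names),
        bse=pd.Series(np.asarray(reg.results_.bse), index=names),
        pvalues=pd.Series(np.asarray(reg.results_.pvalues), index=names),
        r_squared=reg.rsquared_,
        n=reg.n_obs_,
        aic=reg.aic_,
        influence=infl,
        selected=reg.selected_features_,
    )
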