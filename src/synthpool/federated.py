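"""Exact federated least squares via sufficient-statistic exchange.

Each node (country) computes only aggregate interim results — the
cross-product matrix X'X, the vector X'y, the outcome sum of squares and the
row count — over its complete cases. Summing these across nodes and solving
the normal equations reproduces the pooled ordinary-least-squares fit
exactly: no row-level data crosses the node boundary and no approximation is
involved. This is the ground-truth oracle against which pooled
synthetic-data analyses are judged.

The coding map for the cardiovascular-health regressions lives here:
female vs male (ref), age-group ordinal score 1-7, education ordinal 1-4,
household size ordinal 1-5, household income reverse-coded (low = 3 ...
high = 1), marital-status indicators against "single", immigrant yes vs no
(ref), and country indicator against the synthesizing country (ref). The
interaction model adds every predictor x country product term.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.stats import norm

from .schema import HarmonizedSurveyTable
from .simulate import (
    AGE_LEVELS, EDU_LEVELS, HH_LEVELS, INCOME_LEVELS, canheart_scores,
)

INTERCEPT = "intercept"


class FederatedError(ValueError):
    pass


class AliasingWarning(UserWarning):
    """Pooled X'X was rank deficient; pseudo-inverse used, coefficients aliased."""


# --------------------------------------------------------------------------
# Model specification and design coding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A linear model: outcome, harmonized predictor variables, interactions."""

    name: str
    predictors: tuple
    interactions: bool = False
    outcome: str = "canheart"


def univariable_specs() -> list:
    """One single-predictor model per table row of the univariable analysis."""
    vars_ = ("sex", "marital_status", "household_size", "education",
             "income", "immigrant", "age_group", "country")
    return [ModelSpec(f"univariable_{v}", (v,)) for v in vars_]


def main_effects_spec() -> ModelSpec:
    return ModelSpec("main_effects", (
        "sex", "education", "marital_status", "household_size",
        "income", "immigrant", "age_group", "country",
    ))


def interaction_spec() -> ModelSpec:
    return ModelSpec("interaction", (
        "sex", "education", "marital_status", "household_size",
        "income", "immigrant", "age_group", "country",
    ), interactions=True)


def _coded_columns(df: pd.DataFrame, var: str) -> dict:
    """Numeric design columns for one harmonized predictor (NaN propagates)."""
    if var == "sex":
        return {"sex_female": df["sex"].map({"male": 0.0, "female": 1.0})}
    if var == "age_group":
        return {"age": df["age_group"].map(dict(zip(AGE_LEVELS, map(float, range(1, 8)))))}
    if var == "education":
        return {"education": df["education"].map(dict(zip(EDU_LEVELS, map(float, range(1, 5)))))}
    if var == "household_size":
        return {"household_size": df["household_size"].map(dict(zip(HH_LEVELS, map(float, range(1, 6)))))}
    if var == "income":
        # reverse coded: low = 3, medium = 2, high = 1
        return {"income_rev": df["income"].map(dict(zip(INCOME_LEVELS, (3.0, 2.0, 1.0))))}
    if var == "marital_status":
        return {
            "marital_divorced_widowed": df["marital_status"].map(
                {"single": 0.0, "divorced_widowed": 1.0, "married_commonlaw": 0.0}),
            "marital_married": df["marital_status"].map(
                {"single": 0.0, "divorced_widowed": 0.0, "married_commonlaw": 1.0}),
        }
    if var == "immigrant":
        return {"immigrant_yes": df["immigrant"].map({"no": 0.0, "yes": 1.0})}
    if var == "country":
        return {"country_at": df["country"].map({"CA": 0.0, "AT": 1.0})}
    if var in df.columns:
        # any other variable enters as-is (continuous columns, e.g. bmi)
        return {var: pd.to_numeric(df[var])}
    raise FederatedError(f"no coding defined for predictor {var!r}")


def build_design(table: HarmonizedSurveyTable, model: ModelSpec):
    """Design matrix (with intercept) and outcome vector, complete cases only.

    Returns (X, y) as a DataFrame/Series; rows with any missing model
    variable are dropped, per-model.
    """
    df = table.data
    if model.outcome == "canheart":
        y = canheart_scores(table)
    else:
        y = pd.to_numeric(df[model.outcome])
    cols = {INTERCEPT: pd.Series(1.0, index=df.index)}
    main_names = []
    for var in model.predictors:
        if model.interactions and var == "country":
            continue  # country enters below with the products
        for cname, series in _coded_columns(df, var).items():
            cols[cname] = series
            main_names.append(cname)
    if model.interactions:
        cols["country_at"] = _coded_columns(df, "country")["country_at"]
        for cname in main_names:
            cols[f"{cname}:country_at"] = cols[cname] * cols["country_at"]
    X = pd.DataFrame(cols)
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    if len(X) == 0:
        raise FederatedError(f"{model.name}: zero complete cases")
    return X, y


# --------------------------------------------------------------------------
# Node summaries and the federated solve
# --------------------------------------------------------------------------

@dataclass
class NodeSummary:
    """One node's aggregate interim results (no row-level data)."""

    columns: list
    xtx: np.ndarray
    xty: np.ndarray
    yty: float
    n: int

    def __post_init__(self):
        self.xtx = np.asarray(self.xtx, dtype=float)
        self.xty = np.asarray(self.xty, dtype=float)
        p = len(self.columns)
        if self.xtx.shape != (p, p) or self.xty.shape != (p,):
            raise FederatedError("summary dimensions inconsistent with column list")
        if not np.allclose(self.xtx, self.xtx.T, atol=1e-8):
            raise FederatedError("X'X must be symmetric")

    def to_json(self) -> str:
        return json.dumps({
            "columns": list(self.columns),
            "xtx": self.xtx.tolist(),
            "xty": self.xty.tolist(),
            "yty": self.yty,
            "n": self.n,
        })

    @classmethod
    def from_json(cls, text: str) -> "NodeSummary":
        d = json.loads(text)
        return cls(d["columns"], np.array(d["xtx"]), np.array(d["xty"]),
                   float(d["yty"]), int(d["n"]))


def summarize_node(table: HarmonizedSurveyTable, model: ModelSpec) -> NodeSummary:
    """Aggregate cross-products of one node's complete cases for one model."""
    X, y = build_design(table, model)
    Xm = X.to_numpy(float)
    yv = y.to_numpy(float)
    return NodeSummary(
        columns=list(X.columns),
        xtx=Xm.T @ Xm,
        xty=Xm.T @ yv,
        yty=float(yv @ yv),
        n=len(yv),
    )


@dataclass
class OlsFit:
    """Pooled OLS estimates recovered from summed node aggregates."""

    params: pd.Series
    variances: pd.Series
    residual_variance: float
    r2: float
    n: int

    @property
    def se(self) -> pd.Series:
        return np.sqrt(self.variances)

    def conf_int(self, z: float = 1.96) -> pd.DataFrame:
        half = z * self.se
        return pd.DataFrame({"ci_low": self.params - half,
                             "ci_high": self.params + half})

    def p_values(self) -> pd.Series:
        se = self.se.replace(0.0, np.nan)
        z = (self.params / se).abs()
        return pd.Series(2.0 * norm.sf(z), index=self.params.index).fillna(1.0)

    def table(self) -> pd.DataFrame:
        """Coefficient table in the published layout (estimate, CI, flag)."""
        out = pd.DataFrame({"estimate": self.params})
        out[["ci_low", "ci_high"]] = self.conf_int()
        out["p_value"] = self.p_values()
        out["significant"] = out["p_value"] < 0.05
        return out


def solve_federated(summaries) -> OlsFit:
    """Solve pooled OLS from node summaries.

    The summed X'X, X'y, y'y and n are algebraically identical to the
    pooled-data cross-products, so coefficients, coefficient variances,
    residual variance and R^2 all equal the direct pooled fit. Rank-deficient
    pooled X'X falls back to the pseudo-inverse with an aliasing warning.
    """
    summaries = list(summaries)
    if not summaries:
        raise FederatedError("no node summaries given")
    columns = summaries[0].columns
    for s in summaries[1:]:
        if s.columns != columns:
            raise FederatedError("node summaries have mismatched column lists")
    xtx = sum(s.xtx for s in summaries)
    xty = sum(s.xty for s in summaries)
    yty = float(sum(s.yty for s in summaries))
    n = int(sum(s.n for s in summaries))
    p = len(columns)

    try:
        beta = np.linalg.solve(xtx, xty)
        xtx_inv = np.linalg.inv(xtx)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "pooled X'X is rank deficient; using pseudo-inverse "
            "(some coefficients are aliased)", AliasingWarning)
        xtx_inv = np.linalg.pinv(xtx)
        beta = xtx_inv @ xty

    rss = max(yty - float(beta @ xty), 0.0)
    dof = n - p
    sigma2 = rss / dof if dof > 0 else np.nan
    variances = np.clip(sigma2 * np.diag(xtx_inv), 0.0, None)

    if INTERCEPT in columns:
        sum_y = xty[columns.index(INTERCEPT)]
        tss = yty - sum_y**2 / n
    else:
        tss = yty
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return OlsFit(
        params=pd.Series(beta, index=columns),
        variances=pd.Series(variances, index=columns),
        residual_variance=float(sigma2),
        r2=float(np.clip(r2, 0.0, 1.0)),
        n=n,
    )


def pooled_ols(table: HarmonizedSurveyTable, model: ModelSpec) -> OlsFit:
    """Direct OLS on one table (a single-node federated solve)."""
    return solve_federated([summarize_node(table, model)])
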