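"""Two-country harmonized survey simulator and the modified CANHEART index.

The real study data (two national health interview surveys harmonized to
twelve variables) are restricted-access, so this module generates tables with
the same structure to serve as ground truth: demographic variables drawn from
target marginals, and the four cardiometabolic risk factors (BMI < 25,
hypertension, diabetes, smoking) drawn from logistic models in sex, ordinal
age score, household income and education, with intercepts calibrated so the
realized prevalences hit the published sex-specific targets.

The modified CANHEART index is the count of ideal states among non-smoking,
BMI < 25, no diabetes and no hypertension, ranging 0 (worst) to 4 (ideal
cardiovascular health).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .schema import (
    CATEGORICAL,
    CONTINUOUS,
    ORDINAL,
    HarmonizedSurveyTable,
    SchemaError,
    VariableSchema,
)

# --------------------------------------------------------------------------
# Harmonized variable list
# --------------------------------------------------------------------------

AGE_LEVELS = ("<20", "20-29", "30-39", "40-49", "50-59", "60-69", ">=70")
EDU_LEVELS = ("lt_secondary", "secondary", "post_secondary", "gt_post_secondary")
HH_LEVELS = ("1", "2", "3", "4", "5plus")
INCOME_LEVELS = ("low", "medium", "high")
MARITAL_LEVELS = ("single", "divorced_widowed", "married_commonlaw")
RISK_FACTORS = ("bmi_lt25", "hypertension", "diabetes", "smoking")
DEMOGRAPHICS = (
    "sex", "age_group", "marital_status", "household_size",
    "education", "income", "immigrant",
)


def harmonized_schema(continuous_bmi: bool = False) -> list:
    """Schema of the twelve harmonized variables (plus optional continuous BMI)."""
    schema = [
        VariableSchema("country", CATEGORICAL, ("CA", "AT")),
        VariableSchema("sex", CATEGORICAL, ("male", "female")),
        VariableSchema("age_group", ORDINAL, AGE_LEVELS, missing_allowed=True),
        VariableSchema("bmi_lt25", CATEGORICAL, ("no", "yes"), missing_allowed=True),
        VariableSchema("hypertension", CATEGORICAL, ("no", "yes"), missing_allowed=True),
        VariableSchema("diabetes", CATEGORICAL, ("no", "yes"), missing_allowed=True),
        VariableSchema("smoking", CATEGORICAL, ("no", "yes"), missing_allowed=True),
        VariableSchema("marital_status", CATEGORICAL, MARITAL_LEVELS, missing_allowed=True),
        VariableSchema("household_size", ORDINAL, HH_LEVELS, missing_allowed=True),
        VariableSchema("education", ORDINAL, EDU_LEVELS, missing_allowed=True),
        VariableSchema("income", ORDINAL, INCOME_LEVELS, missing_allowed=True),
        VariableSchema("immigrant", CATEGORICAL, ("no", "yes"), missing_allowed=True),
    ]
    if continuous_bmi:
        schema.append(VariableSchema("bmi", CONTINUOUS, missing_allowed=True))
    return schema


# --------------------------------------------------------------------------
# Country specification
# --------------------------------------------------------------------------

#: Default risk-factor dependence on covariates (log-odds per unit), shared by
#: the stock country specs. Age enters as the ordinal score 1-7 centred at 4,
#: income as 1-3 centred at 2, education as 1-4 centred at 2.5. Signs follow
#: the usual epidemiology: hypertension/diabetes rise with age and fall with
#: income/education; smoking falls with income/education; normal BMI (< 25)
#: is more common in the young and the more educated.
DEFAULT_EFFECT_LOGITS: dict = {
    "bmi_lt25": {"age": -0.28, "income": 0.05, "education": 0.15},
    "hypertension": {"age": 0.75, "income": -0.12, "education": -0.08},
    "diabetes": {"age": 0.60, "income": -0.20, "education": -0.12},
    "smoking": {"age": -0.10, "income": -0.22, "education": -0.30},
}


@dataclass
class CountrySpec:
    """Target structure for one simulated country.

    ``marginals`` maps demographic variables to level->proportion dicts and
    each risk factor to either an overall prevalence or a
    ``{"male": p, "female": p}`` pair (intercepts are calibrated per sex so
    realized prevalences match). ``effect_logits`` holds the per-risk-factor
    covariate coefficients; ``missing_rates`` the per-variable MCAR
    nonresponse probability.
    """

    country: str
    n: int
    marginals: dict
    effect_logits: dict = field(default_factory=lambda: DEFAULT_EFFECT_LOGITS)
    missing_rates: dict = field(default_factory=dict)
    continuous_bmi: bool = False

    def validate(self) -> None:
        if self.n < 1:
            raise SchemaError("CountrySpec.n must be >= 1")
        for var in DEMOGRAPHICS:
            probs = self.marginals.get(var)
            if probs is None:
                raise SchemaError(f"marginal missing for variable {var!r}")
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any():
                raise SchemaError(f"negative marginal proportion for variable {var!r}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise SchemaError(
                    f"marginal for variable {var!r} sums to {vals.sum():.6f}, not 1"
                )
        for var in RISK_FACTORS:
            tgt = self.marginals.get(var)
            if tgt is None:
                raise SchemaError(f"marginal missing for risk factor {var!r}")
            vals = tgt.values() if isinstance(tgt, Mapping) else [tgt]
            for p in vals:
                if not (0.0 <= p <= 1.0):
                    raise SchemaError(f"risk-factor prevalence for {var!r} outside [0,1]")
        for var, r in self.missing_rates.items():
            if not (0.0 <= r < 1.0):
                raise SchemaError(f"missing rate for {var!r} outside [0,1)")


def _norm(d: dict) -> dict:
    """Normalize printed percentages (which round to one decimal) to proportions."""
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


def canada_like(n: int = 20_000, continuous_bmi: bool = False) -> CountrySpec:
    """Stock spec anchored to the Canadian survey's published marginals."""
    marginals = {
        "sex": {"male": 0.447, "female": 0.553},
        "age_group": _norm(dict(zip(AGE_LEVELS, (10.2, 10.5, 11.2, 10.4, 17.0, 20.0, 20.8)))),
        "marital_status": _norm(dict(zip(MARITAL_LEVELS, (28.1, 20.9, 51.0)))),
        "household_size": _norm(dict(zip(HH_LEVELS, (27.8, 39.4, 13.1, 12.9, 6.9)))),
        "education": _norm(dict(zip(EDU_LEVELS, (24.1, 19.6, 4.7, 51.6)))),
        "income": _norm(dict(zip(INCOME_LEVELS, (10.2, 39.7, 50.1)))),
        "immigrant": {"no": 0.856, "yes": 0.144},
        "bmi_lt25": {"male": 0.392, "female": 0.506},
        "hypertension": {"male": 0.242, "female": 0.251},
        "diabetes": {"male": 0.103, "female": 0.085},
        "smoking": {"male": 0.203, "female": 0.163},
    }
    missing = {
        "bmi_lt25": 0.0673, "hypertension": 0.0034, "diabetes": 0.0014,
        "smoking": 0.0087, "marital_status": 0.0020, "household_size": 0.0006,
        "education": 0.0161, "income": 0.0010, "immigrant": 0.0323,
    }
    if continuous_bmi:
        missing["bmi"] = missing["bmi_lt25"]
    return CountrySpec("CA", n, marginals, missing_rates=missing,
                       continuous_bmi=continuous_bmi)


def austria_like(n: int = 5_000, continuous_bmi: bool = False) -> CountrySpec:
    """Stock spec anchored to the Austrian survey's published marginals."""
    marginals = {
        "sex": {"male": 0.443, "female": 0.557},
        "age_group": _norm(dict(zip(AGE_LEVELS, (3.5, 12.1, 16.3, 22.2, 22.2, 14.1, 9.4)))),
        "marital_status": _norm(dict(zip(MARITAL_LEVELS, (30.3, 15.0, 54.7)))),
        "household_size": _norm(dict(zip(HH_LEVELS, (15.0, 37.1, 20.7, 18.7, 8.6)))),
        "education": _norm(dict(zip(EDU_LEVELS, (15.6, 52.1, 20.0, 12.3)))),
        "income": _norm(dict(zip(INCOME_LEVELS, (36.0, 21.1, 42.9)))),
        "immigrant": {"no": 0.913, "yes": 0.087},
        "bmi_lt25": {"male": 0.428, "female": 0.616},
        "hypertension": {"male": 0.214, "female": 0.189},
        "diabetes": {"male": 0.051, "female": 0.037},
        "smoking": {"male": 0.440, "female": 0.315},
    }
    missing = {
        "age_group": 0.0063, "smoking": 0.2249,
    }
    if continuous_bmi:
        missing["bmi"] = 0.0
    return CountrySpec("AT", n, marginals, missing_rates=missing,
                       continuous_bmi=continuous_bmi)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _draw_categorical(rng, levels, probs, n):
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) == target."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    f = lambda a: expit(a + eta).mean() - target
    return brentq(f, -30.0, 30.0, xtol=1e-12)


def simulate_country(spec: CountrySpec, seed: int) -> HarmonizedSurveyTable:
    """Draw one country's harmonized survey table.

    Demographics are independent draws from the spec marginals; each risk
    factor follows a logistic model in sex, age score, income and education
    with sex-specific intercept calibration; missingness is applied MCAR per
    variable. Identical seeds give bit-identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n
    schema = harmonized_schema(spec.continuous_bmi)
    cols: dict = {"country": np.full(n, spec.country, dtype=object)}

    for var in DEMOGRAPHICS:
        probs = spec.marginals[var]
        levels = list(probs.keys())
        p = np.array([probs[l] for l in levels], dtype=float)
        cols[var] = _draw_categorical(rng, levels, p, n)

    female = (cols["sex"] == "female").astype(float)
    age_sc = pd.Series(cols["age_group"]).map(
        dict(zip(AGE_LEVELS, range(1, 8)))).to_numpy(float)
    inc_sc = pd.Series(cols["income"]).map(
        dict(zip(INCOME_LEVELS, range(1, 4)))).to_numpy(float)
    edu_sc = pd.Series(cols["education"]).map(
        dict(zip(EDU_LEVELS, range(1, 5)))).to_numpy(float)

    for var in RISK_FACTORS:
        beta = spec.effect_logits.get(var, {})
        eta = (
            beta.get("age", 0.0) * (age_sc - 4.0)
            + beta.get("income", 0.0) * (inc_sc - 2.0)
            + beta.get("education", 0.0) * (edu_sc - 2.5)
            + beta.get("country", 0.0)
        )
        target = spec.marginals[var]
        prob = np.empty(n)
        if isinstance(target, Mapping):
            # separate intercepts per sex reproduce both published prevalences
            for sex_val, is_female in (("male", 0.0), ("female", 1.0)):
                mask = female == is_female
                if mask.any():
                    a = _calibrate_intercept(eta[mask], float(target[sex_val]))
                    prob[mask] = expit(a + eta[mask])
        else:
            eta = eta + beta.get("sex", 0.0) * female
            a = _calibrate_intercept(eta, float(target))
            prob = expit(a + eta)
        draw = rng.random(n) < prob
        cols[var] = np.where(draw, "yes", "no").astype(object)

    if spec.continuous_bmi:
        # continuous BMI consistent with the binary indicator: truncated
        # normals on either side of 25 kg/m^2
        lt = cols["bmi_lt25"] == "yes"
        z = np.abs(rng.standard_normal(n))
        bmi = np.where(lt, 25.0 - 0.9 - 2.6 * z, 25.0 + 0.9 + 3.4 * z)
        cols["bmi"] = np.round(bmi, 2)

    df = pd.DataFrame(cols, columns=[v.name for v in schema])

    for var, rate in spec.missing_rates.items():
        if rate <= 0.0 or var not in df.columns:
            continue
        mask = rng.random(n) < rate
        if mask.any():
            df[var] = df[var].astype(object)
            df.loc[mask, var] = np.nan
    return HarmonizedSurveyTable(schema, df)


# --------------------------------------------------------------------------
# Modified CANHEART index
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CanheartIndex:
    """Count of ideal cardiovascular-health metrics, 0 (worst) to 4 (ideal)."""

    value: int

    def __post_init__(self):
        if self.value not in (0, 1, 2, 3, 4):
            raise ValueError(f"CANHEART index outside 0..4: {self.value}")


def compute_canheart(row) -> Optional[CanheartIndex]:
    """Modified CANHEART index of one respondent record.

    Ideal metrics: non-smoker, BMI < 25, no diabetes, no hypertension.
    Returns None when any component is missing (the row is then excluded
    from outcome models rather than raising).
    """
    if "bmi_lt25" in row and not pd.isna(row["bmi_lt25"]):
        bmi_ideal = row["bmi_lt25"] == "yes"
    elif "bmi" in row and not pd.isna(row["bmi"]):
        bmi_ideal = float(row["bmi"]) < 25.0
    else:
        return None
    score = int(bmi_ideal)
    for var in ("smoking", "diabetes", "hypertension"):
        val = row.get(var) if hasattr(row, "get") else row[var]
        if pd.isna(val):
            return None
        score += int(val == "no")
    return CanheartIndex(score)


def canheart_scores(table: HarmonizedSurveyTable) -> pd.Series:
    """Vectorized CANHEART index over a table; NaN where a component is missing."""
    df = table.data
    if "bmi_lt25" in df.columns:
        bmi_ok = df["bmi_lt25"].map({"yes": 1.0, "no": 0.0})
    else:
        bmi_ok = (pd.to_numeric(df["bmi"]) < 25.0).astype(float).where(df["bmi"].notna())
    parts = [bmi_ok]
    for var in ("smoking", "diabetes", "hypertension"):
        parts.append(df[var].map({"no": 1.0, "yes": 0.0}))
    return sum(parts)


# --------------------------------------------------------------------------
# Member / holdout split (feeds the membership-disclosure attack)
# --------------------------------------------------------------------------

def split_members_holdout(table: HarmonizedSurveyTable, fraction: float, seed: int):
    """Partition rows into a member table and a holdout table.

    ``fraction`` of rows (floored, clamped so both parts are non-empty) become
    members. The partition is disjoint, exhaustive, and seed-reproducible.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    n = table.n
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = min(max(int(np.floor(fraction * n)), 1), n - 1)
    members = table.data.iloc[np.sort(perm[:k])].reset_index(drop=True)
    holdout = table.data.iloc[np.sort(perm[k:])].reset_index(drop=True)
    return (
        HarmonizedSurveyTable(table.schema, members),
        HarmonizedSurveyTable(table.schema, holdout),
    )
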