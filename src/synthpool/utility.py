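"""Utility surface of pooled partially synthetic data.

Two views, mirroring how synthetic-data utility is judged in practice:

* covariate balance — standardized mean differences (SMD) between each
  pooled synthetic+real dataset and the ground-truth pooled dataset,
  averaged across replicates, with 0.1 as the conventional imbalance flag;
* analytic concordance — per-coefficient agreement (sign, significance at
  p < 0.05, CI overlap) between the combined pooled-synthetic regression and
  the exact federated fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .federated import OlsFit
from .schema import CONTINUOUS, HarmonizedSurveyTable, VariableSchema

SMD_FLAG_THRESHOLD = 0.1


class UtilityError(ValueError):
    pass


# --------------------------------------------------------------------------
# Standardized mean difference
# --------------------------------------------------------------------------

def _proportions(values: pd.Series, levels) -> np.ndarray:
    counts = values.value_counts()
    total = counts.sum()
    return np.array([counts.get(l, 0) / total for l in levels], dtype=float)


def smd(sample_a, sample_b, variable: VariableSchema) -> float:
    """Standardized mean difference between two samples of one variable.

    Continuous and ordinal variables use |m_a - m_b| / sqrt((s_a^2+s_b^2)/2)
    (ordinal levels enter through their numeric codes). Binary variables use
    the same with p(1-p) variances. Multi-level categorical variables use the
    multivariate Mahalanobis-type SMD over the level-proportion vectors (one
    level omitted; average multinomial covariance), giving a single value per
    variable.
    """
    a = pd.Series(sample_a).dropna()
    b = pd.Series(sample_b).dropna()
    if len(a) < 2 or len(b) < 2:
        raise UtilityError(f"{variable.name}: need >= 2 non-missing values per sample")

    if variable.kind == CONTINUOUS or variable.kind == "ordinal":
        if variable.kind == "ordinal":
            mapping = dict(zip(variable.levels, variable.codes))
            a = a.map(mapping).astype(float)
            b = b.map(mapping).astype(float)
        else:
            a = pd.to_numeric(a)
            b = pd.to_numeric(b)
        ma, mb = a.mean(), b.mean()
        pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
        if pooled <= 0:
            if np.isclose(ma, mb):
                return 0.0
            warnings.warn(f"{variable.name}: zero pooled variance with unequal means")
            return float("inf")
        return float(abs(ma - mb) / np.sqrt(pooled))

    levels = list(variable.levels)
    if len(levels) == 2:
        pa = float((a == levels[1]).mean())
        pb = float((b == levels[1]).mean())
        pooled = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
        if pooled <= 0:
            if np.isclose(pa, pb):
                return 0.0
            warnings.warn(f"{variable.name}: zero pooled variance with unequal means")
            return float("inf")
        return float(abs(pa - pb) / np.sqrt(pooled))

    # multi-level: Mahalanobis distance of proportion vectors (drop last level)
    pa = _proportions(a, levels)[:-1]
    pb = _proportions(b, levels)[:-1]
    diff = pa - pb
    cov_a = np.diag(pa) - np.outer(pa, pa)
    cov_b = np.diag(pb) - np.outer(pb, pb)
    S = (cov_a + cov_b) / 2.0
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError:
        if np.allclose(diff, 0):
            return 0.0
        warnings.warn(f"{variable.name}: singular proportion covariance")
        sol = np.linalg.pinv(S) @ diff
    return float(np.sqrt(max(diff @ sol, 0.0)))


def smd_per_level_max(sample_a, sample_b, variable: VariableSchema) -> float:
    """Optional per-level view: max binary SMD over a categorical's levels."""
    a = pd.Series(sample_a).dropna()
    b = pd.Series(sample_b).dropna()
    out = 0.0
    for level in variable.levels:
        bin_schema = VariableSchema(variable.name, "categorical", ("other", level))
        out = max(out, smd(a.where(a == level, "other"),
                           b.where(b == level, "other"), bin_schema))
    return out


@dataclass
class SmdReport:
    """Per-variable SMDs per replicate with replicate means and 0.1 flags."""

    per_replicate: pd.DataFrame  # columns: replicate, stratum, variable, smd
    summary: pd.DataFrame        # index (stratum, variable): mean_smd, flagged

    @property
    def any_flagged(self) -> bool:
        return bool(self.summary["flagged"].any())


def smd_report(oracle_pooled: HarmonizedSurveyTable, replicate_pooled,
               variables=None, by_sex: bool = True) -> SmdReport:
    """SMD balance of each pooled replicate against the ground-truth pool.

    ``replicate_pooled`` is the list of pooled (synthetic + real partner)
    tables. SMDs are computed per replicate and averaged — overall and,
    optionally, within sex strata. Mean SMDs above 0.1 are flagged as
    potentially clinically important imbalance.
    """
    if variables is None:
        variables = [v.name for v in oracle_pooled.schema
                     if v.name not in ("country",)]
    schema_map = {v.name: v for v in oracle_pooled.schema}
    strata = {"overall": None}
    if by_sex:
        strata.update({"male": "male", "female": "female"})

    rows = []
    for i, rep in enumerate(replicate_pooled):
        for stratum, sex_val in strata.items():
            if sex_val is None:
                odf, rdf = oracle_pooled.data, rep.data
            else:
                odf = oracle_pooled.data[oracle_pooled.data["sex"] == sex_val]
                rdf = rep.data[rep.data["sex"] == sex_val]
            for name in variables:
                if sex_val is not None and name == "sex":
                    continue
                val = smd(rdf[name], odf[name], schema_map[name])
                rows.append({"replicate": i, "stratum": stratum,
                             "variable": name, "smd": val})
    per_rep = pd.DataFrame(rows)
    summary = (per_rep.groupby(["stratum", "variable"])["smd"].mean()
               .rename("mean_smd").to_frame())
    summary["flagged"] = summary["mean_smd"] > SMD_FLAG_THRESHOLD
    return SmdReport(per_rep, summary)


# --------------------------------------------------------------------------
# Regression-conclusion concordance
# --------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Per-coefficient concordance between the oracle and the combined fit."""

    table: pd.DataFrame          # index: coefficient
    r2_oracle: float = float("nan")
    r2_pooled: float = float("nan")

    @property
    def n_coefficients(self) -> int:
        return len(self.table)

    @property
    def sign_agreement_rate(self) -> float:
        return float(self.table["sign_agree"].mean())

    @property
    def significance_agreement_rate(self) -> float:
        return float(self.table["significance_agree"].mean())

    @property
    def ci_overlap_rate(self) -> float:
        return float(self.table["ci_overlap"].mean())


def compare_fits(oracle: OlsFit, combined: pd.DataFrame,
                 r2_pooled: float = float("nan"),
                 include_intercept: bool = False) -> ComparisonReport:
    """Compare the federated oracle fit with a combined pooled-synthetic fit.

    ``combined`` is the coefficient table produced by
    :func:`synthpool.combining.combine_model`. Per coefficient: sign
    agreement (same sign, or both CIs containing 0), significance agreement
    at p < 0.05, and CI overlap.
    """
    oracle_tab = oracle.table()
    if not include_intercept:
        oracle_tab = oracle_tab.drop(index="intercept", errors="ignore")
        combined = combined.drop(index="intercept", errors="ignore")
    missing = set(oracle_tab.index) ^ set(combined.index)
    if missing:
        raise UtilityError(f"coefficient-name mismatch between fits: {sorted(missing)}")
    combined = combined.loc[oracle_tab.index]

    rows = []
    for name in oracle_tab.index:
        o = oracle_tab.loc[name]
        c = combined.loc[name]
        o_zero = o["ci_low"] <= 0.0 <= o["ci_high"]
        c_zero = c["ci_low"] <= 0.0 <= c["ci_high"]
        sign_agree = bool(np.sign(o["estimate"]) == np.sign(c["estimate"])
                          or (o_zero and c_zero))
        sig_agree = bool(o["significant"] == c["significant"])
        overlap = bool(o["ci_low"] <= c["ci_high"] and c["ci_low"] <= o["ci_high"])
        rows.append({
            "coefficient": name,
            "oracle_estimate": o["estimate"], "oracle_ci_low": o["ci_low"],
            "oracle_ci_high": o["ci_high"], "oracle_significant": o["significant"],
            "pooled_estimate": c["estimate"], "pooled_ci_low": c["ci_low"],
            "pooled_ci_high": c["ci_high"], "pooled_significant": c["significant"],
            "sign_agree": sign_agree, "significance_agree": sig_agree,
            "ci_overlap": overlap,
        })
    table = pd.DataFrame(rows).set_index("coefficient")
    return ComparisonReport(table, r2_oracle=oracle.r2, r2_pooled=r2_pooled)
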