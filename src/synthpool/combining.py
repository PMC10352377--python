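"""Partial-synthesis combining rules.

With m synthetic replicates, an analysis run on each replicate yields
estimates q_i with variances v_i. For partially synthetic data the combined
inference uses

    q_bar = mean(q_i)
    v_bar = mean(v_i)
    b_m   = sum((q_i - q_bar)^2) / (m - 1)      (between-replicate variance)
    T_p   = b_m / m + v_bar                      (adjusted total variance)

with a large-sample 95% CI of q_bar +/- 1.96 * sqrt(T_p) and a normal
reference p-value. These rules account for the extra variability introduced
by the synthesis step; they are not the fully-synthetic-data rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

Z95 = 1.96  # large-sample multiplier, as printed in the tables


class CombiningError(ValueError):
    pass


@dataclass
class EstimateSet:
    """Per-replicate estimates q_i and variances v_i of one coefficient."""

    name: str
    q: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.q.shape != self.v.shape or self.q.ndim != 1:
            raise CombiningError(f"{self.name}: q and v must be equal-length 1-D")
        if self.m < 1:
            raise CombiningError(f"{self.name}: need at least one replicate")
        if (self.v < 0).any():
            raise CombiningError(f"{self.name}: negative variance v_i")

    @property
    def m(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class CombinedEstimate:
    """One coefficient's combined inference across m replicates."""

    name: str
    q_bar: float
    v_bar: float
    b_m: float
    t_p: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int

    @property
    def significant(self) -> bool:
        """Flagged at p < 0.05 (uncorrected, the tables' convention)."""
        return self.p_value < 0.05


def combine(e: EstimateSet) -> CombinedEstimate:
    """Combine one coefficient's per-replicate estimates.

    Requires m >= 2; with a single replicate there is no between-replicate
    variance and the caller should use ordinary single-dataset inference.
    """
    if e.m < 2:
        raise CombiningError(
            f"{e.name}: m = 1 gives no between-replicate variance; "
            "use single-dataset inference instead"
        )
    q_bar = float(e.q.mean())
    v_bar = float(e.v.mean())
    b_m = float(np.sum((e.q - q_bar) ** 2) / (e.m - 1))
    t_p = b_m / e.m + v_bar
    half = Z95 * np.sqrt(t_p)
    if t_p > 0:
        p = 2.0 * float(norm.sf(abs(q_bar) / np.sqrt(t_p)))
    else:
        p = 0.0 if q_bar != 0 else 1.0
    return CombinedEstimate(
        name=e.name, q_bar=q_bar, v_bar=v_bar, b_m=b_m, t_p=t_p,
        ci_low=q_bar - half, ci_high=q_bar + half, p_value=p, m=e.m,
    )


def combine_model(estimate_sets) -> pd.DataFrame:
    """Combine every coefficient of one regression; one row per coefficient.

    All sets must share the same replicate count m. Returns a DataFrame with
    columns (coefficient, estimate, v_bar, b_m, t_p, ci_low, ci_high,
    p_value, significant) mirroring the published table layout.
    """
    sets = list(estimate_sets)
    if not sets:
        raise CombiningError("no coefficients to combine")
    ms = {e.m for e in sets}
    if len(ms) > 1:
        raise CombiningError(f"replicate counts differ across coefficients: {sorted(ms)}")
    rows = []
    for e in sets:
        c = combine(e)
        rows.append({
            "coefficient": c.name, "estimate": c.q_bar, "v_bar": c.v_bar,
            "b_m": c.b_m, "t_p": c.t_p, "ci_low": c.ci_low,
            "ci_high": c.ci_high, "p_value": c.p_value,
            "significant": c.significant,
        })
    return pd.DataFrame(rows).set_index("coefficient")
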