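"""Membership-disclosure attack on synthetic data (relative F1).

The adversary holds a set of target records — some were in the synthesis
training data (members), some were not — plus the released synthetic table.
For each target the distance to its nearest synthetic record is the mean
per-variable distance over the quasi-identifiers (categorical: 0/1 mismatch;
continuous: absolute difference scaled by the synthetic range, capped at 1).
Targets within threshold h are predicted members. By default the adversary
is given their best case: the attack F1 is maximized over all achievable
thresholds (h = None, "adaptive"); a fixed h in [0, 1] may be configured
instead, with h = 0 the strict exact-match attack. The attack F1 is
compared with the naive baseline that predicts every target a member
(F1 = 2t/(1+t) at member fraction t): relative F1 = F1 - naive F1. Values
near 0 mean the synthetic data gives even the best-threshold adversary
essentially nothing beyond the base rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .schema import CONTINUOUS, HarmonizedSurveyTable

#: demographic quasi-identifiers assumed known to the adversary
DEFAULT_QUASI_IDENTIFIERS = (
    "sex", "age_group", "marital_status", "household_size",
    "education", "income", "immigrant",
)


class AttackError(ValueError):
    pass


@dataclass(frozen=True)
class AttackConfig:
    """Attack parameters.

    ``h`` is the mean-distance acceptance threshold in [0, 1]; h = 0 demands
    an exact quasi-identifier match, and h = None (default) lets the
    adversary pick the F1-maximizing threshold. ``member_share`` is the
    assumed member fraction of the target mix, used only when callers build
    target sets through pipeline helpers.
    """

    quasi_identifiers: tuple = DEFAULT_QUASI_IDENTIFIERS
    h: float | None = None
    member_share: float = 0.5

    def __post_init__(self):
        if self.h is not None and not (0.0 <= self.h <= 1.0):
            raise AttackError(f"threshold h must be in [0,1], got {self.h}")
        if not self.quasi_identifiers:
            raise AttackError("at least one quasi-identifier is required")


@dataclass
class MembershipAttackResult:
    """Attack metrics, per synthetic replicate and averaged."""

    precision: float
    recall: float
    f1: float
    naive_f1: float
    relative_f1: float
    per_replicate: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "naive_f1": self.naive_f1,
            "relative_f1": self.relative_f1,
            "per_replicate": (
                self.per_replicate.to_dict(orient="records")
                if self.per_replicate is not None else None),
        }


def _columns_matrix(df: pd.DataFrame, schema_map, qis):
    """Split quasi-identifiers into categorical vs continuous names."""
    cats, conts = [], []
    for q in qis:
        if schema_map[q].kind == CONTINUOUS:
            conts.append(q)
        else:
            cats.append(q)
    return cats, conts


def _cat_codes(series: pd.Series, levels) -> np.ndarray:
    """Integer codes with missing as its own code (missing matches missing)."""
    c = pd.Categorical(series, categories=levels)
    codes = c.codes.astype(np.int16)  # -1 = missing
    return codes


def _min_distances(targets: pd.DataFrame, synthetic: pd.DataFrame,
                   cats, conts, schema_map, ranges, chunk: int = 256
                   ) -> np.ndarray:
    """Nearest-synthetic-record mean distance for every target row."""
    k = len(cats) + len(conts)
    if cats:
        levels = {q: list(schema_map[q].levels) for q in cats}
        T = np.column_stack([_cat_codes(targets[q], levels[q]) for q in cats])
        S = np.column_stack([_cat_codes(synthetic[q], levels[q]) for q in cats])
    t_con = {q: pd.to_numeric(targets[q]).to_numpy(float) for q in conts}
    s_con = {q: pd.to_numeric(synthetic[q]).to_numpy(float) for q in conts}
    out = np.empty(len(targets))
    for start in range(0, len(targets), chunk):
        stop = min(start + chunk, len(targets))
        b = stop - start
        dist = np.zeros((b, len(synthetic)), dtype=np.float32)
        if cats:
            dist += (T[start:stop, None, :] != S[None, :, :]).sum(axis=2)
        for q in conts:
            tv = t_con[q][start:stop, None]
            sv = s_con[q][None, :]
            d = np.abs(tv - sv) / ranges[q] if ranges[q] > 0 else np.abs(tv - sv)
            both_na = np.isnan(tv) & np.isnan(sv)
            d = np.where(both_na, 0.0, np.minimum(np.nan_to_num(d, nan=1.0), 1.0))
            dist += d
        out[start:stop] = dist.min(axis=1) / k
    return out


def _best_threshold(dmin: np.ndarray, truth: np.ndarray):
    """F1-maximizing acceptance threshold (ties broken toward the smallest)."""
    candidates = np.unique(np.concatenate([dmin, [1.0]]))
    best = (0.0, -1.0)  # (threshold, f1)
    for h in candidates:
        _, _, f1 = _prf(dmin <= h + 1e-12, truth)
        if f1 > best[1] + 1e-15:
            best = (float(h), f1)
    return best


def _exact_match_member(targets: pd.DataFrame, synthetic: pd.DataFrame, qis):
    """Fast path for h = 0: exact quasi-identifier tuple membership."""
    syn_keys = set(map(tuple, synthetic[list(qis)].astype(object)
                       .where(synthetic[list(qis)].notna(), "\x00NA").to_numpy()))
    tgt = targets[list(qis)].astype(object).where(
        targets[list(qis)].notna(), "\x00NA").to_numpy()
    return np.fromiter((tuple(r) in syn_keys for r in tgt), dtype=bool,
                       count=len(tgt))


def _prf(pred: np.ndarray, truth: np.ndarray):
    tp = float(np.sum(pred & truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def attack(members: HarmonizedSurveyTable,
           non_members: HarmonizedSurveyTable,
           synthetic, cfg: AttackConfig = AttackConfig()) -> MembershipAttackResult:
    """Run the membership-disclosure attack.

    ``synthetic`` may be a single table or a sequence of replicate tables; in
    the latter case the attack runs per replicate and the reported metrics
    are means across replicates.
    """
    replicates = synthetic if isinstance(synthetic, (list, tuple)) else [synthetic]
    if not replicates:
        raise AttackError("no synthetic table supplied")
    for rep in replicates:
        if rep.n == 0:
            raise AttackError("synthetic table is empty")
    schema_map = {v.name: v for v in members.schema}
    qis = tuple(cfg.quasi_identifiers)
    unknown = [q for q in qis if q not in schema_map]
    if unknown:
        raise AttackError(f"quasi-identifiers not in schema: {unknown}")

    targets = pd.concat([members.data, non_members.data], ignore_index=True)
    truth = np.concatenate([
        np.ones(members.n, dtype=bool), np.zeros(non_members.n, dtype=bool)])
    t = truth.mean()
    naive_f1 = 2 * t / (1 + t)  # predict-everyone-a-member baseline

    cats, conts = _columns_matrix(targets, schema_map, qis)
    rows = []
    for i, rep in enumerate(replicates):
        syn = rep.data
        if cfg.h == 0.0 and not conts:
            pred = _exact_match_member(targets, syn, qis)
            h_used = 0.0
        else:
            ranges = {}
            for q in conts:
                vals = pd.to_numeric(syn[q]).dropna()
                ranges[q] = float(vals.max() - vals.min()) if len(vals) else 1.0
            dmin = _min_distances(targets, syn, cats, conts, schema_map, ranges)
            if cfg.h is None:
                h_used, _ = _best_threshold(dmin, truth)
            else:
                h_used = cfg.h
            pred = dmin <= h_used + 1e-12
        precision, recall, f1 = _prf(pred, truth)
        rows.append({"replicate": i, "threshold": h_used,
                     "precision": precision, "recall": recall,
                     "f1": f1, "naive_f1": naive_f1,
                     "relative_f1": f1 - naive_f1})
    per_rep = pd.DataFrame(rows)
    mean = per_rep[["precision", "recall", "f1", "naive_f1", "relative_f1"]].mean()
    return MembershipAttackResult(
        precision=float(mean["precision"]), recall=float(mean["recall"]),
        f1=float(mean["f1"]), naive_f1=float(mean["naive_f1"]),
        relative_f1=float(mean["relative_f1"]), per_replicate=per_rep,
    )
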