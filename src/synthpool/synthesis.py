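"""Sequential boosted-tree synthesis of harmonized survey tables.

Variables are synthesized one at a time in a fixed order; each variable's
conditional distribution given the variables earlier in the sequence is
learned by a gradient boosted decision tree (LightGBM). Categorical
conditionals are classifiers trained with inverse-frequency class weights
and corrected by beta calibration fitted on out-of-fold predictions;
synthetic values are drawn from the calibrated class probabilities.
Continuous variables are mapped to normal scores (empirical CDF with the
rank/(n+1) convention, then the standard-normal quantile), modelled by a
regressor on that scale, sampled as point prediction plus a bootstrap draw
from the out-of-fold residual pool, and back-transformed. Missing values are
synthesized explicitly (an extra category level, or an indicator for
continuous variables) and restored to empty cells on output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.metrics import log_loss
from sklearn.model_selection import KFold, StratifiedKFold

from .calibration import IDENTITY_MAP, BetaCalibrationMap, apply_calibration, fit_beta_calibration
from .schema import CONTINUOUS, HarmonizedSurveyTable, SchemaError, VariableSchema
from .tuning import TuningConfig, minimize

logger = logging.getLogger("synthpool")

MISSING_LEVEL = "(missing)"


class SynthesisError(ValueError):
    pass


class DegenerateVariableError(SynthesisError):
    """Fewer than 2 distinct values: synthesize as a constant instead."""


# --------------------------------------------------------------------------
# Normal-score transform
# --------------------------------------------------------------------------

@dataclass
class NormalScoreTransform:
    """Empirical-CDF / standard-normal-quantile transform for one variable.

    Forward: z = ndtri(F(x)) with F the empirical CDF under the rank/(n+1)
    convention (average ranks for ties), so scores stay finite. Inverse:
    x = F^{-1}(ndtr(z)) with linear interpolation between support points,
    clipped to the observed training range. The round trip is the identity
    on the training support.
    """

    support: np.ndarray  # sorted training values
    probs: np.ndarray    # (1..n)/(n+1), strictly increasing in (0,1)

    @classmethod
    def fit(cls, values) -> "NormalScoreTransform":
        vals = np.asarray(values, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2 or len(np.unique(vals)) < 2:
            raise DegenerateVariableError(
                "normal-score transform needs >= 2 distinct finite values")
        support = np.sort(vals)
        n = len(support)
        probs = np.arange(1, n + 1) / (n + 1)
        return cls(support=support, probs=probs)

    def _ecdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        n = len(self.support)
        lo = np.searchsorted(self.support, x, side="left")
        hi = np.searchsorted(self.support, x, side="right")
        # average rank for ties; clip off-support points into (0,1)
        rank = (lo + hi + 1) / 2.0
        return np.clip(rank / (n + 1), 1.0 / (n + 1), n / (n + 1))

    def forward(self, x) -> np.ndarray:
        """Monotone map to the normal scale."""
        return ndtri(self._ecdf(x))

    def inverse(self, z) -> np.ndarray:
        """Back to the original scale; clips to the training min/max."""
        p = ndtr(np.asarray(z, dtype=float))
        return np.interp(p, self.probs, self.support)


def normal_score_forward(values) -> np.ndarray:
    """Fit-and-apply convenience: normal scores of one continuous sample."""
    return NormalScoreTransform.fit(values).forward(values)


def normal_score_inverse(transformed, t: NormalScoreTransform) -> np.ndarray:
    return t.inverse(transformed)


# --------------------------------------------------------------------------
# Internal representation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _IVar:
    """One internal synthesis variable (a schema variable or its missing flag)."""

    name: str
    kind: str        # 'cat' | 'num'
    levels: tuple    # category levels incl. the explicit missing level
    source: str      # schema variable it belongs to
    role: str        # 'value' | 'miss'


@dataclass(frozen=True)
class SynthesisOrder:
    """Permutation of the schema's synthesizable variables."""

    names: tuple

    @classmethod
    def for_table(cls, table: HarmonizedSurveyTable, names=None) -> "SynthesisOrder":
        all_names = table.variable_names
        if names is None:
            names = all_names
        names = list(names)
        if sorted(names) != sorted(all_names):
            raise SynthesisError(
                f"order must be a permutation of {sorted(all_names)}")
        return cls(tuple(names))


def _encode_frame(table: HarmonizedSurveyTable, order: SynthesisOrder):
    """Training table -> internal frame (categoricals with explicit missing
    level; continuous as normal scores with 0-imputation plus a missing
    indicator). Degenerate continuous variables stay untransformed."""
    frame = {}
    ivars = []
    transforms = {}
    for varname in order.names:
        v = table.schema_for(varname)
        col = table.data[varname]
        if v.kind == CONTINUOUS:
            isna = col.isna()
            if isna.any():
                iv = _IVar(f"{varname}__miss", "cat", ("obs", "mis"), varname, "miss")
                frame[iv.name] = pd.Categorical(
                    np.where(isna, "mis", "obs"), categories=list(iv.levels))
                ivars.append(iv)
            vals = col.to_numpy(float)
            try:
                t = NormalScoreTransform.fit(vals[~isna])
            except DegenerateVariableError:
                t = None
            transforms[varname] = t
            z = np.zeros(len(col))
            if t is not None:
                z[~isna.to_numpy()] = t.forward(vals[~isna])
            else:
                z[~isna.to_numpy()] = vals[~isna]
            frame[varname] = z
            ivars.append(_IVar(varname, "num", (), varname, "value"))
        else:
            levels = list(v.levels)
            vals = col
            if col.isna().any():
                levels = levels + [MISSING_LEVEL]
                vals = col.fillna(MISSING_LEVEL)
            frame[varname] = pd.Categorical(vals, categories=levels)
            ivars.append(_IVar(varname, "cat", tuple(levels), varname, "value"))
    return pd.DataFrame(frame), ivars, transforms


def _lgb_base_params(seed: int) -> dict:
    return {
        "verbosity": -1,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
        "seed": int(seed) % (2**31 - 1),
        "feature_pre_filter": False,
    }


def _train_params(hp: dict, kind: str, num_class: int, seed: int) -> dict:
    p = _lgb_base_params(seed)
    p.update({
        "learning_rate": hp["learning_rate"],
        "num_leaves": hp["num_leaves"],
        "min_data_in_leaf": hp["min_data_in_leaf"],
    })
    if kind == "classifier":
        if num_class == 2:
            p["objective"] = "binary"
        else:
            p["objective"] = "multiclass"
            p["num_class"] = num_class
    else:
        p["objective"] = "regression"
    return p


def _fit_booster(X, y, w, hp, kind, num_class, seed):
    cat_feats = [c for c in X.columns if isinstance(X[c].dtype, pd.CategoricalDtype)]
    ds = lgb.Dataset(X, label=y, weight=w, categorical_feature=cat_feats,
                     free_raw_data=True, params={"verbosity": -1})
    return lgb.train(_train_params(hp, kind, num_class, seed), ds,
                     num_boost_round=int(hp["num_boost_round"]))


def _predict_proba(booster, X, num_class):
    raw = booster.predict(X)
    if num_class == 2:
        raw = np.asarray(raw).reshape(-1)
        return np.column_stack([1.0 - raw, raw])
    return np.asarray(raw).reshape(len(X), num_class)


def _cv_oof(X, y, w, hp, kind, num_class, seed, n_splits=5):
    """Out-of-fold predictions under a fixed hyperparameter setting."""
    n = len(X)
    if kind == "classifier":
        counts = np.bincount(y, minlength=num_class)
        stratify = counts[counts > 0].min() >= n_splits
        splitter = (StratifiedKFold(n_splits, shuffle=True, random_state=seed)
                    if stratify else KFold(n_splits, shuffle=True, random_state=seed))
        oof = np.zeros((n, num_class))
    else:
        splitter = KFold(n_splits, shuffle=True, random_state=seed)
        oof = np.zeros(n)
    for k, (tr, te) in enumerate(splitter.split(X, y if kind == "classifier" else None)):
        booster = _fit_booster(X.iloc[tr], y[tr], None if w is None else w[tr],
                               hp, kind, num_class, seed + 7 * k)
        if kind == "classifier":
            oof[te] = _predict_proba(booster, X.iloc[te], num_class)
        else:
            oof[te] = booster.predict(X.iloc[te])
    return oof


# --------------------------------------------------------------------------
# Conditional models
# --------------------------------------------------------------------------

@dataclass
class ConditionalModel:
    """One step of the sequential model: target given its predecessors."""

    target: str
    predictors: tuple
    kind: str  # marginal_cat | marginal_num | constant_cat | constant_num | classifier | regressor
    levels: tuple = ()
    booster: Optional[lgb.Booster] = field(default=None, repr=False)
    calibration: list = field(default_factory=list)
    residuals: Optional[np.ndarray] = field(default=None, repr=False)
    marginal_probs: Optional[np.ndarray] = None
    pool: Optional[np.ndarray] = field(default=None, repr=False)
    constant: object = None
    present_levels: tuple = ()
    hyperparams: dict = field(default_factory=dict)
    cv_score: float = float("nan")

    def predict_proba(self, X) -> np.ndarray:
        """Calibrated class probabilities over ``present_levels`` (classifier)."""
        raw = _predict_proba(self.booster, X, len(self.present_levels))
        return apply_calibration(self.calibration, raw)


def _fit_conditional_frame(iv: _IVar, predictors, frame: pd.DataFrame,
                           config: TuningConfig, seed: int) -> ConditionalModel:
    y_col = frame[iv.name]
    n = len(frame)
    if n < config.min_rows:
        raise SynthesisError(
            f"{iv.name}: {n} rows is below the fitting floor of {config.min_rows}")
    X = frame[list(predictors)]

    if iv.kind == "cat":
        counts = y_col.value_counts()
        present = [l for l in iv.levels if counts.get(l, 0) > 0]
        if len(present) < 2:
            return ConditionalModel(iv.name, tuple(predictors), "constant_cat",
                                    levels=iv.levels, constant=present[0])
        codes = pd.Categorical(y_col, categories=present).codes.astype(int)
        num_class = len(present)
        # inverse-frequency weights: larger weights for the minority class
        freq = np.bincount(codes, minlength=num_class).astype(float)
        w = (n / (num_class * freq))[codes]
        kind = "classifier"
        y = codes
    else:
        y = y_col.to_numpy(float)
        if np.ptp(y) < 1e-12:
            return ConditionalModel(iv.name, tuple(predictors), "constant_num",
                                    constant=float(y[0]))
        w = None
        num_class = 0
        kind = "regressor"

    def objective(hp):
        oof = _cv_oof(X, y, w, hp, kind, num_class, seed)
        if kind == "classifier":
            return log_loss(y, np.clip(oof, 1e-9, 1.0), labels=list(range(num_class)))
        return float(np.mean((oof - y) ** 2))

    best_hp, best_score, _ = minimize(objective, config, seed)
    oof = _cv_oof(X, y, w, best_hp, kind, num_class, seed)
    booster = _fit_booster(X, y, w, best_hp, kind, num_class, seed)

    if kind == "classifier":
        maps = []
        for c in range(num_class):
            target_bin = (y == c).astype(int)
            try:
                maps.append(fit_beta_calibration(oof[:, c], target_bin))
            except ValueError:
                maps.append(IDENTITY_MAP)
        return ConditionalModel(
            iv.name, tuple(predictors), "classifier", levels=iv.levels,
            booster=booster, calibration=maps, present_levels=tuple(present),
            hyperparams=best_hp, cv_score=best_score)
    residuals = y - oof
    return ConditionalModel(
        iv.name, tuple(predictors), "regressor", booster=booster,
        residuals=residuals, hyperparams=best_hp, cv_score=best_score)


def _fit_marginal(iv: _IVar, frame: pd.DataFrame) -> ConditionalModel:
    col = frame[iv.name]
    if iv.kind == "cat":
        probs = col.value_counts(normalize=True).reindex(list(iv.levels)).fillna(0.0)
        return ConditionalModel(iv.name, (), "marginal_cat", levels=iv.levels,
                                marginal_probs=probs.to_numpy())
    vals = col.to_numpy(float)
    if np.ptp(vals) < 1e-12:
        return ConditionalModel(iv.name, (), "constant_num", constant=float(vals[0]))
    return ConditionalModel(iv.name, (), "marginal_num", pool=vals.copy())


def fit_conditional(target: str, predictors, data: HarmonizedSurveyTable,
                    config: TuningConfig = TuningConfig(), seed: int = 0
                    ) -> ConditionalModel:
    """Fit one conditional model on a harmonized table.

    Hyperparameters are selected by the sequential model-based search in
    :mod:`synthpool.tuning`, each candidate scored by five-fold cross
    validation (log-loss for categorical targets, squared error for
    normal-score continuous targets). Categorical models carry out-of-fold
    beta-calibration maps; continuous models carry the out-of-fold residual
    pool.
    """
    names = list(dict.fromkeys([*predictors, target]))
    sub_order = [n for n in data.variable_names if n in names]
    sub = HarmonizedSurveyTable(
        [data.schema_for(n) for n in sub_order], data.data[sub_order].copy())
    frame, ivars, _ = _encode_frame(sub, SynthesisOrder(tuple(sub_order)))
    pred_internal = [iv.name for iv in ivars if iv.source in predictors]
    target_iv = next(iv for iv in ivars if iv.source == target and iv.role == "value")
    return _fit_conditional_frame(target_iv, pred_internal, frame, config, seed)


# --------------------------------------------------------------------------
# The sequential model
# --------------------------------------------------------------------------

@dataclass
class SynthesisModel:
    """Ordered conditional models plus the transforms needed to decode."""

    order: SynthesisOrder
    ivars: list
    models: list                 # one ConditionalModel per internal variable
    transforms: dict             # schema var -> NormalScoreTransform | None
    schema: list
    n_train: int

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a single JSON archive (tree ensembles as text)."""
        def model_payload(m: ConditionalModel) -> dict:
            return {
                "target": m.target, "predictors": list(m.predictors),
                "kind": m.kind, "levels": list(m.levels),
                "booster": m.booster.model_to_string() if m.booster else None,
                "calibration": [c.to_tuple() for c in m.calibration],
                "residuals": None if m.residuals is None else m.residuals.tolist(),
                "marginal_probs": None if m.marginal_probs is None else m.marginal_probs.tolist(),
                "pool": None if m.pool is None else np.asarray(m.pool).tolist(),
                "constant": m.constant,
                "present_levels": list(m.present_levels),
                "hyperparams": m.hyperparams, "cv_score": m.cv_score,
            }
        payload = {
            "order": list(self.order.names),
            "ivars": [[iv.name, iv.kind, list(iv.levels), iv.source, iv.role]
                      for iv in self.ivars],
            "models": [model_payload(m) for m in self.models],
            "transforms": {
                k: (None if t is None else {"support": t.support.tolist()})
                for k, t in self.transforms.items()},
            "schema": [v.to_dict() for v in self.schema],
            "n_train": self.n_train,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SynthesisModel":
        d = json.loads(Path(path).read_text())
        ivars = [_IVar(n, k, tuple(lv), s, r) for n, k, lv, s, r in d["ivars"]]
        models = []
        for md in d["models"]:
            models.append(ConditionalModel(
                target=md["target"], predictors=tuple(md["predictors"]),
                kind=md["kind"], levels=tuple(md["levels"]),
                booster=(lgb.Booster(model_str=md["booster"])
                         if md["booster"] else None),
                calibration=[BetaCalibrationMap(*t) for t in md["calibration"]],
                residuals=(None if md["residuals"] is None
                           else np.asarray(md["residuals"])),
                marginal_probs=(None if md["marginal_probs"] is None
                                else np.asarray(md["marginal_probs"])),
                pool=None if md["pool"] is None else np.asarray(md["pool"]),
                constant=md["constant"],
                present_levels=tuple(md["present_levels"]),
                hyperparams=md["hyperparams"], cv_score=md["cv_score"]))
        transforms = {}
        for k, t in d["transforms"].items():
            if t is None:
                transforms[k] = None
            else:
                support = np.asarray(t["support"])
                n = len(support)
                transforms[k] = NormalScoreTransform(
                    support=support, probs=np.arange(1, n + 1) / (n + 1))
        schema = [VariableSchema.from_dict(v) for v in d["schema"]]
        return cls(SynthesisOrder(tuple(d["order"])), ivars, models,
                   transforms, schema, int(d["n_train"]))


@dataclass
class SyntheticReplicates:
    """m synthetic tables sharing schema and row count."""

    m: int
    tables: list

    def __post_init__(self):
        if self.m < 1 or len(self.tables) != self.m:
            raise SynthesisError("replicate count does not match table list")


def fit_sequential(data: HarmonizedSurveyTable, order=None,
                   config: TuningConfig = TuningConfig(), seed: int = 0
                   ) -> SynthesisModel:
    """Fit the full sequential generative model.

    The first variable in the order is stored as its empirical marginal;
    every later variable is fitted conditionally on all earlier ones.
    ``order`` may be a list of names, ``"auto"`` for the opt-in greedy
    predictability heuristic, or None for schema order.
    """
    if order == "auto":
        order = suggest_order(data, seed)
        logger.info("auto synthesis order: %s", order)
    so = order if isinstance(order, SynthesisOrder) else SynthesisOrder.for_table(data, order)
    frame, ivars, transforms = _encode_frame(data, so)
    models = []
    placed: list = []
    for iv in ivars:
        if not placed:
            models.append(_fit_marginal(iv, frame))
        else:
            try:
                models.append(_fit_conditional_frame(iv, placed, frame, config, seed))
            except SynthesisError as err:
                raise SynthesisError(f"while fitting {iv.name}: {err}") from err
        logger.info("fitted %s (%s)", iv.name, models[-1].kind)
        placed.append(iv.name)
    return SynthesisModel(so, ivars, models, transforms, list(data.schema), data.n)


def suggest_order(data: HarmonizedSurveyTable, seed: int = 0,
                  max_rows: int = 5000) -> list:
    """Greedy predictability ordering (opt-in).

    Starts from the lowest-entropy variable and repeatedly appends the
    variable most predictable from those already placed, scored by 3-fold CV
    of a shallow decision tree on integer-coded data. A heuristic only — the
    default order is schema order.
    """
    from sklearn.model_selection import cross_val_score
    from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

    rng = np.random.default_rng(seed)
    df = data.data
    if len(df) > max_rows:
        idx = np.sort(rng.choice(len(df), size=max_rows, replace=False))
        df = df.iloc[idx]
    coded = {}
    kinds = {}
    for v in data.schema:
        if v.kind == CONTINUOUS:
            coded[v.name] = pd.to_numeric(df[v.name]).fillna(df[v.name].median())
            kinds[v.name] = "num"
        else:
            c = pd.Categorical(df[v.name].fillna(MISSING_LEVEL))
            coded[v.name] = pd.Series(c.codes, index=df.index).astype(float)
            kinds[v.name] = "cat"
    coded = pd.DataFrame(coded)

    def entropy(name):
        p = coded[name].value_counts(normalize=True).to_numpy()
        return float(-(p * np.log(np.maximum(p, 1e-12))).sum())

    names = list(coded.columns)
    placed = [min(names, key=entropy)]
    remaining = [n for n in names if n != placed[0]]
    while remaining:
        scores = {}
        X_placed = coded[placed].to_numpy()
        for cand in remaining:
            y = coded[cand].to_numpy()
            if len(np.unique(y)) < 2:
                scores[cand] = 1.0
                continue
            if kinds[cand] == "cat":
                est = DecisionTreeClassifier(max_depth=5, random_state=seed)
            else:
                est = DecisionTreeRegressor(max_depth=5, random_state=seed)
            scores[cand] = float(np.mean(cross_val_score(est, X_placed, y, cv=3)))
        best = max(remaining, key=lambda c: scores[c])
        placed.append(best)
        remaining.remove(best)
    return placed


def _sample_from_probs(probs: np.ndarray, rng) -> np.ndarray:
    cum = probs.cumsum(axis=1)
    u = rng.random(len(probs))
    return np.minimum((u[:, None] > cum).sum(axis=1), probs.shape[1] - 1)


def _generate_one(model: SynthesisModel, n: int, rng) -> HarmonizedSurveyTable:
    frame = {}
    for iv, cm in zip(model.ivars, model.models):
        if cm.kind == "marginal_cat":
            idx = rng.choice(len(iv.levels), size=n, p=cm.marginal_probs)
            frame[iv.name] = pd.Categorical.from_codes(idx, categories=list(iv.levels))
        elif cm.kind == "marginal_num":
            frame[iv.name] = rng.choice(cm.pool, size=n, replace=True)
        elif cm.kind == "constant_cat":
            frame[iv.name] = pd.Categorical([cm.constant] * n, categories=list(iv.levels))
        elif cm.kind == "constant_num":
            frame[iv.name] = np.full(n, float(cm.constant))
        elif cm.kind == "classifier":
            X = pd.DataFrame({p: frame[p] for p in cm.predictors})
            probs = cm.predict_proba(X)
            codes = _sample_from_probs(probs, rng)
            values = np.asarray(cm.present_levels, dtype=object)[codes]
            frame[iv.name] = pd.Categorical(values, categories=list(iv.levels))
        else:  # regressor
            X = pd.DataFrame({p: frame[p] for p in cm.predictors})
            pred = np.asarray(cm.booster.predict(X), dtype=float)
            frame[iv.name] = pred + rng.choice(cm.residuals, size=n, replace=True)

    # decode internal frame -> harmonized table
    out = {}
    for v in model.schema:
        if v.name not in model.order.names:
            continue
        if v.kind == CONTINUOUS:
            z = np.asarray(frame[v.name], dtype=float)
            t = model.transforms.get(v.name)
            vals = t.inverse(z) if t is not None else z
            miss_col = f"{v.name}__miss"
            if miss_col in frame:
                vals = np.where(np.asarray(frame[miss_col]) == "mis", np.nan, vals)
            out[v.name] = vals
        else:
            s = pd.Series(pd.Categorical(frame[v.name]).astype(object))
            out[v.name] = s.where(s != MISSING_LEVEL, np.nan)
    df = pd.DataFrame(out, columns=[v.name for v in model.schema])
    return HarmonizedSurveyTable(list(model.schema), df)


def generate_replicates(model: SynthesisModel, n: int, m: int, seed: int
                        ) -> SyntheticReplicates:
    """Sample m synthetic tables of n rows each.

    Replicate i draws from a child generator seeded by (seed, i), so
    replicates are mutually independent yet individually reproducible.
    """
    if n < 1 or m < 1:
        raise SynthesisError("n and m must both be >= 1")
    tables = []
    for i in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        tables.append(_generate_one(model, n, rng))
    return SyntheticReplicates(m=m, tables=tables)
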