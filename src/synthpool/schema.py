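"""Variable schemas and the harmonized survey table container.

A harmonized survey table is a respondent-level pandas DataFrame plus a list
of :class:`VariableSchema` entries describing each column: its kind
(categorical, ordinal, continuous), its ordered levels, whether item-level
missingness is allowed, and (for ordinals) a numeric score per level.
Missing cells are NaN in memory and empty strings on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CATEGORICAL = "categorical"
ORDINAL = "ordinal"
CONTINUOUS = "continuous"
_KINDS = (CATEGORICAL, ORDINAL, CONTINUOUS)


class SchemaError(ValueError):
    """Raised when data and schema disagree, naming the offending variable."""


@dataclass(frozen=True)
class VariableSchema:
    """Description of one harmonized survey variable.

    Parameters
    ----------
    name : str
        Column name.
    kind : {"categorical", "ordinal", "continuous"}
    levels : tuple of str
        Ordered category labels; empty for continuous variables.
    missing_allowed : bool
        Whether item-level nonresponse may occur in this column.
    codes : tuple of float, optional
        Numeric score per level for ordinal variables (defaults to 1..K).
    """

    name: str
    kind: str
    levels: tuple = ()
    missing_allowed: bool = False
    codes: tuple = ()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"{self.name}: duplicate level labels")
        if self.kind == CONTINUOUS and self.levels:
            raise SchemaError(f"{self.name}: continuous variable cannot have levels")
        if self.kind in (CATEGORICAL, ORDINAL) and not self.levels:
            raise SchemaError(f"{self.name}: {self.kind} variable needs levels")
        if self.kind == ORDINAL and not self.codes:
            object.__setattr__(
                self, "codes", tuple(float(i + 1) for i in range(len(self.levels)))
            )
        else:
            object.__setattr__(self, "codes", tuple(float(c) for c in self.codes))
        if self.codes and len(self.codes) != len(self.levels):
            raise SchemaError(f"{self.name}: codes/levels length mismatch")

    @property
    def is_numericlike(self) -> bool:
        return self.kind == CONTINUOUS

    def code_of(self, level: str) -> float:
        """Numeric score of a level (ordinal variables)."""
        return self.codes[self.levels.index(level)]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "levels": list(self.levels),
            "missing_allowed": self.missing_allowed,
            "codes": list(self.codes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels=tuple(d.get("levels", ())),
            missing_allowed=bool(d.get("missing_allowed", False)),
            codes=tuple(d.get("codes", ())),
        )


@dataclass
class HarmonizedSurveyTable:
    """Respondent-level survey data with a matching schema.

    ``data`` holds one row per respondent; every column must match exactly one
    schema entry. A ``country`` column (categorical) labels each row's origin.
    """

    schema: list = field(default_factory=list)
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.schema = list(self.schema)
        self.validate()

    # -- access -----------------------------------------------------------
    def schema_for(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise SchemaError(f"no schema entry for variable {name!r}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def variable_names(self) -> list:
        return [v.name for v in self.schema]

    def validate(self) -> None:
        if len(self.data) == 0:
            raise SchemaError("table has no rows")
        names = {v.name for v in self.schema}
        cols = set(self.data.columns)
        if names != cols:
            raise SchemaError(
                f"schema/data column mismatch: schema-only={sorted(names - cols)}, "
                f"data-only={sorted(cols - names)}"
            )
        for v in self.schema:
            col = self.data[v.name]
            missing = col.isna()
            if missing.any() and not v.missing_allowed:
                raise SchemaError(f"{v.name}: missing values not allowed")
            if v.kind == CONTINUOUS:
                vals = col[~missing]
                if not np.isfinite(pd.to_numeric(vals, errors="coerce")).all():
                    raise SchemaError(f"{v.name}: non-finite continuous values")
            else:
                bad = set(col[~missing].unique()) - set(v.levels)
                if bad:
                    raise SchemaError(f"{v.name}: values outside levels: {sorted(bad)}")

    def subset(self, mask) -> "HarmonizedSurveyTable":
        return HarmonizedSurveyTable(self.schema, self.data.loc[mask].reset_index(drop=True))

    def ordinal_scores(self, name: str) -> pd.Series:
        """Numeric scores for an ordinal/categorical-binary column (NaN kept)."""
        v = self.schema_for(name)
        if v.kind == CONTINUOUS:
            return pd.to_numeric(self.data[name])
        mapping = dict(zip(v.levels, v.codes))
        return self.data[name].map(mapping).astype(float)

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path, schema_path=None) -> None:
        """Write rows as UTF-8 CSV (empty string = missing) plus a schema sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        if schema_path is None:
            schema_path = path.with_suffix(".schema.yaml")
        write_schema(self.schema, schema_path)

    @classmethod
    def read_csv(cls, path, schema_path=None) -> "HarmonizedSurveyTable":
        path = Path(path)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.yaml")
        schema = read_schema(schema_path)
        dtypes = {v.name: (float if v.kind == CONTINUOUS else "object") for v in schema}
        df = pd.read_csv(path, dtype=dtypes)
        return cls(schema, df)


def write_schema(schema: Iterable[VariableSchema], path) -> None:
    path = Path(path)
    payload = {"variables": [v.to_dict() for v in schema]}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_schema(path) -> list:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return [VariableSchema.from_dict(d) for d in payload["variables"]]


def concat_tables(tables: Sequence[HarmonizedSurveyTable]) -> HarmonizedSurveyTable:
    """Row-concatenate tables sharing a schema (the pooled dataset)."""
    first = tables[0]
    names = first.variable_names
    for t in tables[1:]:
        if t.variable_names != names:
            raise SchemaError("cannot pool tables with different schemas")
    df = pd.concat([t.data for t in tables], ignore_index=True)
    return HarmonizedSurveyTable(first.schema, df)
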