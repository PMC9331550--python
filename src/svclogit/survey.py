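"""Reading, filtering and encoding of individual-level survey records.

The modelling pipeline expects one row per respondent with a binary disease
outcome (diabetes or hypertension), age in years, categorical
socio-demographic covariates, and a region label.  This module turns such a
table into a :class:`SurveyDataset`: eligibility filtering (age >= 35,
listwise deletion of missing outcome/covariates), treatment (dummy) coding
against declared reference levels, and integer age bins for the RW2 smooth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical covariate columns carried by a raw survey table
CATEGORICAL_VARS = (
    "sex",
    "race",
    "education",
    "marital",
    "wage_work",
    "unpaid_work",
    "salary_period",
    "residence",
)

OUTCOMES = ("diabetes", "hypertension")

#: declared level sets (first level need not be the reference; see REFERENCES)
LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("Male", "Female"),
    "race": ("African", "Colored", "Indian/Asian", "White"),
    "education": ("No primary", "Primary", "Secondary", "Tertiary"),
    "marital": ("Single", "Married", "Divorced/Separated/Widowed"),
    "wage_work": ("Yes", "No"),
    "unpaid_work": ("Yes", "No"),
    "salary_period": ("Per week", "Per month", "Annually"),
    "residence": ("Urban", "Rural"),
}

#: reference (omitted) level per covariate, configurable per call
REFERENCES: dict[str, str] = {
    "sex": "Male",
    "race": "African",
    "education": "No primary",
    "marital": "Single",
    "wage_work": "Yes",
    "unpaid_work": "No",
    "salary_period": "Per month",
    "residence": "Urban",
}

#: covariates entering the default model (subset of CATEGORICAL_VARS)
DEFAULT_COVARIATES = ("sex", "race", "education", "marital", "wage_work", "residence")


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


@dataclass
class RawSurveyTable:
    """Typed individual-level survey table (pre-model form).

    ``df`` has canonical column names: person_id, age, the categorical
    covariates, region, and the outcome columns present in the source.
    """

    df: pd.DataFrame
    levels: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(LEVELS))

    @property
    def n(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        if "age" not in self.df or "region" not in self.df:
            raise SchemaError("table must have 'age' and 'region' columns")
        ages = self.df["age"].dropna()
        if (ages < 0).any():
            raise ValueError("negative ages present")
        for var, lv in self.levels.items():
            if var in self.df:
                seen = set(self.df[var].dropna().unique())
                extra = seen - set(lv)
                if extra:
                    raise ValueError(f"unknown levels for {var!r}: {sorted(extra)}")


@dataclass
class SurveyDataset:
    """Model-ready encoded dataset.

    y is the binary outcome; X the dummy-coded covariate matrix (reference
    levels omitted, no intercept column); region_idx indexes into region_ids;
    age_bin indexes into bin_grid (integer years of age).
    """

    y: np.ndarray
    age: np.ndarray
    age_bin: np.ndarray
    bin_grid: np.ndarray
    X: pd.DataFrame
    region_idx: np.ndarray
    region_ids: tuple[str, ...]
    outcome: str
    covariates: tuple[str, ...]
    reference: dict[str, str]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def validate(self) -> None:
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("y must be binary")
        if self.region_idx.min() < 0 or self.region_idx.max() >= len(self.region_ids):
            raise ValueError("region_idx out of range")
        if (self.age < 0).any():
            raise ValueError("negative age")
        if self.age_bin.min() < 0 or self.age_bin.max() >= len(self.bin_grid):
            raise ValueError("age_bin out of range")
        # no dummy trap: X must have full column rank
        if self.X.shape[1] and np.linalg.matrix_rank(self.X.to_numpy(float)) < self.X.shape[1]:
            raise ValueError("design matrix columns are linearly dependent")


def load_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> RawSurveyTable:
    """Read a delimited text file into a :class:`RawSurveyTable`.

    ``schema`` maps canonical names (age, region, sex, ..., diabetes) to the
    file's column names when they differ.  Unparseable age cells become
    missing; the row is retained (eligibility filtering decides later).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    if schema:
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"columns not found in {path.name}: {missing}")
        df = df.rename(columns={src: canon for canon, src in schema.items()})
    for col in ("age", "region"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    for out in OUTCOMES:
        if out in df.columns:
            df[out] = pd.to_numeric(df[out], errors="coerce")
    table = RawSurveyTable(df=df.reset_index(drop=True))
    table.validate()
    return table


def apply_eligibility(
    table: RawSurveyTable,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_age: float = 35,
) -> RawSurveyTable:
    """Apply the modelling eligibility rule.

    Keeps rows with age >= ``min_age`` (inclusive) and complete data on the
    outcome and every modelled covariate (listwise deletion).  Removal counts
    are logged.  Idempotent.
    """
    if outcome not in table.df.columns:
        raise SchemaError(f"outcome column {outcome!r} missing")
    df = table.df
    n0 = len(df)
    keep_age = df["age"].notna() & (df["age"] >= min_age)
    needed = [outcome, "region", *covariates]
    complete = df[needed].notna().all(axis=1)
    kept = df[keep_age & complete].reset_index(drop=True)
    log.info(
        "eligibility: %d rows in, %d under age %s, %d incomplete, %d retained",
        n0, int((~keep_age).sum()), min_age, int((keep_age & ~complete).sum()), len(kept),
    )
    if kept.empty:
        raise ValueError("no rows remain after eligibility filtering")
    return RawSurveyTable(df=kept, levels=table.levels)


def encode_covariates(
    table: RawSurveyTable,
    region_ids: Sequence[str],
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    reference: Mapping[str, str] | None = None,
    bin_grid: np.ndarray | None = None,
) -> SurveyDataset:
    """Dummy-code covariates and assemble the model-ready dataset.

    Treatment coding: for each categorical covariate the declared reference
    level is omitted and the remaining levels become 0/1 columns named
    ``"<var>=<level>"``.  No intercept column is added (the model holds the
    intercept).  Ages are binned one bin per integer year over the observed
    range (or over a supplied ``bin_grid``).
    """
    ref = dict(REFERENCES)
    if reference:
        ref.update(reference)
    df = table.df
    for var in covariates:
        if var not in df.columns:
            raise SchemaError(f"covariate column {var!r} missing")
        if var not in ref:
            raise ValueError(f"no reference level declared for {var!r}")
    region_ids = tuple(region_ids)
    ridx_map = {lab: k for k, lab in enumerate(region_ids)}
    unknown = set(df["region"].unique()) - set(region_ids)
    if unknown:
        raise ValueError(f"unknown region labels: {sorted(unknown)}")
    region_idx = df["region"].map(ridx_map).to_numpy(int)

    cols: dict[str, np.ndarray] = {}
    for var in covariates:
        levels = table.levels.get(var)
        observed = set(df[var].unique())
        if levels is None:
            levels = tuple(sorted(observed))
        else:
            extra = observed - set(levels)
            if extra:
                raise ValueError(f"unseen level(s) for {var!r}: {sorted(extra)}")
        if ref[var] not in levels:
            raise ValueError(f"reference {ref[var]!r} not a level of {var!r}")
        for lv in levels:
            if lv == ref[var]:
                continue
            cols[f"{var}={lv}"] = (df[var] == lv).to_numpy(float)
    X = pd.DataFrame(cols, index=df.index)

    age = df["age"].to_numpy(float)
    if bin_grid is None:
        lo, hi = int(np.floor(age.min())), int(np.floor(age.max()))
        bin_grid = np.arange(lo, hi + 1, dtype=float)
    bin_grid = np.asarray(bin_grid, dtype=float)
    age_bin = np.clip(
        np.searchsorted(bin_grid, np.floor(age), side="right") - 1, 0, len(bin_grid) - 1
    ).astype(int)

    y = df[outcome].to_numpy(float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1 after filtering")
    ds = SurveyDataset(
        y=y.astype(int), age=age, age_bin=age_bin, bin_grid=bin_grid,
        X=X.reset_index(drop=True), region_idx=region_idx, region_ids=region_ids,
        outcome=outcome, covariates=tuple(covariates), reference=ref,
    )
    ds.validate()
    return ds


def decode_covariates(dataset: SurveyDataset) -> pd.DataFrame:
    """Invert the dummy coding back to categorical labels (test utility)."""
    out = {}
    for var in dataset.covariates:
        prefix = f"{var}="
        block = [c for c in dataset.X.columns if c.startswith(prefix)]
        lab = np.full(dataset.n, dataset.reference[var], dtype=object)
        for c in block:
            lab[dataset.X[c].to_numpy() == 1.0] = c[len(prefix):]
        out[var] = lab
    return pd.DataFrame(out)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def descriptive_table(
    table: RawSurveyTable | pd.DataFrame,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable level counts and percentages (survey descriptive table).

    Percentages are 100 * count / n rounded half-up to one decimal.  Returns
    a DataFrame with columns (variable, level, count, percent).
    """
    df = table.df if isinstance(table, RawSurveyTable) else table
    if df.empty:
        raise ValueError("empty table")
    if variables is None:
        variables = [v for v in (*CATEGORICAL_VARS, "region") if v in df.columns]
    rows = []
    for var in variables:
        counts = df[var].value_counts(dropna=True)
        n = int(counts.sum())
        for level, c in counts.items():
            rows.append(
                {"variable": var, "level": level, "count": int(c),
                 "percent": _round_half_up(100.0 * c / n, 1)}
            )
    return pd.DataFrame(rows)


def render_descriptive(table: pd.DataFrame) -> str:
    """Aligned-text rendering of a descriptive table."""
    lines = []
    for var, grp in table.groupby("variable", sort=False):
        lines.append(var)
        for _, r in grp.iterrows():
            lines.append(f"  {str(r['level']):<30s} {r['count']:>8d} ({r['percent']:.1f})")
    return "\n".join(lines)
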