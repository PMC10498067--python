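"""Reading, validating and writing response tables, configs and reports.

Input is a wide UTF-8 CSV, one row per person, integer item columns coded
``1..m`` plus string covariate columns (group, demographics).  Validation
reports out-of-range or non-integer cells by row and column instead of
silently clamping, and never mutates the parsed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResponseMatrix",
    "RunConfig",
    "ValidationError",
    "ConfigurationError",
    "read_responses",
    "write_report",
    "read_report",
]

REPORT_STAT_COLUMNS = [
    "chi2_nonuniform",
    "p_nonuniform",
    "deltaR2",
    "chi2_uniform",
    "p_uniform",
    "deltaR1",
    "deltaBeta1",
]
REPORT_FLAG_COLUMNS = [
    "flag_uniform_sig",
    "flag_nonuniform_sig",
    "flag_large_r2",
    "flag_large_cvbl",
]


class ValidationError(ValueError):
    """Raised when response data violate the declared coding."""


class ConfigurationError(ValueError):
    """Raised for malformed run configuration."""


@dataclass
class ResponseMatrix:
    """Person x item ordered responses with per-person group labels.

    ``responses`` is an n x J float frame (NaN marks missing) whose values,
    where observed, are integers in ``1..n_categories``.  ``group`` is the
    categorical column a DIF run splits on (exactly two observed levels
    required at analysis time); ``covariates`` holds any further
    demographic columns.
    """

    responses: pd.DataFrame
    group: pd.Series
    n_categories: int = 5
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    @property
    def item_ids(self) -> list[str]:
        return [str(c) for c in self.responses.columns]

    @property
    def n_persons(self) -> int:
        return len(self.responses)

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.responses.isna()

    def validate(self) -> None:
        if self.n_persons < 1 or self.n_items < 1:
            raise ValidationError("need at least one person and one item")
        ids = self.item_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("item_ids must be unique")
        if len(self.group) != self.n_persons:
            raise ValidationError("group length differs from response rows")
        vals = self.responses.to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        bad = obs & ((vals < 1) | (vals > self.n_categories) | (vals != np.round(vals)))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"response {vals[r, c]!r} at row {r}, column {ids[c]!r} is not "
                f"an integer in [1, {self.n_categories}]"
            )

    def require_two_groups(self) -> list:
        levels = sorted(pd.unique(self.group.dropna()))
        if len(levels) != 2:
            raise ValidationError(
                f"DIF analysis needs exactly 2 group levels, found {levels!r}"
            )
        return levels

    def complete_cases(self) -> "ResponseMatrix":
        """Listwise deletion: drop persons with any missing item or group."""
        keep = ~self.responses.isna().any(axis=1) & self.group.notna()
        return ResponseMatrix(
            self.responses.loc[keep].reset_index(drop=True),
            self.group.loc[keep].reset_index(drop=True),
            self.n_categories,
            None
            if self.covariates is None
            else self.covariates.loc[keep].reset_index(drop=True),
        )

    def group_codes(self) -> tuple[np.ndarray, list]:
        """0/1 coding: reference = first level in sorted label order."""
        levels = self.require_two_groups()
        return (self.group == levels[1]).to_numpy().astype(int), levels


@dataclass
class RunConfig:
    """Options of one DIF run (thresholds, model variant, purification)."""

    grouping_variable: str = "group"
    alpha: float = 0.05
    r2_threshold: float = 0.070
    cvbl_threshold: float = 0.01
    max_purification_iters: int = 10
    model_variant: str = "graded"
    missing_policy: str = "listwise"
    n_quadrature: int = 49
    refit_anchors: bool = True
    purify_on: str = "chi2"  # chi2 | chi2_or_effect
    delta_r_formula: str = "paper_ratio"
    bonferroni: bool = False
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.r2_threshold <= 0 or self.cvbl_threshold <= 0:
            raise ConfigurationError("effect-size thresholds must be positive")
        if self.max_purification_iters < 1:
            raise ConfigurationError("max_purification_iters must be >= 1")
        if self.model_variant not in ("graded", "equal_discrimination"):
            raise ConfigurationError("model_variant must be graded|equal_discrimination")
        if self.missing_policy not in ("listwise", "pairwise_item"):
            raise ConfigurationError("missing_policy must be listwise|pairwise_item")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_responses(
    path,
    item_columns: list[str],
    group_column: str,
    n_categories: int = 5,
    covariate_columns: list[str] | None = None,
    missing_token: str = "",
) -> ResponseMatrix:
    """Parse a wide CSV into a validated :class:`ResponseMatrix`.

    Raises :class:`ConfigurationError` for absent columns and
    :class:`ValidationError` (naming row and column) for cells that are
    neither the missing token nor an integer in ``1..n_categories``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in [*item_columns, group_column] if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(f"columns absent from {path.name}: {missing_cols}")
    resp = pd.DataFrame(index=df.index, dtype=float)
    for col in item_columns:
        cell = df[col].str.strip()
        is_missing = (cell == missing_token) | (cell.str.upper() == "NA")
        parsed = pd.to_numeric(cell.where(~is_missing), errors="coerce")
        bad = ~is_missing & parsed.isna()
        if bad.any():
            r = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"non-numeric response {cell.iloc[r]!r} at row {r}, column {col!r}"
            )
        resp[col] = parsed
    cov = None
    if covariate_columns:
        absent = [c for c in covariate_columns if c not in df.columns]
        if absent:
            raise ConfigurationError(f"covariate columns absent: {absent}")
        cov = df[covariate_columns].copy()
    return ResponseMatrix(resp, df[group_column].rename(group_column), n_categories, cov)


def write_report(report, path, float_format: str = "%.4f") -> None:
    """Write a DIF report as CSV (one row per item, statistics then flags).

    Statistics are printed to 4 decimals, matching the conventional
    precision of published DIF tables; flags are written verbatim.
    """
    df = report if isinstance(report, pd.DataFrame) else report.to_frame()
    cols = ["item_id", *REPORT_STAT_COLUMNS, *REPORT_FLAG_COLUMNS]
    extra = [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, float_format=float_format, columns=[*cols, *extra])


def read_report(path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    df = pd.read_csv(path)
    for c in REPORT_FLAG_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df
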