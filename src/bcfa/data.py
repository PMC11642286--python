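"""Reading, validating and standardizing questionnaire response tables.

The Partners in Health (PIH) instrument scores 12 items on a 1-8 Likert scale
across four self-management subscales (Knowledge, Partnership, Management,
Coping).  This module provides the response-matrix container used throughout
the package, listwise handling of incomplete forms, column standardization
(the estimator operates on standardized indicators), and the ML-convention
sample covariance that the discrepancy functions consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SUBSCALES = ("Knowledge", "Partnership", "Management", "Coping")

DEFAULT_ITEM_LABELS: tuple[str, ...] = tuple(f"item{i}" for i in range(1, 13))

#: Hypothesized item -> subscale assignment of the 12-item PIH scale:
#: items 1-2 Knowledge, 3-6 Partnership, 7-8 Management, 9-12 Coping.
DEFAULT_SUBSCALE_MAP: dict[str, str] = {
    "item1": "Knowledge",
    "item2": "Knowledge",
    "item3": "Partnership",
    "item4": "Partnership",
    "item5": "Partnership",
    "item6": "Partnership",
    "item7": "Management",
    "item8": "Management",
    "item9": "Coping",
    "item10": "Coping",
    "item11": "Coping",
    "item12": "Coping",
}


@dataclass
class ResponseMatrix:
    """Subject-by-item response table with its subscale mapping.

    Parameters
    ----------
    values
        ``(n_subjects, n_items)`` numeric array.
    item_labels
        Ordered item names; defaults to ``item1..item12`` style labels.
    scale_min, scale_max
        Likert bounds; raw entries must fall inside them when ``likert``.
    subscale_map
        Item name -> subscale name, covering every item.
    likert
        Whether entries are raw Likert codes (range-checked) or continuous
        (e.g. synthetic draws from the latent linear model).
    """

    values: np.ndarray
    item_labels: tuple[str, ...] = DEFAULT_ITEM_LABELS
    scale_min: int = 1
    scale_max: int = 8
    subscale_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUBSCALE_MAP)
    )
    likert: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D subject-by-item array")
        n, p = self.values.shape
        if n < 1:
            raise ValidationError("need at least one subject")
        if p < 2:
            raise ValidationError("need at least two items")
        self.item_labels = tuple(self.item_labels)
        if len(self.item_labels) != p:
            raise ValidationError(
                f"{len(self.item_labels)} item labels for {p} item columns"
            )
        missing = [it for it in self.item_labels if it not in self.subscale_map]
        if missing:
            raise ValidationError(f"subscale_map does not cover items: {missing}")
        if not np.all(np.isfinite(self.values)):
            idx = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite entry at row {idx[0]}, column {self.item_labels[idx[1]]}"
            )
        if self.likert:
            bad = np.argwhere(
                (self.values < self.scale_min) | (self.values > self.scale_max)
            )
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"entry {self.values[r, c]:g} at row {r}, column "
                    f"{self.item_labels[c]} outside [{self.scale_min}, {self.scale_max}]"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subscale_items(self, subscale: str) -> list[str]:
        """Item labels assigned to one subscale, in questionnaire order."""
        return [it for it in self.item_labels if self.subscale_map[it] == subscale]

    def to_csv(self, path: str | Path) -> None:
        """Write one respondent per row with a header of item labels."""
        df = pd.DataFrame(self.values, columns=list(self.item_labels))
        if self.likert:
            df = df.astype(int)
        df.to_csv(path, index=False)


@dataclass
class StandardizedMatrix:
    """Column-standardized responses plus the raw moments for back-transform."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    item_labels: tuple[str, ...]
    subscale_map: Mapping[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0, ddof=1)
        if np.max(np.abs(mu)) > 1e-10 or np.max(np.abs(sd - 1.0)) > 1e-10:
            raise ValidationError("standardized columns must have mean 0 and sd 1")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subscale_items(self, subscale: str) -> list[str]:
        return [it for it in self.item_labels if self.subscale_map[it] == subscale]


def load_responses(
    path: str | Path, config: Mapping[str, object] | None = None
) -> ResponseMatrix:
    """Read a response CSV and return a validated :class:`ResponseMatrix`.

    ``config`` keys (all optional): ``scale_min``, ``scale_max``,
    ``missing_values`` (token list), ``id_column``, ``subscale_map``,
    ``item_labels``, ``likert``.  Rows with any missing item are dropped
    (listwise deletion) and the dropped count is logged.
    """
    cfg = dict(config or {})
    na_values = cfg.get("missing_values", ["", "NA", "na", "."])
    try:
        df = pd.read_csv(path, na_values=na_values, skipinitialspace=True)
    except (pd.errors.ParserError, OSError) as exc:
        raise ValidationError(f"cannot parse response file {path}: {exc}") from exc
    id_column = cfg.get("id_column")
    if id_column is not None:
        if id_column not in df.columns:
            raise ValidationError(f"id column {id_column!r} not found in {path}")
        df = df.drop(columns=[id_column])
    item_labels = cfg.get("item_labels")
    if item_labels is not None:
        missing_cols = [c for c in item_labels if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"item columns not found: {missing_cols}")
        df = df[list(item_labels)]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric entry {df[col].iloc[row]!r} at row {row}, column {col}"
            )
        df[col] = coerced
    complete = df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "listwise deletion dropped %d of %d rows with missing items",
            n_dropped,
            len(df),
        )
    df = df.loc[complete]
    if df.empty:
        raise InsufficientDataError(f"no complete rows in {path}")
    subscale_map = cfg.get("subscale_map")
    if subscale_map is None:
        if tuple(df.columns) == DEFAULT_ITEM_LABELS:
            subscale_map = dict(DEFAULT_SUBSCALE_MAP)
        else:
            raise ValidationError(
                "subscale_map required when item columns are not the default "
                "item1..item12 layout"
            )
    return ResponseMatrix(
        values=df.to_numpy(dtype=float),
        item_labels=tuple(df.columns),
        scale_min=int(cfg.get("scale_min", 1)),
        scale_max=int(cfg.get("scale_max", 8)),
        subscale_map=dict(subscale_map),
        likert=bool(cfg.get("likert", True)),
    )


def standardize(data: ResponseMatrix) -> StandardizedMatrix:
    """Standardize each item column to mean 0, sample sd 1 (ddof=1)."""
    y = data.values
    mu = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1) if y.shape[0] > 1 else np.zeros(y.shape[1])
    degenerate = np.flatnonzero(sd <= 1e-12)
    if degenerate.size:
        names = [data.item_labels[i] for i in degenerate]
        raise DegenerateVarianceError(f"zero-variance columns: {names}")
    return StandardizedMatrix(
        values=(y - mu) / sd,
        column_means=mu,
        column_sds=sd,
        item_labels=data.item_labels,
        subscale_map=dict(data.subscale_map),
    )


def sample_covariance(
    data: StandardizedMatrix | np.ndarray, divisor: str = "ml"
) -> np.ndarray:
    """Sample covariance of the columns.

    ``divisor="ml"`` divides by n (the SEM maximum-likelihood convention used
    by the discrepancy functions); ``"unbiased"`` divides by n-1.
    """
    y = data.values if isinstance(data, StandardizedMatrix) else np.asarray(data, float)
    n = y.shape[0]
    if n < 2:
        raise InsufficientDataError("sample covariance needs at least 2 rows")
    if divisor not in ("ml", "unbiased"):
        raise ValueError("divisor must be 'ml' or 'unbiased'")
    yc = y - y.mean(axis=0)
    denom = n if divisor == "ml" else n - 1
    cov = yc.T @ yc / denom
    return (cov + cov.T) / 2.0
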