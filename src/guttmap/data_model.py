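"""Core domain types and delimited-file I/O for item-response data.

A scale is a respondent x item matrix of small non-negative integer
response codes. Dichotomous items use {0, 1}; polytomous items use
{0, ..., m_j}. Sampling weights, when present, are one positive real
per respondent.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("guttmap")


class GuttmapError(Exception):
    """Base class for all guttmap errors."""


class ConfigurationError(GuttmapError):
    """A run option or column specification is invalid."""


class DataError(GuttmapError):
    """The input data violate a structural requirement."""


@dataclass
class ResponseMatrix:
    """Validated respondent x item matrix of integer response codes.

    Parameters
    ----------
    values : ndarray of shape (n, k)
        Integer codes; column ``j`` must lie in ``{0, ..., m_j}``.
    item_labels : list of str
        Unique column labels, length ``k``.
    n_categories : ndarray of shape (k,)
        Number of response categories per item (``m_j + 1``), each >= 2.
        Items default to dichotomous when not specified.
    """

    values: np.ndarray
    item_labels: list[str]
    n_categories: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DataError("response matrix must be two-dimensional")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                raise DataError("response codes must be integers")
            self.values = self.values.astype(np.int64)
        n, k = self.values.shape
        if k < 2:
            raise DataError(f"need at least 2 items, got {k}")
        if n < 1:
            raise DataError("need at least 1 respondent after missing-data handling")
        self.item_labels = [str(lbl) for lbl in self.item_labels]
        if len(self.item_labels) != k:
            raise DataError(
                f"{len(self.item_labels)} labels for {k} items"
            )
        if len(set(self.item_labels)) != k:
            raise DataError("item labels must be unique")
        if self.n_categories is None:
            self.n_categories = np.full(k, 2, dtype=np.int64)
        else:
            self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
            if self.n_categories.shape != (k,):
                raise DataError("n_categories must have one entry per item")
            if np.any(self.n_categories < 2):
                raise DataError("each item needs at least 2 response categories")
        self._validate_codes()

    def _validate_codes(self) -> None:
        for j, label in enumerate(self.item_labels):
            col = self.values[:, j]
            bad = (col < 0) | (col > self.n_categories[j] - 1)
            if np.any(bad):
                row = int(np.argmax(bad))
                raise DataError(
                    f"item {label!r}, row {row}: code {col[row]} outside "
                    f"0..{self.n_categories[j] - 1}"
                )
            # reject gaps between observed codes rather than silently recoding
            observed = np.unique(col)
            if len(observed) > 1:
                lo, hi = observed[0], observed[-1]
                if len(observed) != hi - lo + 1:
                    absent = sorted(set(range(lo, hi + 1)) - set(observed.tolist()))
                    raise DataError(
                        f"item {label!r}: observed codes have gaps "
                        f"(missing {absent}); recode to consecutive integers"
                    )

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path, delimiter: str = ",") -> None:
        """Write the matrix as delimited text with a header row."""
        pd.DataFrame(self.values, columns=self.item_labels).to_csv(
            path, index=False, sep=delimiter
        )


@dataclass
class WeightVector:
    """Original sampling weights and their integer internal counterpart.

    ``sw1[i] = round(sw_orig[i] * s / sw_min)`` with half-away-from-zero
    rounding; the minimum-weight observation maps to ``round(s)``.
    """

    sw_orig: np.ndarray
    sw_min: float
    s: float
    sw1: np.ndarray

    def __post_init__(self) -> None:
        self.sw_orig = np.asarray(self.sw_orig, dtype=float)
        self.sw1 = np.asarray(self.sw1, dtype=np.int64)
        if np.any(self.sw_orig <= 0):
            raise DataError("sampling weights must be strictly positive")
        if self.sw_min <= 0 or not np.isclose(self.sw_min, self.sw_orig.min()):
            raise DataError("sw_min must equal min(sw_orig) > 0")
        if self.s >= 1 and np.any(self.sw1 < 1):
            raise DataError("internal weights must be >= 1 when s >= 1")

    def __len__(self) -> int:
        return len(self.sw_orig)


@dataclass
class PairCounts:
    """Observed (F) and independence-expected (E) Guttman-error mass per pair.

    Both matrices are symmetric with NaN diagonal, indexed in display
    (popularity) order. ``undefined`` marks pairs with zero expected mass
    (an item step endorsed by everyone or no one).
    """

    F: np.ndarray
    E: np.ndarray
    n_eff: float
    labels: list[str]
    ordering: np.ndarray
    undefined: np.ndarray

    def __post_init__(self) -> None:
        k = self.F.shape[0]
        if self.F.shape != (k, k) or self.E.shape != (k, k):
            raise DataError("F and E must be square and congruent")
        off = ~np.eye(k, dtype=bool) & ~self.undefined
        if np.any(self.F[off] < 0):
            raise DataError("observed error mass must be non-negative")
        if np.any(self.E[off] <= 0):
            raise DataError("expected mass must be positive for defined pairs")


@dataclass
class ErrorMap:
    """Symmetric matrix of Guttman-error percentages, e_ij x 100.

    The diagonal carries NaN and is never rendered as a value; ``labels``
    are in display (popularity) order; ``ordering`` maps display position
    to the original item index.
    """

    e_percent: np.ndarray
    ordering: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        k = self.e_percent.shape[0]
        off = ~np.eye(k, dtype=bool)
        defined = off & np.isfinite(self.e_percent)
        if not np.allclose(
            self.e_percent[defined], self.e_percent.T[defined], equal_nan=True
        ):
            raise DataError("error percentages must be symmetric")
        if np.any(self.e_percent[defined] < 0):
            raise DataError("error percentages must be non-negative")

    @property
    def n_items(self) -> int:
        return self.e_percent.shape[0]


@dataclass
class HSummary:
    """Loevinger scalability coefficients: pairwise, per item, and total."""

    h_pair: np.ndarray
    h_item: np.ndarray
    h_total: float
    labels: list[str]

    def __post_init__(self) -> None:
        fin = np.isfinite(self.h_pair)
        if np.any(self.h_pair[fin] > 1 + 1e-12):
            raise DataError("pairwise h cannot exceed 1")
        if self.h_total > 1 + 1e-12:
            raise DataError("total H cannot exceed 1")


class ReadResult(NamedTuple):
    responses: ResponseMatrix
    weights: Optional[np.ndarray]
    n_dropped: int


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_responses(
    path,
    item_columns: Sequence[str],
    weight_column: Optional[str] = None,
    n_categories: Optional[Sequence[int]] = None,
    delimiter: Optional[str] = None,
) -> ReadResult:
    """Read a delimited response file with listwise deletion of missing rows.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row (UTF-8).
    item_columns : sequence of str
        Names of the item columns, in scale order.
    weight_column : str, optional
        Name of a per-respondent sampling-weight column.
    n_categories : sequence of int, optional
        Response categories per item; omitted items are dichotomous.
    delimiter : str, optional
        Field delimiter; auto-detected when omitted.

    Returns
    -------
    ReadResult
        The validated :class:`ResponseMatrix`, the raw weights (or None),
        and the count of listwise-deleted rows.
    """
    if len(item_columns) < 2:
        raise ConfigurationError("at least two item columns are required")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    missing = [c for c in list(item_columns) + ([weight_column] if weight_column else [])
               if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"column(s) not found in {path}: {', '.join(missing)}"
        )
    sub = df[list(item_columns) + ([weight_column] if weight_column else [])]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("%d row%s excluded (missing responses)", n_dropped,
                    "" if n_dropped == 1 else "s")
    sub = sub.loc[complete]
    if sub.empty:
        raise DataError("no complete rows remain after listwise deletion")

    raw = sub[list(item_columns)]
    for col in item_columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise DataError(f"item {col!r}, row {row}: non-numeric response")
        if np.any(vals != np.floor(vals)):
            row = int(vals.index[vals != np.floor(vals)][0])
            raise DataError(f"item {col!r}, row {row}: non-integer response")
    values = raw.astype(np.int64).to_numpy()

    rm = ResponseMatrix(values, list(item_columns), n_categories)
    weights = None
    if weight_column:
        weights = pd.to_numeric(sub[weight_column], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(weights)):
            raise DataError(f"weight column {weight_column!r}: non-numeric value")
        if np.any(weights <= 0):
            raise DataError(f"weight column {weight_column!r}: non-positive weight")
    return ReadResult(rm, weights, n_dropped)
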