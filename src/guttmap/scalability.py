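"""Guttman-error counting and Loevinger scalability coefficients.

For a pair of dichotomous items with endorsement proportions
``p_a >= p_b`` (``a`` the easier item), a Guttman error is the pattern
``X_a = 0, X_b = 1``: the harder item endorsed without the easier one.
The error ratio for the pair is

    e_ab = F_ab / E_ab,

where ``F_ab`` is the (weighted) observed error count and
``E_ab = n_eff * (1 - p_a) * p_b`` the count expected were the items
statistically independent. The Loevinger coefficients are the
complements ``h_ab = 1 - e_ab``, aggregated per item and for the whole
scale by pooling F and E over pairs.

Polytomous items are handled through item steps: step ``s`` of item
``j`` is the dichotomous indicator ``X_j >= s``. Every step pair of an
item pair contributes an error count and an expectation, with the
easier/harder roles assigned per step pair by step popularity; summing
over step pairs makes ``1 - F/E`` identical to the classical
``cov(X_a, X_b) / cov_max`` construction and reduces exactly to the
dichotomous rule when every item has two categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .data_model import (
    DataError,
    ErrorMap,
    HSummary,
    PairCounts,
    ResponseMatrix,
    WeightVector,
)

__all__ = [
    "ItemOrdering",
    "endorsement",
    "order_items",
    "pair_counts",
    "error_matrix",
    "loevinger",
    "mat_report",
]


@dataclass
class ItemOrdering:
    """Permutation of items for display, most endorsed (easiest) first."""

    order: np.ndarray
    endorsement: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        k = len(self.endorsement)
        if sorted(self.order.tolist()) != list(range(k)):
            raise DataError("order must be a permutation of item indices")


def _weights_as_array(
    R: ResponseMatrix, w: Union[WeightVector, np.ndarray, None]
) -> np.ndarray:
    if w is None:
        return np.ones(R.n_respondents)
    arr = np.asarray(w.sw1 if isinstance(w, WeightVector) else w, dtype=float)
    if arr.shape != (R.n_respondents,):
        raise DataError(
            f"weight length {arr.shape} does not match {R.n_respondents} rows"
        )
    if np.any(arr <= 0):
        raise DataError("weights must be strictly positive")
    return arr


def endorsement(
    R: ResponseMatrix, w: Union[WeightVector, np.ndarray, None] = None
) -> np.ndarray:
    """Per-item weighted mean response.

    For dichotomous items this is the endorsement proportion
    ``sum(w_i * x_ij) / sum(w_i)``; unweighted calls use unit weights.
    Lower endorsement marks a more intense (harder) item.
    """
    wa = _weights_as_array(R, w)
    return wa @ R.values / wa.sum()


def order_items(
    endors: np.ndarray,
    mode: str = "decreasing",
    custom: Optional[Sequence[int]] = None,
) -> ItemOrdering:
    """Build the display ordering of items.

    ``mode="decreasing"`` sorts by endorsement descending with ties broken
    by original input position (stable), so the easiest item comes first.
    ``mode="custom"`` uses the user-supplied permutation unchanged.
    """
    endors = np.asarray(endors, dtype=float)
    k = len(endors)
    if mode == "decreasing":
        if custom is not None:
            raise DataError("custom order given but mode is 'decreasing'")
        order = np.argsort(-endors, kind="stable")
    elif mode == "custom":
        if custom is None:
            raise DataError("mode 'custom' requires an explicit item order")
        order = np.asarray(custom, dtype=np.int64)
        if sorted(order.tolist()) != list(range(k)):
            raise DataError(f"custom order is not a permutation of 0..{k - 1}")
    else:
        raise DataError(f"unknown ordering mode {mode!r}")
    return ItemOrdering(order=order, endorsement=endors)


def pair_counts(
    R: ResponseMatrix,
    ordering: ItemOrdering,
    w: Union[WeightVector, np.ndarray, None] = None,
) -> PairCounts:
    """Count observed and expected Guttman errors for every item pair.

    Returns symmetric ``F`` and ``E`` matrices in display order with NaN
    diagonal. Pairs whose expected mass is zero (an item step endorsed by
    all or none of the sample) are flagged undefined rather than set to
    zero.
    """
    wa = _weights_as_array(R, w)
    n_eff = float(wa.sum())
    k = R.n_items
    order = ordering.order

    # Step indicators per item, in display order: steps[j] has shape (n, m_j)
    steps: list[np.ndarray] = []
    pops: list[np.ndarray] = []
    for pos in range(k):
        j = order[pos]
        m = R.n_categories[j] - 1
        ind = R.values[:, j : j + 1] >= np.arange(1, m + 1)
        steps.append(ind)
        pops.append(wa @ ind / n_eff)

    F = np.full((k, k), np.nan)
    E = np.full((k, k), np.nan)
    undefined = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            f_ab = 0.0
            e_ab = 0.0
            for s in range(steps[a].shape[1]):
                for t in range(steps[b].shape[1]):
                    pa, pb = pops[a][s], pops[b][t]
                    # easier step = higher popularity; ties favor the item
                    # placed earlier in the display ordering
                    if pa >= pb:
                        easy, hard = steps[a][:, s], steps[b][:, t]
                        pe, ph = pa, pb
                    else:
                        easy, hard = steps[b][:, t], steps[a][:, s]
                        pe, ph = pb, pa
                    f_ab += float(wa @ (~easy & hard))
                    e_ab += n_eff * (1.0 - pe) * ph
            if e_ab <= 0.0:
                undefined[a, b] = undefined[b, a] = True
            else:
                F[a, b] = F[b, a] = f_ab
                E[a, b] = E[b, a] = e_ab
    labels = [R.item_labels[j] for j in order]
    return PairCounts(F=F, E=E, n_eff=n_eff, labels=labels,
                      ordering=order, undefined=undefined)


def error_matrix(counts: PairCounts) -> ErrorMap:
    """Symmetric percentage matrix ``e_percent = 100 * F / E``.

    Undefined pairs propagate as NaN; the diagonal is NaN and never
    rendered as a value.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        e = 100.0 * counts.F / counts.E
    return ErrorMap(e_percent=e, ordering=counts.ordering, labels=counts.labels)


def loevinger(counts: PairCounts) -> HSummary:
    """Loevinger coefficients from pooled Guttman-error counts.

    ``h_pair = 1 - F/E`` per pair; ``h_item[i]`` pools F and E over all
    pairs containing item ``i``; ``h_total`` pools over all unordered
    pairs. Undefined pairs are excluded from the pooled sums with a
    warning.
    """
    if counts.undefined.any():
        n_undef = int(counts.undefined.sum() // 2)
        warnings.warn(
            f"{n_undef} item pair(s) have zero expected Guttman errors and "
            "are excluded from pooled H coefficients",
            stacklevel=2,
        )
    k = counts.F.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        h_pair = 1.0 - counts.F / counts.E
    defined = ~counts.undefined & ~np.eye(k, dtype=bool) & np.isfinite(counts.F)

    h_item = np.full(k, np.nan)
    for i in range(k):
        row = defined[i]
        if row.any():
            h_item[i] = 1.0 - counts.F[i, row].sum() / counts.E[i, row].sum()
    upper = np.triu(defined, 1)
    if upper.any():
        h_total = float(1.0 - counts.F[upper].sum() / counts.E[upper].sum())
    else:
        h_total = float("nan")
    return HSummary(h_pair=h_pair, h_item=h_item, h_total=h_total,
                    labels=counts.labels)


def _fmt_matrix(mat: np.ndarray, labels: Sequence[str], fmt: str,
                diag: str = ".") -> str:
    width = max(max(len(s) for s in labels) + 1,
                max(len(fmt % v) for v in np.nan_to_num(mat).ravel()) + 1, 7)
    lines = [" " * width + "".join(f"{s:>{width}}" for s in labels)]
    for i, lab in enumerate(labels):
        cells = []
        for j in range(len(labels)):
            if i == j:
                cells.append(f"{diag:>{width}}")
            elif np.isfinite(mat[i, j]):
                cells.append(f"{fmt % mat[i, j]:>{width}}")
            else:
                cells.append(f"{'undef':>{width}}")
        lines.append(f"{lab:>{width}}" + "".join(cells))
    return "\n".join(lines)


def mat_report(em: ErrorMap, hs: HSummary, n_eff: float) -> str:
    """Plain-text report of the e_ij, h_ij, h_i and H matrices.

    Percentages print with 1 decimal, coefficients with 3, mirroring the
    console output produced when matrix printing is requested.
    """
    lines = [
        "Guttman error percentages e_ij (%):",
        _fmt_matrix(em.e_percent, em.labels, "%.1f"),
        "",
        "Loevinger pairwise coefficients h_ij:",
        _fmt_matrix(hs.h_pair, hs.labels, "%.3f"),
        "",
        "Item coefficients h_i:",
    ]
    for lab, h in zip(hs.labels, hs.h_item):
        lines.append(f"  {lab}: " + ("%.3f" % h if np.isfinite(h) else "undef"))
    lines += [
        "",
        "Total H: " + ("%.3f" % hs.h_total if np.isfinite(hs.h_total) else "undef"),
        f"Effective n: {n_eff:g}",
    ]
    return "\n".join(lines)
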