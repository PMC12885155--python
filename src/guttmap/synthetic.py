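"""Synthetic response data: parametric Guttman scales, emulation
resampling, and weight fixtures.

`generate_guttman` draws a uniform latent trait per respondent and
endorses item j iff the trait exceeds the item's difficulty — a perfect
scalogram — then flips each response independently with a chosen error
probability. At error rate 0 every item pair has zero Guttman errors;
at 0.5 responses carry no trait information and error ratios approach
100% of the independence expectation.

`emulate_dataset` reproduces a confidentiality-preserving resampling
scheme: the source data are first trimmed or expanded to a fixed size,
then each output row is filled by drawing a large candidate pool with
replacement and selecting one candidate at random. Whole rows are
resampled, so inter-item dependence (the overlap profile of the items)
is preserved while no original record survives identifiably.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import DataError, ResponseMatrix

__all__ = ["generate_guttman", "emulate_dataset", "generate_weights",
           "write_fixture"]


def generate_guttman(
    n: int,
    difficulties,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ResponseMatrix:
    """Simulate dichotomous responses from a noisy Guttman scalogram.

    Parameters
    ----------
    n : int
        Number of respondents.
    difficulties : increasing floats in (0, 1)
        Item difficulty thresholds on the latent-trait scale; item j is
        endorsed iff the respondent's uniform(0,1) trait exceeds it.
    error_rate : float in [0, 1]
        Independent per-response flip probability. 0 gives a perfect
        scalogram; 0.5 destroys all trait information.
    seed : int
        Seed for the random generator; output is deterministic given it.
    """
    diffs = np.asarray(difficulties, dtype=float)
    if np.any(np.diff(diffs) <= 0):
        raise DataError("difficulties must be strictly increasing")
    if np.any((diffs <= 0) | (diffs >= 1)):
        raise DataError("difficulties must lie strictly inside (0, 1)")
    if not 0 <= error_rate <= 1:
        raise DataError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    trait = rng.uniform(size=(n, 1))
    values = (trait > diffs).astype(np.int64)
    if error_rate > 0:
        flips = rng.uniform(size=values.shape) < error_rate
        values = np.where(flips, 1 - values, values)
    labels = [f"i{j + 1}" for j in range(len(diffs))]
    return ResponseMatrix(values, labels)


def emulate_dataset(
    R_orig: ResponseMatrix,
    n_target: int = 1000,
    seed: int = 0,
    fast: bool = False,
) -> ResponseMatrix:
    """Resample a response matrix to a fixed size, preserving row profiles.

    Step 1 trims (uniform subsample without replacement) or expands
    (resample with replacement) the source to ``n_target`` rows. Then,
    for each output row, step 2 draws ``n_target`` candidate records
    with replacement from the step-1 data and step 3 selects one of
    them uniformly. ``fast=True`` replaces steps 2-3 with the single
    uniform draw per row they compose to; the two paths are
    distributionally identical.
    """
    if n_target < 1:
        raise DataError("n_target must be at least 1")
    rng = np.random.default_rng(seed)
    n = R_orig.n_respondents

    if n > n_target:
        base_idx = rng.choice(n, size=n_target, replace=False)
    elif n < n_target:
        base_idx = rng.choice(n, size=n_target, replace=True)
    else:
        base_idx = np.arange(n)
    base = R_orig.values[base_idx]

    if fast:
        rows = rng.integers(0, n_target, size=n_target)
    else:
        rows = np.empty(n_target, dtype=np.int64)
        for r in range(n_target):
            pool = rng.integers(0, n_target, size=n_target)
            rows[r] = pool[rng.integers(0, n_target)]
    return ResponseMatrix(base[rows], list(R_orig.item_labels),
                          R_orig.n_categories.copy())


def generate_weights(
    n: int,
    low: float,
    high: float,
    seed: int = 0,
) -> np.ndarray:
    """Log-uniform sampling weights on [low, high].

    The first two entries are pinned to ``low`` and ``high`` so every
    fixture contains the range endpoints by construction.
    """
    if not 0 < low <= high:
        raise DataError("need 0 < low <= high")
    if n < 1:
        raise DataError("n must be at least 1")
    rng = np.random.default_rng(seed)
    w = np.exp(rng.uniform(np.log(low), np.log(high), size=n))
    if n >= 1:
        w[0] = low
    if n >= 2:
        w[1] = high
    return w


def write_fixture(
    R: ResponseMatrix,
    path,
    weights=None,
    weight_column: str = "sw",
    manifest: dict | None = None,
) -> None:
    """Write a response matrix (plus optional weight column) as CSV.

    When ``manifest`` is given, a sibling ``<path>.manifest.json``
    records the generation parameters and seeds for reproducibility.
    """
    df = pd.DataFrame(R.values, columns=R.item_labels)
    if weights is not None:
        if len(weights) != R.n_respondents:
            raise DataError("weights do not align with response rows")
        df[weight_column] = np.asarray(weights, dtype=float)
    df.to_csv(path, index=False)
    if manifest is not None:
        mpath = Path(str(path) + ".manifest.json")
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
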