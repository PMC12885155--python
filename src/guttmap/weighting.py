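"""Sample-weight rescaling and case expansion for complex-survey data.

Guttman-error counting needs only point estimates, so survey weights can
enter either by direct frequency weighting or by replicating each record
an integer number of times. Raw weights are unusable for replication
(values below 0.5 round to zero and drop the respondent), so they are
first min-normalized and scaled:

    sw1_i = round(sw_orig_i * s / min(sw_orig))

with half-away-from-zero rounding. The minimum-weight observation maps
to ``round(s)``, so every record survives whenever ``s >= 1``; larger
``s`` preserves more of the original weight resolution at the cost of a
bigger expanded dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DataError, ResponseMatrix, WeightVector

__all__ = ["rescale_weights", "expand_rows", "weight_diagnostics",
           "WeightDiagnostics", "DEFAULT_EXPANSION_CAP"]

DEFAULT_EXPANSION_CAP = 5_000_000


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds halves to even; weights are positive so +0.5/floor works
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def rescale_weights(sw_orig, s: float = 1.0) -> WeightVector:
    """Transform raw sampling weights to integer internal weights.

    Parameters
    ----------
    sw_orig : array-like of positive floats
        Original per-respondent sampling weights.
    s : float, default 1
        Scaling factor; must be >= 1 so every internal weight is >= 1.
    """
    sw = np.asarray(sw_orig, dtype=float)
    if sw.size == 0:
        raise DataError("empty weight vector")
    if np.any(~np.isfinite(sw)) or np.any(sw <= 0):
        raise DataError("sampling weights must be finite and strictly positive")
    if s < 1:
        raise DataError(f"scaling factor must be >= 1, got {s}")
    sw_min = float(sw.min())
    sw1 = _round_half_away(sw * s / sw_min)
    return WeightVector(sw_orig=sw, sw_min=sw_min, s=float(s), sw1=sw1)


def expand_rows(
    R: ResponseMatrix,
    wv: WeightVector,
    cap: int = DEFAULT_EXPANSION_CAP,
) -> ResponseMatrix:
    """Replicate each row ``sw1[i]`` times, in stable input order.

    Raises if the expanded size would exceed ``cap`` (guidance: lower the
    scaling factor ``s``).
    """
    if len(wv) != R.n_respondents:
        raise DataError("weight vector does not align with response rows")
    if np.any(wv.sw1 < 1):
        raise DataError("all internal weights must be >= 1 for expansion")
    total = int(wv.sw1.sum())
    if total > cap:
        raise DataError(
            f"expansion would create {total} rows (cap {cap}); "
            "lower the scaling factor s or raise the cap"
        )
    values = np.repeat(R.values, wv.sw1, axis=0)
    return ResponseMatrix(values, list(R.item_labels), R.n_categories.copy())


@dataclass
class WeightDiagnostics:
    """Console diagnostics describing a weight transformation."""

    orig_min: float
    orig_max: float
    transformed_min: int
    transformed_max: int
    n_unique: int
    total_expanded: int
    s: float
    naive_zero: int   # observations a naive round() would drop (weight -> 0)
    naive_one: int    # observations a naive round() would leave unexpanded

    def __str__(self) -> str:
        return "\n".join([
            f"Original weights: min {self.orig_min:g}, max {self.orig_max:g}",
            f"Scaling factor s = {self.s:g}",
            f"Internal integer weights: min {self.transformed_min}, "
            f"max {self.transformed_max} ({self.n_unique} unique values)",
            f"Expanded dataset size: {self.total_expanded} rows",
            f"Naive rounding of the raw weights would drop {self.naive_zero} "
            f"observation(s) (weight rounds to 0) and leave {self.naive_one} "
            "unexpanded (weight rounds to 1)",
        ])


def weight_diagnostics(sw_orig, s: float = 1.0) -> WeightDiagnostics:
    """Summarize the rescaling transform to guide the choice of ``s``."""
    wv = rescale_weights(sw_orig, s)
    naive = _round_half_away(wv.sw_orig)
    return WeightDiagnostics(
        orig_min=float(wv.sw_orig.min()),
        orig_max=float(wv.sw_orig.max()),
        transformed_min=int(wv.sw1.min()),
        transformed_max=int(wv.sw1.max()),
        n_unique=int(np.unique(wv.sw1).size),
        total_expanded=int(wv.sw1.sum()),
        s=float(s),
        naive_zero=int(np.sum(naive == 0)),
        naive_one=int(np.sum(naive == 1)),
    )
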