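"""High-level analysis pipeline: weights -> ordering -> counts -> e/H."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import scalability, weighting
from .data_model import (
    ConfigurationError,
    ErrorMap,
    HSummary,
    PairCounts,
    ResponseMatrix,
    WeightVector,
)

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    """Everything computed in one scalability run."""

    error_map: ErrorMap
    h_summary: HSummary
    counts: PairCounts
    n_eff: float
    weight_vector: Optional[WeightVector]

    def mat_report(self) -> str:
        return scalability.mat_report(self.error_map, self.h_summary, self.n_eff)


def analyze(
    R: ResponseMatrix,
    weights=None,
    scl: float = 1.0,
    engine: str = "weighted",
    item_order: str = "decreasing",
    custom_order: Optional[Sequence[int]] = None,
    expansion_cap: int = weighting.DEFAULT_EXPANSION_CAP,
) -> AnalysisResult:
    """Run the full Guttman-error analysis on a response matrix.

    When raw sampling weights are given they are first rescaled to
    integer internal weights with scaling factor ``scl``. The default
    engine counts with frequency weights directly; ``engine="expand"``
    replicates rows instead and counts unweighted — the two give
    identical point estimates.
    """
    wv: Optional[WeightVector] = None
    if weights is not None:
        wv = weights if isinstance(weights, WeightVector) else \
            weighting.rescale_weights(weights, scl)

    if engine == "expand" and wv is not None:
        R_work = weighting.expand_rows(R, wv, cap=expansion_cap)
        w_work = None
    elif engine in ("weighted", "expand"):
        R_work = R
        w_work = wv
    else:
        raise ConfigurationError(f"unknown engine {engine!r}")

    endors = scalability.endorsement(R_work, w_work)
    ordering = scalability.order_items(endors, item_order, custom_order)
    counts = scalability.pair_counts(R_work, ordering, w_work)
    em = scalability.error_matrix(counts)
    hs = scalability.loevinger(counts)
    return AnalysisResult(error_map=em, h_summary=hs, counts=counts,
                          n_eff=counts.n_eff, weight_vector=wv)
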