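"""Offline comparators: the Benjamini-Hochberg step-up procedure and
uncorrected testing on a fixed batch of p-values."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RejectionSet", "bh_procedure", "uncorrected"]


@dataclass(frozen=True)
class RejectionSet:
    """Indices (0-based) of rejected hypotheses and the threshold used."""

    indices: tuple
    threshold: float

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, i) -> bool:
        return i in self.indices


def bh_procedure(pvals, alpha: float) -> RejectionSet:
    """Standard BH step-up: reject all p-values at or below the largest
    threshold whose estimated FDP ``n * s / |R(s)|`` stays at or below alpha.

    Ties are handled by the step-up scan from the largest index; an empty
    input yields an empty rejection set.
    """
    p = np.asarray(list(pvals), dtype=float)
    n = len(p)
    if n == 0:
        return RejectionSet((), 0.0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = alpha * np.arange(1, n + 1) / n
    below = np.nonzero(sorted_p <= crit)[0]
    if below.size == 0:
        return RejectionSet((), 0.0)
    k = below[-1]
    threshold = float(sorted_p[k])
    idx = tuple(int(i) for i in np.nonzero(p <= threshold)[0])
    return RejectionSet(idx, threshold)


def uncorrected(pvals, alpha: float) -> RejectionSet:
    """Reject every p-value at or below alpha, with no correction."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size and np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    idx = tuple(int(i) for i in np.nonzero(p <= alpha)[0])
    return RejectionSet(idx, float(alpha))
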