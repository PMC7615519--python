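"""Spending sequences: the weight schedules {gamma_t} used by all online policies.

A spending sequence is a non-increasing, non-negative schedule of weights
summing to one, over an index set starting at 0 or 1.  A *bounded* sequence
zeroes every weight past a horizon ``M`` and renormalizes the retained
weights so they again sum to one; this is the convention used for the
bounded algorithm variants throughout the package.

Three families are provided:

``lord-default``
    ``u_t = log(max(t, 2)) / (t * exp(sqrt(log t)))``, indexed from 1.
``power`` / ``power+1``
    ``u_t = (t + offset) ** -s``; ``power`` is indexed from 1 with
    ``offset = 0``; ``power+1`` is indexed from 0 with ``offset = 1``
    (the two give identical weight values, shifted by one index).
``uniform``
    ``1 / M`` up to the bound, which must be finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import zeta

__all__ = [
    "SpendingSequence",
    "lord_default_sequence",
    "power_law_sequence",
    "uniform_sequence",
    "sequence_from_spec",
    "lord_default_gamma",
    "power_law_gamma",
    "uniform_gamma",
]

#: Default cutoff for direct summation when normalizing an infinite sequence
#: that has no closed-form constant (the tail past the cutoff is handled by
#: an Euler-Maclaurin correction).
DEFAULT_CUTOFF = 200_000


def _lord_default_raw(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    logt = np.log(t)
    return np.log(np.maximum(t, 2.0)) / (t * np.exp(np.sqrt(logt)))


def _lord_default_tail(a: float) -> float:
    """Sum of the lord-default raw weights over [a, inf), a >= 3.

    Integral part is exact after the substitution v = sqrt(log t):
    int_a^inf log(t) e^{-sqrt(log t)} / t dt = 2 e^{-v}(v^3 + 3v^2 + 6v + 6)
    with v = sqrt(log a); Euler-Maclaurin adds f(a)/2 - f'(a)/12.
    """
    v = math.sqrt(math.log(a))
    integral = 2.0 * math.exp(-v) * (v**3 + 3 * v**2 + 6 * v + 6)
    L = math.log(a)
    f = L * math.exp(-v) / a
    fprime = math.exp(-v) * (1.0 - v / 2.0 - L) / a**2
    return integral + f / 2.0 - fprime / 12.0


@lru_cache(maxsize=8)
def _lord_default_constant(cutoff: int = DEFAULT_CUTOFF) -> float:
    head = float(_lord_default_raw(np.arange(1, cutoff + 1)).sum())
    return head + _lord_default_tail(cutoff + 1)


@dataclass(frozen=True)
class SpendingSequence:
    """A normalized, non-increasing weight schedule.

    Parameters
    ----------
    kind
        One of ``"lord-default"``, ``"power-law"``, ``"uniform"``.
    exponent
        Power-law exponent ``s`` (ignored for other kinds).
    offset
        Index offset for the power law: ``weight(t) ~ (t + offset)**-s``.
    start
        First valid index (0 or 1).
    bound
        Horizon ``M``; ``math.inf`` for an unbounded sequence.  Finite
        bounds renormalize the first ``M`` retained weights to sum to one.
    """

    kind: str
    exponent: float = float("nan")
    offset: int = 0
    start: int = 1
    bound: float = math.inf
    cutoff: int = DEFAULT_CUTOFF
    _norm: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("lord-default", "power-law", "uniform"):
            raise ValueError(f"unknown spending sequence kind: {self.kind!r}")
        if self.start not in (0, 1):
            raise ValueError("start index must be 0 or 1")
        finite = math.isfinite(self.bound)
        if finite and (self.bound < 1 or self.bound != int(self.bound)):
            raise ValueError("bound M must be a positive integer or inf")
        if self.kind == "uniform" and not finite:
            raise ValueError("uniform sequence requires a finite bound M")
        if self.kind == "power-law":
            if not finite and self.exponent <= 1:
                raise ValueError(
                    "power-law exponent must exceed 1 for an unbounded sequence"
                )
            if self.exponent <= 0:
                raise ValueError("power-law exponent must be positive")
        object.__setattr__(self, "_norm", self._normalizer())

    # -- raw (unnormalized) weights ---------------------------------------

    def _raw(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        if self.kind == "lord-default":
            return _lord_default_raw(idx)
        if self.kind == "power-law":
            return (idx + self.offset) ** (-self.exponent)
        return np.ones_like(idx)  # uniform

    def _normalizer(self) -> float:
        if math.isfinite(self.bound):
            n = int(self.bound)
            idx = np.arange(self.start, self.start + n)
            return float(self._raw(idx).sum())
        if self.kind == "power-law":
            # start=1/offset=0 and start=0/offset=1 both sum to zeta(s)
            return float(zeta(self.exponent)) - sum(
                (k + self.offset) ** (-self.exponent)
                for k in range(1, self.start + self.offset)
            )
        return _lord_default_constant(self.cutoff)

    # -- public API --------------------------------------------------------

    def weight(self, t: int) -> float:
        """Normalized weight at index ``t`` (0 past the bound)."""
        if t < self.start:
            raise ValueError(f"index {t} below first valid index {self.start}")
        if t - self.start >= self.bound:
            return 0.0
        return float(self._raw(np.array([t]))[0]) / self._norm

    def weights(self, n: int) -> np.ndarray:
        """The first ``n`` normalized weights, starting at index ``start``."""
        idx = np.arange(self.start, self.start + n)
        w = self._raw(idx) / self._norm
        if math.isfinite(self.bound):
            w[int(self.bound):] = 0.0
        return w

    def partial_sum(self, n: int) -> float:
        return float(self.weights(n).sum())


# -- constructors ----------------------------------------------------------


def lord_default_sequence(bound: float = math.inf, cutoff: int = DEFAULT_CUTOFF) -> SpendingSequence:
    return SpendingSequence("lord-default", start=1, bound=bound, cutoff=cutoff)


def power_law_sequence(exponent: float, offset: int = 0, bound: float = math.inf) -> SpendingSequence:
    start = 0 if offset == 1 else 1
    return SpendingSequence("power-law", exponent=exponent, offset=offset, start=start, bound=bound)


def uniform_sequence(bound: float) -> SpendingSequence:
    return SpendingSequence("uniform", start=1, bound=bound)


def sequence_from_spec(spec: str, bound: float = math.inf) -> SpendingSequence:
    """Build a sequence from a configuration string.

    Accepted forms: ``"lord-default"``, ``"power:<s>"``, ``"power+1:<s>"``,
    ``"uniform"``.
    """
    spec = spec.strip().lower()
    if spec == "lord-default":
        return lord_default_sequence(bound=bound)
    if spec == "uniform":
        return uniform_sequence(bound=bound)
    if spec.startswith("power+1:"):
        return power_law_sequence(float(spec.split(":", 1)[1]), offset=1, bound=bound)
    if spec.startswith("power:"):
        return power_law_sequence(float(spec.split(":", 1)[1]), offset=0, bound=bound)
    raise ValueError(f"unrecognized spending sequence spec: {spec!r}")


# -- single-weight convenience functions -----------------------------------


def lord_default_gamma(t: int, bound: float = math.inf) -> float:
    """Weight at index ``t >= 1`` of the (possibly bounded) default sequence."""
    if t < 1:
        raise ValueError("index t must be >= 1")
    return lord_default_sequence(bound=bound).weight(t)


def power_law_gamma(t: int, exponent: float, offset: int = 0, bound: float = math.inf) -> float:
    seq = power_law_sequence(exponent, offset=offset, bound=bound)
    return seq.weight(t)


def uniform_gamma(t: int, bound: float) -> float:
    if t < 1:
        raise ValueError("index t must be >= 1")
    return uniform_sequence(bound).weight(t)
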