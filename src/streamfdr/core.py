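"""Generalized alpha-investing substrate: decision rule, wealth ledger,
payout cap, and the FDP estimators that the level policies keep below alpha.

Every online policy in :mod:`streamfdr.fdr` and :mod:`streamfdr.fwer`
produces a :class:`DecisionLog`: an ordered record of per-hypothesis
(p-value, test level, rejection, wealth-after) tuples plus the level that
would apply to the next, not-yet-seen hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WealthError",
    "DecisionRecord",
    "DecisionLog",
    "StreamState",
    "decide",
    "update_wealth",
    "gai_pp_payout_cap",
    "fdp_hat_lord",
    "fdp_hat_saffron",
]


class WealthError(ValueError):
    """Raised when a testing price exceeds the available alpha-wealth."""


def decide(p: float, alpha_t: float) -> int:
    """The online decision rule: reject (1) iff ``p <= alpha_t``.

    Ties reject.  Both arguments must lie in [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if not 0.0 <= alpha_t <= 1.0:
        raise ValueError(f"test level {alpha_t!r} outside [0, 1]")
    return int(p <= alpha_t)


def update_wealth(wealth: float, price: float, payout: float, reject: int) -> float:
    """One step of the wealth recursion ``W(t) = W(t-1) - price + R_t * payout``.

    The price may never exceed the current wealth; violating configurations
    raise :class:`WealthError` rather than silently producing negative wealth.
    """
    if price < 0:
        raise ValueError("price must be non-negative")
    if price > wealth + 1e-12:
        raise WealthError(f"price {price} exceeds available wealth {wealth}")
    return wealth - price + (payout if reject else 0.0)


def gai_pp_payout_cap(price: float, alpha_t: float, b_t: float) -> float:
    """Largest admissible payout for a rejection under the GAI++ constraint.

    Returns ``min(price + b_t, price / alpha_t + b_t - 1)``, clamped at 0.
    With ``alpha_t == 0`` the second bound is vacuous (infinite) and only the
    first applies.  Degenerate inputs (zero price at small levels) clamp to 0.
    """
    first = price + b_t
    if alpha_t > 0:
        cap = min(first, price / alpha_t + b_t - 1.0)
    else:
        cap = first
    return max(cap, 0.0)


def fdp_hat_lord(levels, n_rejections: int) -> float:
    """LORD-style FDP estimate: sum of emitted levels over ``R(t) v 1``."""
    total = float(np.sum(np.asarray(levels, dtype=float)))
    return total / max(int(n_rejections), 1)


def fdp_hat_saffron(levels, candidates, lam: float, n_rejections: int) -> float:
    """SAFFRON-style FDP estimate.

    ``sum_j alpha_j * 1{P_j > lambda} / (1 - lambda)`` over ``R(t) v 1``;
    only non-candidate steps contribute to the numerator.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    levels = np.asarray(levels, dtype=float)
    noncand = ~np.asarray(candidates, dtype=bool)
    total = float((levels[noncand]).sum()) / (1.0 - lam)
    return total / max(int(n_rejections), 1)


@dataclass
class StreamState:
    """Mutable per-run record shared by all level policies.

    Policies attach their own bookkeeping via ``extra``; the fields here are
    the auditable ledger: per-step levels, prices, payouts, and indicator
    sequences, plus the running wealth and rejection times.
    """

    t: int = 0
    wealth: float = 0.0
    rejection_times: list = field(default_factory=list)
    levels: list = field(default_factory=list)
    prices: list = field(default_factory=list)
    payouts: list = field(default_factory=list)
    rejected: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    selected: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def record(self, alpha_t, price, payout, reject, candidate, selected) -> None:
        self.t += 1
        self.levels.append(alpha_t)
        self.prices.append(price)
        self.payouts.append(payout)
        self.rejected.append(int(reject))
        self.candidates.append(int(candidate))
        self.selected.append(int(selected))
        if reject:
            self.rejection_times.append(self.t)
        self.wealth = update_wealth(self.wealth, price, payout, reject)
        if self.wealth < -1e-12:
            raise WealthError(f"wealth went negative at t={self.t}: {self.wealth}")
        self.wealth = max(self.wealth, 0.0)

    @property
    def n_rejections(self) -> int:
        return len(self.rejection_times)


@dataclass(frozen=True)
class DecisionRecord:
    index: int
    id: str
    pval: float
    alpha: float
    reject: int
    wealth: float

    def __post_init__(self):
        if self.reject != int(self.pval <= self.alpha):
            raise ValueError(
                f"inconsistent record at index {self.index}: "
                f"reject={self.reject} but p={self.pval}, alpha={self.alpha}"
            )


@dataclass
class DecisionLog:
    """Ordered per-hypothesis decisions for a whole run.

    ``next_level`` is the test level that would apply to the hypothesis
    after the last one processed.
    """

    records: list
    next_level: float
    algorithm: str = ""
    config: dict = field(default_factory=dict)
    batches: list | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rejected_ids(self) -> list:
        return [r.id for r in self.records if r.reject]

    @property
    def n_rejections(self) -> int:
        return sum(r.reject for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "index": [r.index for r in self.records],
                "id": [r.id for r in self.records],
                "pval": [r.pval for r in self.records],
                "alpha": [r.alpha for r in self.records],
                "reject": [r.reject for r in self.records],
                "wealth": [r.wealth for r in self.records],
            }
        )
        if self.batches is not None:
            frame["batch"] = list(self.batches)
        return frame
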