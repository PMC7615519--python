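"""Online FWER control: Bonferroni-type alpha-spending and the online
Sidak method.

FWER policies never earn wealth back (``psi_t = 0``); the ledger records
the fraction of the overall budget consumed at each step.  The online
Sidak level ``1 - (1 - alpha)**gamma_t`` dominates the alpha-spending
level ``alpha * gamma_t`` pointwise for any weight in [0, 1].
"""

from __future__ import annotations

from .core import StreamState, decide
from .fdr import AlphaSpending
from .spending import SpendingSequence

__all__ = ["FwerAlphaSpending", "OnlineSidak", "online_sidak_level", "fwer_alpha_spending_level"]


class FwerAlphaSpending(AlphaSpending):
    """Alpha-spending viewed as an online FWER procedure (same levels)."""

    name = "fwer-alpha-spending"


class OnlineSidak(AlphaSpending):
    """Online Sidak: tests ``H_t`` at level ``1 - (1 - alpha)**gamma_t``."""

    name = "sidak"

    def level(self, state: StreamState) -> float:
        g = self._gamma(state, state.t + 1)
        return 1.0 - (1.0 - self.alpha) ** g

    def observe(self, state, p, ledger=True):
        alpha_t = self.level(state)
        reject = decide(p, alpha_t)
        if ledger:
            # ledger spend is the budget fraction alpha * gamma_t, so the
            # wealth trajectory stays non-negative even though the emitted
            # Sidak levels sum to more than alpha
            g = self._gamma(state, state.t + 1)
            state.record(alpha_t, self.alpha * g, 0.0, reject, 1, 1)
        else:
            state.t += 1
        return alpha_t, reject


def online_sidak_level(t: int, alpha: float, sequence: SpendingSequence) -> float:
    """Closed-form online Sidak level at step ``t`` (1-based)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    g = sequence.weight(t) if t >= sequence.start else 0.0
    return 1.0 - (1.0 - alpha) ** g


def fwer_alpha_spending_level(t: int, alpha: float, sequence: SpendingSequence) -> float:
    """Bonferroni-type spending level ``alpha * gamma_t`` at step ``t``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha * (sequence.weight(t) if t >= sequence.start else 0.0)
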