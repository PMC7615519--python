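"""Online FDR level policies: alpha-spending, LORD, LORD++, SAFFRON, ADDIS,
monotone alpha-investing, plus the uncorrected baseline and a stream runner.

Each policy exposes the same small surface:

``start(horizon=None)``
    Fresh :class:`~streamfdr.core.StreamState`.
``level(state)``
    The test level for the upcoming hypothesis (a pure read).
``observe(state, p)``
    Decide on one p-value and advance the state (wealth ledger included).
``run(pvals, ids=None)``
    Convenience driver returning a :class:`~streamfdr.core.DecisionLog`
    that also reports the level the *next* hypothesis would get.

Internally every wealth-earning policy is expressed through a shared
allocation schedule: each wealth source (the initial wealth, then each
rejection) spreads its reward over future steps according to the spending
sequence, on a policy-specific clock.  LORD-type policies tick the clock on
every step; SAFFRON ticks only on non-candidates (``p > lambda``); ADDIS
ticks only on selected non-candidates (``lambda < p <= eta``), which is
what makes discarded p-values invisible to all future levels.
"""

from __future__ import annotations

import math

import numpy as np

from .core import DecisionLog, DecisionRecord, StreamState, decide
from .spending import (
    SpendingSequence,
    lord_default_sequence,
    power_law_sequence,
    sequence_from_spec,
)

__all__ = [
    "OnlinePolicy",
    "Uncorrected",
    "AlphaSpending",
    "LordOriginal",
    "LordPlusPlus",
    "Saffron",
    "Addis",
    "MonotoneAlphaInvesting",
    "make_policy",
    "run_stream",
    "POLICY_NAMES",
]


class _Schedule:
    """Allocation curve A[c] = sum over sources of reward * gamma(c - offset).

    ``c`` is the policy clock.  Sources are retained so the curve can be
    rebuilt when it grows past its current capacity.
    """

    __slots__ = ("seq", "gamma", "curve", "sources", "start")

    def __init__(self, seq: SpendingSequence, capacity: int):
        self.seq = seq
        self.start = seq.start
        capacity = max(capacity, 16)
        self.gamma = seq.weights(capacity)
        self.curve = np.zeros(capacity)
        self.sources: list[tuple[float, int]] = []

    def _grow(self, needed: int) -> None:
        capacity = max(needed + 1, 2 * len(self.curve))
        self.gamma = self.seq.weights(capacity)
        self.curve = np.zeros(capacity)
        sources, self.sources = self.sources, []
        for reward, offset in sources:
            self.add(reward, offset)

    def add(self, reward: float, offset: int) -> None:
        lo = offset + self.start
        if lo >= len(self.curve):
            self._grow(lo)
        n = len(self.curve) - lo
        self.curve[lo:] += reward * self.gamma[:n]
        self.sources.append((reward, offset))

    def value(self, c: int) -> float:
        if c >= len(self.curve):
            self._grow(c)
        return float(self.curve[c])


class OnlinePolicy:
    """Base class for online level policies."""

    name = "base"

    def __init__(self, alpha: float):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.alpha = alpha

    # -- subclass hooks ----------------------------------------------------

    def start(self, horizon: int | None = None) -> StreamState:
        raise NotImplementedError

    def level(self, state: StreamState) -> float:
        raise NotImplementedError

    def observe(self, state: StreamState, p: float, ledger: bool = True):
        raise NotImplementedError

    # -- drivers -----------------------------------------------------------

    def run(self, pvals, ids=None, batches=None) -> DecisionLog:
        """Process a whole stream, returning the auditable decision log."""
        pvals = list(pvals)
        for i, p in enumerate(pvals, 1):
            if not (isinstance(p, (int, float)) and 0.0 <= p <= 1.0):
                raise ValueError(f"invalid p-value at index {i}: {p!r}")
        if ids is None:
            ids = [str(i) for i in range(1, len(pvals) + 1)]
        state = self.start(horizon=len(pvals) + 1)
        records = []
        for i, (hid, p) in enumerate(zip(ids, pvals), 1):
            alpha_t, reject = self.observe(state, float(p))
            records.append(DecisionRecord(i, hid, float(p), alpha_t, reject, state.wealth))
        return DecisionLog(
            records,
            next_level=self.level(state),
            algorithm=self.name,
            config=self.describe(),
            batches=list(batches) if batches is not None else None,
        )

    def run_array(self, pvals: np.ndarray):
        """Fast path for simulations: (levels, rejections), no ledger."""
        state = self.start(horizon=len(pvals) + 1)
        n = len(pvals)
        alphas = np.empty(n)
        rejects = np.zeros(n, dtype=bool)
        observe = self.observe
        for i in range(n):
            a, r = observe(state, float(pvals[i]), ledger=False)
            alphas[i] = a
            rejects[i] = r
        return alphas, rejects

    def describe(self) -> dict:
        return {"algorithm": self.name, "alpha": self.alpha}


class Uncorrected(OnlinePolicy):
    """No multiplicity adjustment: ``alpha_t = alpha`` for every t."""

    name = "uncorrected"

    def start(self, horizon=None):
        return StreamState(wealth=0.0)

    def level(self, state):
        return self.alpha

    def observe(self, state, p, ledger=True):
        reject = decide(p, self.alpha)
        if ledger:
            state.record(self.alpha, 0.0, 0.0, reject, 1, 1)
        else:
            state.t += 1
        return self.alpha, reject


class AlphaSpending(OnlinePolicy):
    """Bonferroni-type correction: ``alpha_t = alpha * gamma_t``.

    Controls the FWER (and hence the FDR); no wealth is ever earned back.
    """

    name = "alpha-spending"

    def __init__(self, alpha: float, sequence: SpendingSequence | None = None):
        super().__init__(alpha)
        self.sequence = sequence if sequence is not None else lord_default_sequence()

    def start(self, horizon=None):
        state = StreamState(wealth=self.alpha)
        state.extra["gamma"] = self.sequence.weights(max(horizon or 0, 64))
        return state

    def _gamma(self, state, t):
        g = state.extra["gamma"]
        if t > len(g):
            g = state.extra["gamma"] = self.sequence.weights(2 * t)
        return float(g[t - 1])

    def level(self, state):
        return self.alpha * self._gamma(state, state.t + 1)

    def observe(self, state, p, ledger=True):
        alpha_t = self.level(state)
        reject = decide(p, alpha_t)
        if ledger:
            state.record(alpha_t, alpha_t, 0.0, reject, 1, 1)
        else:
            state.t += 1
        return alpha_t, reject

    def describe(self):
        return {
            "algorithm": self.name,
            "alpha": self.alpha,
            "sequence": self.sequence.kind,
            "bound": self.sequence.bound,
        }


class _WealthPolicy(OnlinePolicy):
    """Shared machinery for the schedule-based (generalized alpha-investing)
    policies.  Subclasses define the clock, candidacy, scaling and rewards."""

    #: gamma sequence used when none is supplied
    def _default_sequence(self) -> SpendingSequence:
        raise NotImplementedError

    def __init__(self, alpha, w0, sequence):
        super().__init__(alpha)
        self.w0 = w0
        self.sequence = sequence if sequence is not None else self._default_sequence()

    def start(self, horizon=None):
        state = StreamState(wealth=self._initial_wealth())
        sched = _Schedule(self.sequence, capacity=(horizon or 0) + 2)
        sched.add(self.w0, 0)
        state.extra["sched"] = sched
        state.extra["clock"] = 0
        state.extra["nrej"] = 0
        return state

    # hooks ---------------------------------------------------------------

    def _initial_wealth(self) -> float:
        return self.w0

    def _scale_and_cap(self, bracket: float) -> float:
        raise NotImplementedError

    def _ticks(self, p: float, alpha_t: float) -> bool:
        """Whether this step advances the clock (i.e. spends wealth)."""
        raise NotImplementedError

    def _flags(self, p: float, alpha_t: float) -> tuple[int, int]:
        """(candidate, selected) indicators for the ledger."""
        return 1, 1

    def _price(self, alpha_t: float, ticked: bool) -> float:
        return alpha_t if ticked else 0.0

    def _payout(self, first: bool) -> float:
        raise NotImplementedError

    # mechanics ------------------------------------------------------------

    def level(self, state):
        sched = state.extra["sched"]
        bracket = sched.value(state.extra["clock"] + sched.start)
        return self._scale_and_cap(bracket)

    def observe(self, state, p, ledger=True):
        alpha_t = self.level(state)
        reject = decide(p, alpha_t)
        ticked = self._ticks(p, alpha_t)
        if ticked:
            state.extra["clock"] += 1
        payout = 0.0
        if reject:
            first = state.extra["nrej"] == 0
            state.extra["nrej"] += 1
            payout = self._payout(first)
            state.extra["sched"].add(self._bracket_reward(first), state.extra["clock"])
        if ledger:
            cand, sel = self._flags(p, alpha_t)
            state.record(alpha_t, self._price(alpha_t, ticked), payout, reject, cand, sel)
        else:
            state.t += 1
        return alpha_t, reject

    def _bracket_reward(self, first: bool) -> float:
        """Reward as it enters the level formula (unscaled)."""
        raise NotImplementedError

    def describe(self):
        return {
            "algorithm": self.name,
            "alpha": self.alpha,
            "w0": self.w0,
            "sequence": self.sequence.kind,
            "bound": self.sequence.bound,
        }


class LordOriginal(_WealthPolicy):
    """The original LORD rule: every rejection earns a fixed reward ``b0``.

    Requires ``w0 + b0 <= alpha``.
    """

    name = "lord"

    def __init__(self, alpha, w0=None, b0=None, sequence=None):
        w0 = alpha / 10 if w0 is None else w0
        b0 = alpha - w0 if b0 is None else b0
        if w0 < 0 or b0 < 0 or w0 + b0 > alpha + 1e-12:
            raise ValueError("LORD requires w0 >= 0, b0 >= 0 and w0 + b0 <= alpha")
        self.b0 = b0
        super().__init__(alpha, w0, sequence)

    def _default_sequence(self):
        return lord_default_sequence()

    def _scale_and_cap(self, bracket):
        return min(bracket, 1.0)

    def _ticks(self, p, alpha_t):
        return True

    def _payout(self, first):
        return self.b0

    def _bracket_reward(self, first):
        return self.b0

    def describe(self):
        d = super().describe()
        d["b0"] = self.b0
        return d


class LordPlusPlus(_WealthPolicy):
    """LORD++: earns ``alpha - w0`` for the first rejection, ``alpha`` after.

    Requires ``0 <= w0 <= alpha``.  With no rejections it coincides with
    alpha-spending at rate ``w0``.
    """

    name = "lordpp"

    def __init__(self, alpha, w0=None, sequence=None):
        w0 = alpha / 10 if w0 is None else w0
        if not 0.0 <= w0 <= alpha:
            raise ValueError("LORD++ requires 0 <= w0 <= alpha")
        super().__init__(alpha, w0, sequence)

    def _default_sequence(self):
        return lord_default_sequence()

    def _scale_and_cap(self, bracket):
        return min(bracket, 1.0)

    def _ticks(self, p, alpha_t):
        return True

    def _payout(self, first):
        return (self.alpha - self.w0) if first else self.alpha

    _bracket_reward = _payout


class Saffron(_WealthPolicy):
    """SAFFRON: adaptive online FDR control via candidate p-values.

    Candidates are ``p <= lambda``; non-candidates can never be rejected and
    are the only steps that consume wealth.  Levels are capped at ``lambda``.
    """

    name = "saffron"

    def __init__(self, alpha, w0=None, lam=0.5, sequence=None):
        w0 = alpha / 2 if w0 is None else w0
        if not 0.0 < lam < 1.0:
            raise ValueError("lambda must lie in (0, 1)")
        if not 0.0 <= w0 <= alpha:
            raise ValueError("SAFFRON requires 0 <= w0 <= alpha")
        self.lam = lam
        super().__init__(alpha, w0, sequence)

    def _default_sequence(self):
        return power_law_sequence(1.6, offset=0)

    def _initial_wealth(self):
        return (1.0 - self.lam) * self.w0

    def _scale_and_cap(self, bracket):
        return min(self.lam, (1.0 - self.lam) * bracket)

    def _ticks(self, p, alpha_t):
        return p > self.lam

    def _flags(self, p, alpha_t):
        return int(p <= self.lam), 1

    def _payout(self, first):
        return (1.0 - self.lam) * self._bracket_reward(first)

    def _bracket_reward(self, first):
        return (self.alpha - self.w0) if first else self.alpha

    def describe(self):
        d = super().describe()
        d["lambda"] = self.lam
        return d


class Addis(_WealthPolicy):
    """ADDIS: adaptivity plus discarding of conservative nulls.

    p-values above ``eta`` are discarded outright and leave every future
    level unchanged; candidates are ``p <= lambda`` with ``lambda < eta``.
    The spending sequence is indexed from 0.
    """

    name = "addis"

    def __init__(self, alpha, w0=None, lam=0.25, eta=0.5, sequence=None):
        w0 = alpha / 2 if w0 is None else w0
        if not 0.0 < lam < eta <= 1.0:
            raise ValueError("ADDIS requires 0 < lambda < eta <= 1")
        if not 0.0 <= w0 <= alpha:
            raise ValueError("ADDIS requires 0 <= w0 <= alpha")
        self.lam = lam
        self.eta = eta
        super().__init__(alpha, w0, sequence)

    def _default_sequence(self):
        return power_law_sequence(1.6, offset=1)

    def _initial_wealth(self):
        return (self.eta - self.lam) * self.w0

    def _scale_and_cap(self, bracket):
        return min(self.lam, (self.eta - self.lam) * bracket)

    def _ticks(self, p, alpha_t):
        return self.lam < p <= self.eta

    def _flags(self, p, alpha_t):
        return int(p <= self.lam), int(p <= self.eta)

    def _payout(self, first):
        return (self.eta - self.lam) * self._bracket_reward(first)

    def _bracket_reward(self, first):
        return (self.alpha - self.w0) if first else self.alpha

    def describe(self):
        d = super().describe()
        d["lambda"] = self.lam
        d["eta"] = self.eta
        return d


class MonotoneAlphaInvesting(_WealthPolicy):
    """Monotone alpha-investing, built as the adaptive recursion with the
    candidacy threshold at each step equal to the emitted level itself.

    The level solves the one-dimensional fixed point
    ``alpha_t = (1 - alpha_t) * B_t``, i.e. ``alpha_t = B_t / (1 + B_t)``,
    where ``B_t`` is the scheduled allocation; the clock advances only when
    ``p > alpha_t`` (a non-rejection spend).
    """

    name = "alpha-investing"

    def __init__(self, alpha, w0=None, sequence=None):
        w0 = alpha / 2 if w0 is None else w0
        if not 0.0 <= w0 <= alpha:
            raise ValueError("alpha-investing requires 0 <= w0 <= alpha")
        super().__init__(alpha, w0, sequence)

    def _default_sequence(self):
        return power_law_sequence(1.6, offset=0)

    def _scale_and_cap(self, bracket):
        return bracket / (1.0 + bracket)

    def _ticks(self, p, alpha_t):
        return p > alpha_t

    def _flags(self, p, alpha_t):
        return int(p <= alpha_t), 1

    def _price(self, alpha_t, ticked):
        # price in bracket units: alpha_t = (1 - alpha_t) * B_t
        return alpha_t / (1.0 - alpha_t) if ticked else 0.0

    def _payout(self, first):
        return self._bracket_reward(first)

    def _bracket_reward(self, first):
        return (self.alpha - self.w0) if first else self.alpha


POLICY_NAMES = (
    "uncorrected",
    "alpha-spending",
    "lord",
    "lordpp",
    "saffron",
    "addis",
    "ai",
    "sidak",
)


def make_policy(
    name: str,
    alpha: float = 0.05,
    bound: float = math.inf,
    w0: float | None = None,
    b0: float | None = None,
    lam: float | None = None,
    eta: float | None = None,
    gamma: str | None = None,
) -> OnlinePolicy:
    """Build a policy by CLI-style name with its documented defaults.

    ``bound`` truncates-and-renormalizes the spending sequence at ``M``;
    ``gamma`` overrides the default sequence family (e.g. ``"power:1.6"``).
    """
    from .fwer import OnlineSidak  # local import to avoid a cycle

    name = name.lower()

    def seq(default_spec: str) -> SpendingSequence:
        return sequence_from_spec(gamma or default_spec, bound=bound)

    if name == "uncorrected":
        return Uncorrected(alpha)
    if name == "alpha-spending":
        default = "uniform" if math.isfinite(bound) and gamma is None else "lord-default"
        return AlphaSpending(alpha, sequence=seq(default))
    if name == "lord":
        return LordOriginal(alpha, w0=w0, b0=b0, sequence=seq("lord-default"))
    if name == "lordpp":
        return LordPlusPlus(alpha, w0=w0, sequence=seq("lord-default"))
    if name == "saffron":
        return Saffron(alpha, w0=w0, lam=0.5 if lam is None else lam, sequence=seq("power:1.6"))
    if name == "addis":
        return Addis(
            alpha,
            w0=w0,
            lam=0.25 if lam is None else lam,
            eta=0.5 if eta is None else eta,
            sequence=seq("power+1:1.6"),
        )
    if name == "ai":
        return MonotoneAlphaInvesting(alpha, w0=w0, sequence=seq("power:1.6"))
    if name == "sidak":
        default = "uniform" if math.isfinite(bound) and gamma is None else "lord-default"
        return OnlineSidak(alpha, sequence=seq(default))
    raise ValueError(f"unknown algorithm {name!r}; choose from {POLICY_NAMES}")


def run_stream(pvals, policy: OnlinePolicy, ids=None, batches=None) -> DecisionLog:
    """Apply ``policy`` stepwise to an ordered p-value stream."""
    return policy.run(pvals, ids=ids, batches=batches)
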