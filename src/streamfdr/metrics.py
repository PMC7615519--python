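"""Error-rate and power estimators over labeled decision logs.

A :class:`LabeledLog` pairs the per-hypothesis rejection indicators of one
replicate with ground-truth null / non-null labels.  The estimators follow
the standard conventions: FDP denominators are floored at one, the mFDR is
a ratio of expectations (not an expectation of ratios), and the FDX is the
probability that the running supremum of the FDP reaches the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledLog",
    "MetricsReport",
    "fdp",
    "fdr_estimate",
    "mfdr_estimate",
    "fdx_estimate",
    "fwer_estimate",
    "power_estimate",
    "proportion_se",
    "summarize",
]


@dataclass(frozen=True)
class LabeledLog:
    """Rejections and truth labels for one replicate, aligned by index."""

    rejected: np.ndarray
    nonnull: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rejected, dtype=bool)
        h = np.asarray(self.nonnull, dtype=bool)
        if r.shape != h.shape or r.ndim != 1:
            raise ValueError("rejected and nonnull must be 1-d arrays of equal length")
        object.__setattr__(self, "rejected", r)
        object.__setattr__(self, "nonnull", h)

    def __len__(self) -> int:
        return len(self.rejected)


def _horizon(log: LabeledLog, T: int | None) -> int:
    n = len(log)
    if T is None:
        return n
    if not 0 <= T <= n:
        raise ValueError(f"T={T} outside [0, {n}]")
    return T


def fdp(log: LabeledLog, T: int | None = None) -> float:
    """False discovery proportion ``V(T) / (R(T) v 1)``."""
    T = _horizon(log, T)
    r = log.rejected[:T]
    v = int((r & ~log.nonnull[:T]).sum())
    return v / max(int(r.sum()), 1)


def proportion_se(p: float, n: int) -> float:
    """Monte-Carlo standard error of a proportion: ``sqrt(p(1-p)/n)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.sqrt(p * (1.0 - p) / n)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = len(values)
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(values.mean()), se


def fdr_estimate(logs, T: int | None = None) -> tuple[float, float]:
    """FDR (mean per-replicate FDP) with its Monte-Carlo standard error."""
    return _mean_se([fdp(log, T) for log in logs])


def mfdr_estimate(logs, T: int | None = None) -> float:
    """Marginal FDR: ``E[V] / E[R v 1]`` across replicates."""
    vs, rs = [], []
    for log in logs:
        t = _horizon(log, T)
        r = log.rejected[:t]
        vs.append(int((r & ~log.nonnull[:t]).sum()))
        rs.append(max(int(r.sum()), 1))
    return float(np.mean(vs) / np.mean(rs))


def fdx_estimate(logs, eps: float, T: int | None = None) -> tuple[float, float]:
    """FDX(eps): fraction of replicates whose running-max FDP reaches eps."""
    hits = []
    for log in logs:
        t = _horizon(log, T)
        r = log.rejected[:t].astype(int)
        v = (r & ~log.nonnull[:t]).astype(int)
        running = np.cumsum(v) / np.maximum(np.cumsum(r), 1)
        sup = float(running.max()) if t else 0.0
        hits.append(sup >= eps)
    return _mean_se(np.asarray(hits, dtype=float))


def fwer_estimate(logs, T: int | None = None) -> tuple[float, float]:
    """FWER: fraction of replicates with at least one false rejection."""
    hits = []
    for log in logs:
        t = _horizon(log, T)
        hits.append(bool((log.rejected[:t] & ~log.nonnull[:t]).any()))
    return _mean_se(np.asarray(hits, dtype=float))


def power_estimate(logs, T: int | None = None) -> tuple[float, float]:
    """Mean fraction of non-null hypotheses rejected (denominator floored)."""
    fracs = []
    for log in logs:
        t = _horizon(log, T)
        h1 = log.nonnull[:t]
        fracs.append(int((log.rejected[:t] & h1).sum()) / max(int(h1.sum()), 1))
    return _mean_se(fracs)


@dataclass
class MetricsReport:
    """Point estimates with Monte-Carlo SEs across replicates."""

    fdr: float
    fdr_se: float
    mfdr: float
    fwer: float
    fwer_se: float
    power: float
    power_se: float
    fdx: float = float("nan")
    fdx_se: float = float("nan")
    fdx_eps: float = float("nan")
    n_replicates: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fdr": self.fdr,
            "fdr_se": self.fdr_se,
            "mfdr": self.mfdr,
            "fwer": self.fwer,
            "fwer_se": self.fwer_se,
            "power": self.power,
            "power_se": self.power_se,
            "fdx": self.fdx,
            "fdx_se": self.fdx_se,
            "n_replicates": self.n_replicates,
        }


def summarize(logs, T: int | None = None, fdx_eps: float | None = None) -> MetricsReport:
    """All error-rate and power estimates for a set of replicate logs."""
    logs = list(logs)
    fdr, fdr_se = fdr_estimate(logs, T)
    fwer, fwer_se = fwer_estimate(logs, T)
    power, power_se = power_estimate(logs, T)
    report = MetricsReport(
        fdr=fdr,
        fdr_se=fdr_se,
        mfdr=mfdr_estimate(logs, T),
        fwer=fwer,
        fwer_se=fwer_se,
        power=power,
        power_se=power_se,
        n_replicates=len(logs),
    )
    if fdx_eps is not None:
        report.fdx, report.fdx_se = fdx_estimate(logs, fdx_eps, T)
        report.fdx_eps = fdx_eps
    return report
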