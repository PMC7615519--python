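"""Gaussian simulation testbed for power / error-rate experiments.

Streams of one-sided p-values are generated from a two-group mixture over
test-statistic means: with probability ``pi1`` the mean is drawn from the
alternative law (default ``N(3, 1)``), otherwise from the null law (a
point mass at 0, or a conservative ``N(-0.5, sd=0.1)``).  The observation
is ``Z ~ N(mu, 1)`` and the p-value is ``P = Phi(-Z)``.

Seeding uses one master seed that spawns an independent child stream per
replicate, so any single replicate is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fdr import OnlinePolicy, make_policy
from .metrics import LabeledLog, summarize

__all__ = ["SimulationConfig", "generate_stream", "simulate_policy", "run_experiment"]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulation cell.

    ``null_kind`` is ``"point"`` (mean exactly 0 under the null) or
    ``"gaussian"`` with location ``null_loc`` and standard deviation
    ``null_scale``.  ``null_scale_is_variance=True`` reinterprets
    ``null_scale`` as a variance instead.
    """

    T: int = 1000
    pi1: float = 0.5
    null_kind: str = "gaussian"
    null_loc: float = -0.5
    null_scale: float = 0.1
    null_scale_is_variance: bool = False
    alt_loc: float = 3.0
    alt_scale: float = 1.0
    replicates: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must lie in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.null_kind not in ("point", "gaussian"):
            raise ValueError("null_kind must be 'point' or 'gaussian'")
        if self.null_scale < 0 or self.alt_scale < 0:
            raise ValueError("scales must be non-negative")

    @property
    def null_sd(self) -> float:
        if self.null_kind == "point":
            return 0.0
        s = self.null_scale
        return float(np.sqrt(s)) if self.null_scale_is_variance else float(s)


def generate_stream(config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """One labeled stream: (p-values, non-null indicator array).

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    rng = np.random.default_rng(rng)
    T = config.T
    nonnull = rng.random(T) < config.pi1
    mu = np.empty(T)
    n1 = int(nonnull.sum())
    mu[nonnull] = rng.normal(config.alt_loc, config.alt_scale, n1)
    if config.null_kind == "point":
        mu[~nonnull] = 0.0
    else:
        mu[~nonnull] = rng.normal(config.null_loc, config.null_sd, T - n1)
    z = rng.normal(mu, 1.0)
    pvals = norm.sf(z)
    return pvals, nonnull


def _replicate_rngs(config: SimulationConfig):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(config.replicates)]


def simulate_policy(config: SimulationConfig, policy: OnlinePolicy) -> list[LabeledLog]:
    """Run one policy over every replicate stream of a simulation cell."""
    logs = []
    for rng in _replicate_rngs(config):
        pvals, nonnull = generate_stream(config, rng)
        if policy.name == "uncorrected":
            rejects = pvals <= policy.alpha
        else:
            _, rejects = policy.run_array(pvals)
        logs.append(LabeledLog(rejects, nonnull))
    return logs


def run_experiment(
    config: SimulationConfig,
    algorithms,
    pi1_grid=None,
    alpha: float = 0.05,
    fdx_eps: float | None = None,
) -> pd.DataFrame:
    """Power/FDR table over a (pi1, algorithm) grid.

    ``algorithms`` is a list of policy names (see
    :func:`streamfdr.fdr.make_policy`) or ready-made policy objects.
    Every cell reuses the same per-replicate random streams.
    """
    pi1_grid = [config.pi1] if pi1_grid is None else list(pi1_grid)
    rows = []
    for pi1 in pi1_grid:
        cell = replace(config, pi1=pi1)
        for alg in algorithms:
            policy = make_policy(alg, alpha=alpha) if isinstance(alg, str) else alg
            report = summarize(simulate_policy(cell, policy), fdx_eps=fdx_eps)
            row = {"pi1": pi1, "algorithm": policy.name, "T": cell.T,
                   "replicates": cell.replicates, **report.to_dict()}
            rows.append(row)
    return pd.DataFrame(rows)
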