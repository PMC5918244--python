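"""Models of competing beneficial mutations along an adapting lineage.

The fitness trajectory of a population adapting under diminishing-returns
epistasis follows the power law W(t) = (a t + 1)^b.  Combining this with
an empirical accumulation curve for beneficial mutations, n = c sqrt(t)
(equivalently t_n = (n/c)^2 for the n-th mutation), yields a schedule of
the generation t_n at which each successive beneficial mutation fixes in
the winning lineage and its selection coefficient
s_n = W(t_n) - W(t_{n-1}).  A newly arising mutation (such as one
activating citT) is predicted to be able to drive its own sweep only when
its fitness effect exceeds s(t), the effect of a typical successful
competing mutation at that time.

A second schedule built from explicit sweep recurrences (successive
cohorts of beneficial mutations) is exposed as a plug-in interface only;
its defining equations are external to this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

#: default parameters: power-law fit for the citrate population (a, b),
#: beneficial-mutation accumulation coefficient for non-mutator
#: populations (c), and sweep-model inputs (alpha0, mu, pop_n).
DEFAULT_A = 0.0842
DEFAULT_B = 0.00611
DEFAULT_C = 0.135
DEFAULT_ALPHA0 = 58.4
DEFAULT_MU = 1e-7
DEFAULT_POP_N = 3.3e7


@dataclass(frozen=True)
class TrajectoryParams:
    a: float = DEFAULT_A          # per generation
    b: float = DEFAULT_B          # dimensionless exponent
    c: float = DEFAULT_C          # mutations per sqrt(generation)
    alpha0: float = DEFAULT_ALPHA0
    mu: float = DEFAULT_MU        # beneficial mutations per genome per generation
    pop_n: float = DEFAULT_POP_N  # effective population size

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not (0 < self.b < 1):
            raise ValueError("b must be in (0, 1)")
        if self.c <= 0:
            raise ValueError("c must be > 0")


@dataclass(frozen=True)
class MutationSchedule:
    """(n, t_n, s_n) for successive beneficial mutations of one model."""

    entries: tuple  # of (n, t_n, s_n)
    model_tag: str  # tenaillon_derived | wiser_plugin

    def __post_init__(self) -> None:
        ts = [t for _, t, _ in self.entries]
        if any(b <= a for a, b in zip(ts, ts[1:])) or (ts and ts[0] <= 0):
            raise ValueError("t_n must be strictly increasing and positive")
        if any(s <= 0 for _, _, s in self.entries):
            raise ValueError("selection coefficients must be > 0")

    @property
    def t_max(self) -> float:
        return self.entries[-1][1]

    def s_at(self, t: float) -> float:
        """Step-function selection coefficient at generation t.

        Right-continuous in n: value s_n on the interval (t_{n-1}, t_n].
        Raises if t lies beyond the schedule.
        """
        if t < 0:
            raise ValueError("t must be >= 0")
        for _, t_n, s_n in self.entries:
            if t <= t_n:
                return s_n
        raise ValueError(
            f"t = {t:.0f} beyond schedule end t = {self.t_max:.0f}; extend n_max"
        )


def fitness_trajectory(t: float, params: TrajectoryParams = TrajectoryParams()) -> float:
    """Population mean fitness W(t) = (a t + 1)^b relative to the ancestor."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return (params.a * t + 1.0) ** params.b

def beneficial_count(t: float, params: TrajectoryParams = TrajectoryParams()) -> float:
    """Expected beneficial mutations accumulated by generation t: n = c sqrt(t)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return params.c * math.sqrt(t)


def mutation_schedule(
    params: TrajectoryParams = TrajectoryParams(), n_max: int | None = None
) -> MutationSchedule:
    """Schedule from the accumulation curve: t_n = (n/c)^2, s_n telescoping.

    s_n = W(t_n) - W(t_{n-1}) with t_0 = 0, so sum(s_n, n <= N) telescopes
    to W(t_N) - 1 exactly.  By default n_max is chosen so the schedule
    covers at least 40,000 generations.
    """
    if n_max is None:
        n_max = math.ceil(params.c * math.sqrt(40_000.0))
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    entries = []
    w_prev = 1.0  # W(t_0 = 0)
    for n in range(1, n_max + 1):
        t_n = (n / params.c) ** 2
        w_n = fitness_trajectory(t_n, params)
        entries.append((n, t_n, w_n - w_prev))
        w_prev = w_n
    return MutationSchedule(entries=tuple(entries), model_tag="tenaillon_derived")


#: registry for sweep-model plug-ins implementing the explicit cohort
#: recurrences.  A plugin maps (alpha0, mu, pop_n) -> iterable of (t, s).
_SWEEP_PLUGINS: dict[str, Callable] = {}


def register_sweep_plugin(name: str, fn: Callable) -> None:
    _SWEEP_PLUGINS[name] = fn


def sweep_model_schedule(
    params: TrajectoryParams = TrajectoryParams(), plugin: str | Callable | None = None
) -> MutationSchedule:
    """Schedule of successive sweeping cohorts, delegated to a plug-in.

    The cohort-sweep recurrences are defined outside this package; supply
    a registered plugin name or a callable ``f(alpha0, mu, pop_n)``
    yielding (t, s) pairs.  Output is contract-checked (t strictly
    increasing, s > 0).
    """
    if plugin is None:
        raise ValueError(
            "no sweep-model plugin registered: the cohort-sweep recurrences "
            "(Model 1) are not implemented in this package; register one with "
            "register_sweep_plugin() or pass a callable"
        )
    fn = _SWEEP_PLUGINS[plugin] if isinstance(plugin, str) else plugin
    pairs = list(fn(params.alpha0, params.mu, params.pop_n))
    entries = tuple((n + 1, t, s) for n, (t, s) in enumerate(pairs))
    return MutationSchedule(entries=entries, model_tag="wiser_plugin")


@dataclass(frozen=True)
class EpochVerdict:
    strains: tuple
    gen_start: float
    gen_end: float
    s_group: float
    s_model: tuple  # s(t) at (gen_start, midpoint, gen_end)
    verdict: str    # driver | suppressed | marginal
    conservative_driver: bool  # CI lower bound clears the model everywhere


def epoch_vs_model(groups, schedule: MutationSchedule) -> list[EpochVerdict]:
    """Compare each epoch group's fitness effect to the competing-mutation model.

    s_group = pooled effect - 1 is compared to the model step function at
    the group's start, midpoint, and end generations.  ``driver`` when the
    group effect exceeds the model at all three (a citT activation then
    beats a typical successful competing mutation and can sweep on its own
    merits), ``suppressed`` when below at all three, ``marginal``
    otherwise.  ``conservative_driver`` additionally requires the CI lower
    bound to clear the model at all three points.
    """
    cluster_groups = getattr(groups, "groups", groups)
    verdicts = []
    for g in cluster_groups:
        t0, t1 = g.gen_start, g.gen_end
        mid = 0.5 * (t0 + t1)
        s_model = tuple(schedule.s_at(t) for t in (t0, mid, t1))
        s_group = g.pooled_point - 1.0
        if all(s_group > s for s in s_model):
            verdict = "driver"
        elif all(s_group < s for s in s_model):
            verdict = "suppressed"
        else:
            verdict = "marginal"
        conservative = all(g.pooled_ci[0] - 1.0 > s for s in s_model)
        verdicts.append(
            EpochVerdict(
                strains=tuple(g.strains), gen_start=t0, gen_end=t1,
                s_group=s_group, s_model=s_model, verdict=verdict,
                conservative_driver=conservative,
            )
        )
    return verdicts
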