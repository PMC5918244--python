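"""Bootstrap and t-test machinery for combining competition assays.

The fitness effect of activating citT in a strain is measured by two
competitions: the Cit competition (Cit+ construct vs Cit- construct,
which carries both the effect of interest and the Ara marker) and the
Ara competition (marker control).  The combined effect is the product of
the two mean fitnesses; uncertainty is propagated by resampling the two
replicate sets independently, B = 10,000 times by default, and taking
percentile intervals of the product of resampled means.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_B = 10_000
DEFAULT_CI_LEVEL = 0.95


def strain_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-strain RNG substream from a global seed.

    Derived from (seed, crc32(label)) so results do not depend on the
    order in which strains are processed.
    """
    return np.random.default_rng([seed, zlib.crc32(label.encode("utf-8"))])


@dataclass(frozen=True)
class ReplicateSet:
    """Per-replicate W values for one strain pair and competition class."""

    label: str
    values: tuple
    competition_class: str = "cit_effect"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if any(v <= 0 for v in self.values):
            raise ValueError(f"{self.label}: all W values must be > 0")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    b_reps: int
    ci_level: float
    ci_lo: float
    ci_hi: float
    draws: np.ndarray = field(repr=False)
    seed: int | None = None


@dataclass(frozen=True)
class CombinedEffect:
    """A strain's citT-activation fitness effect: product of Cit and Ara means."""

    strain: str
    w_combined: float
    boot: BootstrapResult
    n_cit: int
    n_ara: int


@dataclass(frozen=True)
class TestResult:
    p: float
    tail: str  # lower | upper | two_sided
    null_value: float
    method: str  # bootstrap | t_test

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"p must be in (0, 1], got {self.p}")


def _percentile_ci(draws: np.ndarray, point: float, ci_level: float) -> tuple[float, float]:
    alpha = 1 - ci_level
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    if not (lo <= point <= hi):
        logger.warning(
            "percentile CI [%g, %g] excludes point estimate %g (skewed resamples)",
            lo, hi, point,
        )
    return float(lo), float(hi)


def bootstrap_estimate(
    values,
    b_reps: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> BootstrapResult:
    """Bootstrap the sample mean: resample n values with replacement B times."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"need >= 2 values to bootstrap, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b_reps, n))
    draws = values[idx].mean(axis=1)
    point = float(values.mean())
    ci_lo, ci_hi = _percentile_ci(draws, point, ci_level)
    return BootstrapResult(
        point=point, b_reps=b_reps, ci_level=ci_level,
        ci_lo=ci_lo, ci_hi=ci_hi, draws=draws,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def combined_cit_effect(
    cit: ReplicateSet,
    ara: ReplicateSet,
    b_reps: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
    ci_level: float = DEFAULT_CI_LEVEL,
    strain: str | None = None,
) -> CombinedEffect:
    """Combine Cit and Ara competitions into one fitness effect.

    Point estimate is mean(cit) x mean(ara); each bootstrap draw resamples
    the two replicate sets independently and multiplies the resampled
    means (the two competitions are unpaired experiments).
    """
    if ara.competition_class != "ara_marker":
        raise ValueError(
            f"ara replicate set has class {ara.competition_class!r}, expected 'ara_marker'"
        )
    if cit.competition_class not in ("cit_effect", "population_context"):
        raise ValueError(
            f"cit replicate set has class {cit.competition_class!r}, "
            "expected 'cit_effect' or 'population_context'"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cit_v = np.asarray(cit.values)
    ara_v = np.asarray(ara.values)
    if cit_v.size < 2 or ara_v.size < 2:
        raise ValueError("both replicate sets need n >= 2")
    cit_means = cit_v[rng.integers(0, cit_v.size, size=(b_reps, cit_v.size))].mean(axis=1)
    ara_means = ara_v[rng.integers(0, ara_v.size, size=(b_reps, ara_v.size))].mean(axis=1)
    draws = cit_means * ara_means
    point = float(cit_v.mean() * ara_v.mean())
    ci_lo, ci_hi = _percentile_ci(draws, point, ci_level)
    boot = BootstrapResult(
        point=point, b_reps=b_reps, ci_level=ci_level,
        ci_lo=ci_lo, ci_hi=ci_hi, draws=draws,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
    return CombinedEffect(
        strain=strain or cit.label, w_combined=point, boot=boot,
        n_cit=cit_v.size, n_ara=ara_v.size,
    )


def _draws_of(eff: CombinedEffect | BootstrapResult) -> np.ndarray:
    boot = eff.boot if isinstance(eff, CombinedEffect) else eff
    return boot.draws


def bootstrap_test_vs_null(
    eff: CombinedEffect | BootstrapResult,
    null_value: float = 1.0,
    tail: str = "two_sided",
) -> TestResult:
    """Bootstrap p-value against a point null.

    Uses the add-one correction (k + 1) / (B + 1) so p is never exactly 0;
    ties at the null count toward both tails.
    """
    draws = _draws_of(eff)
    b = draws.size
    p_lower = (np.count_nonzero(draws <= null_value) + 1) / (b + 1)
    p_upper = (np.count_nonzero(draws >= null_value) + 1) / (b + 1)
    if tail == "lower":
        p = p_lower
    elif tail == "upper":
        p = p_upper
    elif tail == "two_sided":
        p = min(1.0, 2 * min(p_lower, p_upper))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult(p=float(p), tail=tail, null_value=null_value, method="bootstrap")


def pairwise_difference_test(
    eff1: CombinedEffect | BootstrapResult,
    eff2: CombinedEffect | BootstrapResult,
    tail: str = "two_sided",
) -> TestResult:
    """Two-sided bootstrap test of effect1 - effect2 = 0.

    Difference draws pair draw b of each effect; the two sets of draws
    were generated by independent resampling, so the pairing is an
    independent product sample.
    """
    d1, d2 = _draws_of(eff1), _draws_of(eff2)
    if d1.size != d2.size:
        raise ValueError(f"draw counts differ ({d1.size} vs {d2.size}); re-draw with shared B")
    delta = d1 - d2
    boot = BootstrapResult(
        point=float(delta.mean()), b_reps=delta.size, ci_level=DEFAULT_CI_LEVEL,
        ci_lo=float(np.quantile(delta, 0.025)), ci_hi=float(np.quantile(delta, 0.975)),
        draws=delta,
    )
    res = bootstrap_test_vs_null(boot, null_value=0.0, tail=tail)
    return TestResult(p=res.p, tail=tail, null_value=0.0, method="bootstrap")


def threshold_benefit_test(
    eff: CombinedEffect | BootstrapResult, threshold: float = 1.01
) -> TestResult:
    """One-tailed test of H0: effect >= threshold (default 1% benefit).

    p = (#{draws >= threshold} + 1) / (B + 1).  When p >= 0.05 the data
    cannot rule out a benefit of (threshold - 1) or greater.
    """
    draws = _draws_of(eff)
    b = draws.size
    p = (np.count_nonzero(draws >= threshold) + 1) / (b + 1)
    return TestResult(p=float(p), tail="upper", null_value=threshold, method="bootstrap")


def t_test_fitness(
    values1,
    values2=None,
    null_value: float | None = None,
    tail: str = "two_sided",
) -> TestResult:
    """Welch two-sample t-test, or one-sample t-test against a null value.

    Degenerate zero-variance samples with equal means give p = 1.
    """
    v1 = np.asarray(values1, dtype=float)
    if v1.size < 2:
        raise ValueError("need >= 2 values in each sample")
    if values2 is not None:
        v2 = np.asarray(values2, dtype=float)
        if v2.size < 2:
            raise ValueError("need >= 2 values in each sample")
        if v1.std(ddof=1) == 0 and v2.std(ddof=1) == 0 and v1.mean() == v2.mean():
            return TestResult(p=1.0, tail=tail, null_value=0.0, method="t_test")
        t, p_two = stats.ttest_ind(v1, v2, equal_var=False)
        null = 0.0
        direction = v1.mean() - v2.mean()
    else:
        if null_value is None:
            raise ValueError("provide values2 or null_value")
        if v1.std(ddof=1) == 0 and v1.mean() == null_value:
            return TestResult(p=1.0, tail=tail, null_value=null_value, method="t_test")
        t, p_two = stats.ttest_1samp(v1, null_value)
        null = null_value
        direction = v1.mean() - null_value
    if tail == "two_sided":
        p = p_two
    elif tail == "upper":
        p = p_two / 2 if direction > 0 else 1 - p_two / 2
    elif tail == "lower":
        p = p_two / 2 if direction < 0 else 1 - p_two / 2
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult(p=float(min(max(p, np.nextafter(0, 1)), 1.0)), tail=tail,
                      null_value=null, method="t_test")
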