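"""Resampling estimation of the invisible-fraction bias.

The bias statistic is the difference in mean first-flowering day between
a "control" (descendant) cohort and an "aged" (ancestral) cohort, each
assembled from first- and last-priority flowering-day pools.  Unequal
storage survival of the two priority groups skews the aged cohort's
priority mix; if the pools differ in mean, the skew biases the ancestral
mean estimate.  Two resampling designs quantify this:

* ``simulation_one`` draws both cohorts' priority mixes from observed
  survival rates (what the experiment actually implies);
* ``simulation_two`` sweeps the aged cohort's first:last ratio over a
  grid (50:50 .. 95:5) against a 50:50 control, mapping bias against the
  strength of the priority effect on survival.

``end_to_end_replay`` wires the phenology simulator and the storage
sieve into a full resurrection-experiment replay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from seedsieve.phenology import (
    Plant,
    SurvivalModel,
    add_phenotypes,
    apply_storage,
    assign_priority,
    simulate_seed_cohort,
)
from seedsieve.toy_model import GenotypeValueMap

_CHUNK = 10_000  # iterations per vectorised block (memory cap)


@dataclass(frozen=True)
class ResampleConfig:
    """Settings shared by the resampling simulations.

    ``sample_size_per_cohort`` defaults to 245, one experimental
    treatment x priority group; ``n_iterations`` defaults to 10,000
    resamples.
    """

    n_iterations: int = 10_000
    sample_size_per_cohort: int = 245
    with_replacement: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.sample_size_per_cohort < 1:
            raise ValueError("sample_size_per_cohort must be >= 1")


@dataclass
class BiasResult:
    """Per-iteration bias values (days) plus config echo.

    Sign convention: bias = control mean - aged mean; positive when the
    aged (ancestral) cohort appears to flower earlier than it should.
    """

    biases: np.ndarray
    config: ResampleConfig
    fraction_first_aged: Optional[float] = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.biases))

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the mean bias."""
        n = len(self.biases)
        if n < 2:
            return float("nan")
        return float(np.std(self.biases, ddof=1) / np.sqrt(n))

    def summary(self) -> Dict[str, float]:
        q = np.quantile(self.biases, [0.025, 0.975])
        out = {
            "n_iterations": len(self.biases),
            "mean": self.mean,
            "min": float(np.min(self.biases)),
            "max": float(np.max(self.biases)),
            "q2.5": float(q[0]),
            "q97.5": float(q[1]),
            "mc_se": self.mc_se,
        }
        if self.fraction_first_aged is not None:
            out["fraction_first_aged"] = self.fraction_first_aged
        return out


def summary_frame(results: Iterable[BiasResult]) -> pd.DataFrame:
    """Stack ``BiasResult.summary()`` rows into one table."""
    return pd.DataFrame([r.summary() for r in results])


def bias_statistic(control_mean: float, aged_mean: float) -> float:
    """Invisible-fraction bias in days: control mean minus aged mean."""
    return float(control_mean) - float(aged_mean)


def _pool_arrays(pools: Mapping[str, Sequence[float]]) -> Tuple[np.ndarray, np.ndarray]:
    try:
        first = np.asarray(pools["first"], dtype=float)
        last = np.asarray(pools["last"], dtype=float)
    except KeyError as exc:
        raise ValueError("pools must provide 'first' and 'last' entries") from exc
    if first.size == 0 or last.size == 0:
        raise ValueError("both priority pools must be nonempty")
    if np.isnan(first).any() or np.isnan(last).any():
        raise ValueError("pools must not contain NaN (exclude censored upstream)")
    return first, last


def _sample_cohort_means(
    first: np.ndarray,
    last: np.ndarray,
    p_first: float,
    n: int,
    iters: int,
    rng: np.random.Generator,
    *,
    fixed_counts: bool,
    with_replacement: bool = True,
) -> np.ndarray:
    """Means of ``iters`` cohorts of size n mixing the two priority pools.

    ``fixed_counts`` pins the first:last split at round(n * p_first) every
    iteration; otherwise each seed's priority is an independent Bernoulli
    draw at ``p_first``.
    """
    means = np.empty(iters, dtype=float)
    done = 0
    while done < iters:
        m = min(_CHUNK, iters - done)
        if fixed_counts:
            k = int(round(n * p_first))
            f = _draw(rng, first, (m, k), with_replacement)
            l = _draw(rng, last, (m, n - k), with_replacement)
            means[done : done + m] = (f.sum(axis=1) + l.sum(axis=1)) / n
        else:
            take_first = rng.random((m, n)) < p_first
            f = _draw(rng, first, (m, n), with_replacement)
            l = _draw(rng, last, (m, n), with_replacement)
            means[done : done + m] = np.where(take_first, f, l).mean(axis=1)
        done += m
    return means


def _draw(rng, pool, shape, with_replacement):
    if with_replacement:
        return pool[rng.integers(0, len(pool), size=shape)]
    if shape[1] > len(pool):
        raise ValueError(
            "cannot draw without replacement: cohort slice exceeds pool size"
        )
    out = np.empty(shape, dtype=float)
    for i in range(shape[0]):
        out[i] = rng.choice(pool, size=shape[1], replace=False)
    return out


def survival_mix_fraction(
    survival_props: Mapping[Tuple[str, str], float], treatment: str
) -> float:
    """First-priority share of a cohort whose mix follows survival rates."""
    s_first = float(survival_props[(treatment, "first")])
    s_last = float(survival_props[(treatment, "last")])
    tot = s_first + s_last
    if tot == 0.0:
        raise ValueError(f"survival proportions for {treatment!r} are all zero")
    return s_first / tot


def simulation_one(
    f2_pools: Mapping[str, Sequence[float]],
    survival_props: Mapping[Tuple[str, str], float],
    config: ResampleConfig = ResampleConfig(),
    aged_pools: Optional[Mapping[str, Sequence[float]]] = None,
) -> BiasResult:
    """Bias under the priority mix implied by observed survivorship.

    Each iteration draws a control cohort whose first:last mix follows
    the control survival rates and an aged cohort whose mix follows the
    aged rates (each of ``sample_size_per_cohort`` seeds, priorities
    drawn per seed), takes cohort means as if priority were unknown, and
    records control mean - aged mean.

    Both cohorts draw from ``f2_pools`` (the design's default: control
    flowering days only); pass ``aged_pools`` to source the aged cohort
    from its own treatment's pools instead.
    """
    first, last = _pool_arrays(f2_pools)
    first_a, last_a = (first, last) if aged_pools is None else _pool_arrays(aged_pools)
    p_ctrl = survival_mix_fraction(survival_props, "control")
    p_aged = survival_mix_fraction(survival_props, "aged")
    rng = np.random.default_rng([int(config.rng_seed), 1])
    n, iters = config.sample_size_per_cohort, config.n_iterations
    ctrl = _sample_cohort_means(
        first, last, p_ctrl, n, iters, rng,
        fixed_counts=False, with_replacement=config.with_replacement,
    )
    aged = _sample_cohort_means(
        first_a, last_a, p_aged, n, iters, rng,
        fixed_counts=False, with_replacement=config.with_replacement,
    )
    return BiasResult(biases=ctrl - aged, config=config, fraction_first_aged=p_aged)


def simulation_two(
    f2_pools: Mapping[str, Sequence[float]],
    config: ResampleConfig = ResampleConfig(),
    fraction_grid: Optional[Sequence[float]] = None,
) -> List[BiasResult]:
    """Bias across a sweep of survival asymmetries (the bias surface).

    Control cohorts mix the pools 50:50; aged cohorts at each grid value
    of the first-priority fraction (default 0.50 .. 0.95 in steps of
    0.05), with fixed counts so the ratio is exact.  Aged and control
    cohorts share the same size so that mortality alone (independent of
    priority) cannot create a difference.
    """
    first, last = _pool_arrays(f2_pools)
    if fraction_grid is None:
        fraction_grid = np.round(np.arange(0.50, 0.951, 0.05), 10)
    fraction_grid = [float(f) for f in fraction_grid]
    if any(not 0.0 <= f <= 1.0 for f in fraction_grid):
        raise ValueError("fraction grid values must lie in [0, 1]")
    n, iters = config.sample_size_per_cohort, config.n_iterations
    results = []
    for gi, frac in enumerate(fraction_grid):
        rng = np.random.default_rng([int(config.rng_seed), 2, gi])
        ctrl = _sample_cohort_means(
            first, last, 0.5, n, iters, rng,
            fixed_counts=True, with_replacement=config.with_replacement,
        )
        aged = _sample_cohort_means(
            first, last, frac, n, iters, rng,
            fixed_counts=True, with_replacement=config.with_replacement,
        )
        results.append(
            BiasResult(biases=ctrl - aged, config=config, fraction_first_aged=frac)
        )
    return results


def end_to_end_replay(
    population: Sequence[Plant],
    seeds_per_dam: int,
    values: GenotypeValueMap,
    survival_model: SurvivalModel,
    config: ResampleConfig = ResampleConfig(n_iterations=8),
    *,
    treatment: str = "aged",
    first_fraction: float = 0.5,
    last_fraction: float = 0.5,
    env_sd: float = 0.0,
    exclude_self: bool = True,
) -> BiasResult:
    """Full resurrection-experiment replay through the phenology simulator.

    Per iteration: simulate an ancestral seed cohort, label priorities,
    pass it through the storage sieve, and take the survivors' mean
    flowering day as the "aged" estimate; simulate an independent,
    unselected cohort from the same population as the "descendant"
    (control) mean.  The recorded bias is control mean - aged mean, so a
    sieve that kills late-allele-enriched seeds yields a positive bias.
    """
    biases = np.empty(config.n_iterations, dtype=float)
    for it in range(config.n_iterations):
        base = int(config.rng_seed) + 7919 * it
        anc, _ = simulate_seed_cohort(
            population, seeds_per_dam, rng_seed=base, exclude_self=exclude_self
        )
        anc = assign_priority(anc, first_fraction, last_fraction)
        anc = apply_storage(anc, survival_model, treatment=treatment, rng_seed=base + 1)
        anc = add_phenotypes(anc, values, env_sd=env_sd, rng_seed=base + 2)
        survivors = anc.loc[anc["survived_storage"], "flowering_day"]
        if survivors.empty:
            raise ValueError("storage sieve left no ancestral survivors")
        desc, _ = simulate_seed_cohort(
            population, seeds_per_dam, rng_seed=base + 3, exclude_self=exclude_self
        )
        desc = add_phenotypes(desc, values, env_sd=env_sd, rng_seed=base + 4)
        biases[it] = bias_statistic(desc["flowering_day"].mean(), survivors.mean())
    return BiasResult(biases=biases, config=config)
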