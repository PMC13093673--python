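"""Stochastic flowering-season simulator with a storage sieve.

Generates seed cohorts whose sire genotypes depend on when each seed's
flower opened: a dam's early flowers can only be pollinated by plants
that are already flowering, so in a population where the early line
starts ~14 days ahead of the late line, the pollen pool shifts from
early-line to late-line over the season.  Seeds are then ranked by birth
order within each dam, labelled by provisioning priority (first / middle
/ last), and passed through a storage-survival model in which survival
may depend on priority — the selective sieve.

Cohorts are plain pandas DataFrames with the column schema in
``COHORT_COLUMNS``; one row is one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from seedsieve.toy_model import GenotypeValueMap

COHORT_COLUMNS = [
    "seed_id",
    "dam_id",
    "dam_line",
    "dam_genotype",
    "sire_genotype",
    "genotype",
    "birth_time",
    "birth_rank",
    "priority",
    "survived_storage",
]


@dataclass(frozen=True)
class FloweringSchedule:
    """Flower-deployment density of one plant over the season.

    ``uniform`` spreads flowers evenly over [onset, onset+duration];
    ``triangular`` peaks at the midpoint (unit area in both cases).
    Times are days; day 0 is germination of the parental generation.
    """

    onset: float
    duration: float
    shape: str = "uniform"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.shape not in ("uniform", "triangular"):
            raise ValueError(f"unknown density shape {self.shape!r}")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def density(self, t) -> np.ndarray:
        """Open-flower density at time(s) t; zero outside the schedule."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.onset) & (t <= self.end)
        if self.shape == "uniform":
            d = inside / self.duration
        else:
            mid = self.onset + self.duration / 2.0
            d = np.where(
                inside,
                (2.0 / self.duration)
                * (1.0 - np.abs(t - mid) / (self.duration / 2.0)),
                0.0,
            )
        return d

    def sample_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.shape == "uniform":
            return rng.uniform(self.onset, self.end, size=n)
        mid = self.onset + self.duration / 2.0
        return rng.triangular(self.onset, mid, self.end, size=n)


@dataclass(frozen=True)
class Plant:
    id: str
    line: str  # "EE" or "LL"
    genotype: str
    schedule: FloweringSchedule
    block: str = "1"

    def __post_init__(self) -> None:
        if self.line not in ("EE", "LL"):
            raise ValueError(f"line must be 'EE' or 'LL', got {self.line!r}")


@dataclass(frozen=True)
class SurvivalModel:
    """Storage-survival probabilities by aging treatment and seed priority.

    ``probs`` maps ``(treatment, priority)`` to a survival probability;
    middle-priority seeds use the mean of the first and last
    probabilities for their treatment.
    """

    probs: Dict[Tuple[str, str], float]

    def __post_init__(self) -> None:
        for key, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival probability {key} = {p} outside [0, 1]")

    def s(self, treatment: str, priority: str) -> float:
        if priority == "middle":
            return 0.5 * (
                self.probs[(treatment, "first")] + self.probs[(treatment, "last")]
            )
        try:
            return self.probs[(treatment, priority)]
        except KeyError:
            raise KeyError(
                f"no survival probability for ({treatment!r}, {priority!r})"
            ) from None

    @classmethod
    def default(cls) -> "SurvivalModel":
        """Germination-rate defaults: 99% control, 78%/68% aged first/last.

        The aged mean (~0.73) sits 26 points below control, with a 10-point
        first-vs-last gap under aging.
        """
        return cls(
            probs={
                ("control", "first"): 0.99,
                ("control", "last"): 0.99,
                ("aged", "first"): 0.78,
                ("aged", "last"): 0.68,
            }
        )


def open_flower_density(plant: Plant, t) -> np.ndarray:
    """Open-flower density of one plant at time(s) t (1/days)."""
    return plant.schedule.density(t)


class NoOpenFlowersError(ValueError):
    """Raised when the pollen-pool composition is requested at a time with
    no open flowers in the (dam-excluded) population."""


def pollen_pool_fraction_L(
    population: Sequence[Plant],
    t,
    exclude_dam: Optional[str] = None,
    *,
    missing: str = "nan",
):
    """Late-line (LL) share of the pollen pool at time(s) t.

    The pool is weighted by open-flower density, summed over plants;
    ``exclude_dam`` removes one plant's own flowers (obligate outcrosser).
    Where no flowers are open the result is NaN (``missing="nan"``, the
    default, distinguishable from a true 0) or an error
    (``missing="raise"``).
    """
    if not population:
        raise ValueError("population is empty")
    t_arr = np.asarray(t, dtype=float)
    total = np.zeros_like(t_arr, dtype=float)
    late = np.zeros_like(t_arr, dtype=float)
    for plant in population:
        if exclude_dam is not None and plant.id == exclude_dam:
            continue
        d = plant.schedule.density(t_arr)
        total = total + d
        if plant.line == "LL":
            late = late + d
    none_open = total == 0.0
    if missing == "raise" and np.any(none_open):
        raise NoOpenFlowersError(f"no open flowers at t={t!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(none_open, np.nan, late / np.where(none_open, 1.0, total))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(frac)
    return frac


def _offspring_genotype(dam_line: str, sire_is_late: np.ndarray) -> np.ndarray:
    """Genotype of offspring of a homozygous dam given sire-line flags."""
    if dam_line == "EE":
        return np.where(sire_is_late, "EL", "EE")
    return np.where(sire_is_late, "LL", "EL")


def simulate_seed_cohort(
    population: Sequence[Plant],
    seeds_per_dam: int,
    rng_seed: int = 0,
    *,
    exclude_self: bool = True,
) -> Tuple[pd.DataFrame, int]:
    """Simulate one season's seed cohort over all dams in the population.

    For each dam, ``seeds_per_dam`` birth times are drawn from its
    flower-deployment density and ranked to give birth order; each seed's
    sire line is drawn from the pollen pool at its birth time (the dam's
    own flowers excluded unless ``exclude_self=False``), and the offspring
    genotype follows the Mendelian single-locus cross.  Seeds born when no
    compatible sire is flowering are dropped and counted, not selfed.

    Returns ``(cohort, n_skipped)`` where ``cohort`` has the
    ``COHORT_COLUMNS`` schema (``priority`` and ``survived_storage``
    initialised to ``"unassigned"`` / ``True``).  Deterministic for a
    fixed ``rng_seed``: each dam gets a sub-stream derived from the seed
    and its index, so results do not depend on cohort-level ordering.
    """
    if seeds_per_dam < 1:
        raise ValueError("seeds_per_dam must be >= 1")
    frames: List[pd.DataFrame] = []
    n_skipped = 0
    for dam_idx, dam in enumerate(population):
        rng = np.random.default_rng([int(rng_seed), dam_idx])
        times = np.sort(dam.schedule.sample_times(seeds_per_dam, rng))
        frac_L = pollen_pool_fraction_L(
            population, times, exclude_dam=dam.id if exclude_self else None
        )
        frac_L = np.atleast_1d(np.asarray(frac_L, dtype=float))
        ok = ~np.isnan(frac_L)
        n_skipped += int((~ok).sum())
        if not ok.any():
            continue
        times_ok = times[ok]
        sire_is_late = rng.random(ok.sum()) < frac_L[ok]
        n = len(times_ok)
        frames.append(
            pd.DataFrame(
                {
                    "seed_id": [f"{dam.id}:{k}" for k in range(1, n + 1)],
                    "dam_id": dam.id,
                    "dam_line": dam.line,
                    "dam_genotype": dam.genotype,
                    "sire_genotype": np.where(sire_is_late, "LL", "EE"),
                    "genotype": _offspring_genotype(dam.line, sire_is_late),
                    "birth_time": times_ok,
                    "birth_rank": np.arange(1, n + 1),
                    "priority": "unassigned",
                    "survived_storage": True,
                }
            )
        )
    if frames:
        cohort = pd.concat(frames, ignore_index=True)
    else:
        cohort = pd.DataFrame(
            {c: pd.Series(dtype=object) for c in COHORT_COLUMNS}
        )
    return cohort, n_skipped


def assign_priority(
    cohort: pd.DataFrame, first_fraction: float = 0.25, last_fraction: float = 0.25
) -> pd.DataFrame:
    """Label each seed first / middle / last by its within-dam birth rank.

    Per dam with n seeds, the lowest-rank ``ceil(n * first_fraction)``
    seeds are ``first`` and the highest-rank ``ceil(n * last_fraction)``
    are ``last``; the remainder are ``middle``.  Deterministic.
    """
    if first_fraction < 0 or last_fraction < 0:
        raise ValueError("priority fractions must be nonnegative")
    if first_fraction + last_fraction > 1.0 + 1e-12:
        raise ValueError("first_fraction + last_fraction must not exceed 1")
    cohort = cohort.copy()
    labels = np.full(len(cohort), "middle", dtype=object)
    for _, idx in cohort.groupby("dam_id", sort=False).indices.items():
        n = len(idx)
        ranks = cohort["birth_rank"].to_numpy()[idx]
        order = np.argsort(ranks, kind="stable")
        n_first = math.ceil(n * first_fraction)
        n_last = math.ceil(n * last_fraction)
        if n_first + n_last > n:  # ceiling overlap on tiny dams
            n_last = n - n_first
        labels[idx[order[:n_first]]] = "first"
        if n_last > 0:
            labels[idx[order[n - n_last:]]] = "last"
    cohort["priority"] = labels
    return cohort


def apply_storage(
    cohort: pd.DataFrame,
    model: SurvivalModel,
    treatment: str = "aged",
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Draw storage survival for every seed, independently per seed.

    Survival probability is ``model.s(treatment, priority)``; requires
    priorities to have been assigned.
    """
    if (cohort["priority"] == "unassigned").any():
        raise ValueError("assign_priority must run before apply_storage")
    cohort = cohort.copy()
    rng = np.random.default_rng([int(rng_seed), 104729])
    p = cohort["priority"].map(
        {prio: model.s(treatment, prio) for prio in ("first", "middle", "last")}
    )
    cohort["survived_storage"] = rng.random(len(cohort)) < p.to_numpy(dtype=float)
    return cohort


def phenotype(
    genotype,
    values: GenotypeValueMap,
    env_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Flowering day of one genotype: genetic value plus Gaussian noise.

    With ``env_sd=0`` this reduces to the deterministic genotype value.
    Accepts a scalar genotype or an array of genotypes.
    """
    if env_sd < 0:
        raise ValueError("env_sd must be >= 0")
    scalar = isinstance(genotype, str)
    geno = np.atleast_1d(np.asarray(genotype, dtype=object))
    base = np.array([values.value(g) for g in geno], dtype=float)
    if env_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        base = base + rng.normal(0.0, env_sd, size=base.shape)
    return float(base[0]) if scalar else base


def add_phenotypes(
    cohort: pd.DataFrame,
    values: GenotypeValueMap,
    env_sd: float = 0.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Attach a ``flowering_day`` phenotype column to a seed cohort."""
    cohort = cohort.copy()
    rng = np.random.default_rng([int(rng_seed), 224737])
    cohort["flowering_day"] = phenotype(
        cohort["genotype"].to_numpy(dtype=object), values, env_sd, rng
    )
    return cohort
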