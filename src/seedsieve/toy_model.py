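"""Deterministic single-locus model of the mating/storage-sieve mechanism.

A population carries two flowering-time lines: early homozygotes (``EE``)
and late homozygotes (``LL``), with partially dominant heterozygotes
(``EL``).  Because plants can only exchange pollen while co-flowering,
the sire pool available to a seed depends on when its flower opened:
first-produced seeds on early dams see only early pollen, last-produced
seeds see a mixture, and symmetrically for late dams.  If storage then
kills last-produced (poorly provisioned) seeds preferentially, the
survivors carry fewer late alleles than the cohort that entered storage,
and the mean flowering time estimated from survivors is biased early.

This module computes that bias exactly for the four dam-line x priority
seed batches, by enumeration over (batch, sire class, offspring genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Literal, Mapping, Optional, Sequence, Union

Genotype = Literal["EE", "EL", "LL"]
GENOTYPES: tuple = ("EE", "EL", "LL")

#: Allele contributed by each homozygous line.
_LINE_ALLELE = {"EE": "E", "LL": "L"}

_DIST_TOL = 1e-12


@dataclass(frozen=True)
class GenotypeValueMap:
    """Flowering-time genetic values (days from germination) per genotype.

    Defaults encode an early line at 10 days, a late line at 30 days and a
    partially dominant heterozygote at 20 days.
    """

    value_EE: float = 10.0
    value_EL: float = 20.0
    value_LL: float = 30.0

    def __post_init__(self) -> None:
        vals = (self.value_EE, self.value_EL, self.value_LL)
        if not all(v == v and abs(v) != float("inf") for v in vals):
            raise ValueError("genotype values must be finite")
        if not (self.value_EE <= self.value_EL <= self.value_LL):
            raise ValueError(
                "genotype values must satisfy EE <= EL <= LL "
                f"(got {vals})"
            )

    def value(self, genotype: str) -> float:
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}")
        return getattr(self, f"value_{genotype}")

    def as_dict(self) -> Dict[str, float]:
        return {g: self.value(g) for g in GENOTYPES}


@dataclass(frozen=True)
class SirePool:
    """Composition of the pollen pool: shares of early- and late-line sires."""

    p_EE: float
    p_LL: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_EE <= 1.0 and 0.0 <= self.p_LL <= 1.0):
            raise ValueError("sire-pool proportions must lie in [0, 1]")
        if abs(self.p_EE + self.p_LL - 1.0) > _DIST_TOL:
            raise ValueError("sire-pool proportions must sum to 1")


@dataclass
class SeedBatch:
    """One dam-line x priority cell of the seed crop.

    ``offspring_dist`` is the Mendelian offspring genotype distribution,
    ``weight`` the batch's share of all seeds produced, and ``survival``
    its probability of surviving storage.
    """

    dam_line: str
    priority: str
    offspring_dist: Dict[str, float]
    weight: float = 0.25
    survival: float = 1.0

    def __post_init__(self) -> None:
        if self.dam_line not in ("EE", "LL"):
            raise ValueError(f"dam_line must be 'EE' or 'LL', got {self.dam_line!r}")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("survival must lie in [0, 1]")
        total = sum(self.offspring_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"offspring distribution sums to {total}, not 1")
        # a homozygous dam can only transmit its own allele
        forbidden = "LL" if self.dam_line == "EE" else "EE"
        if self.offspring_dist.get(forbidden, 0.0) > _DIST_TOL:
            raise ValueError(
                f"{self.dam_line} dam cannot produce {forbidden} offspring"
            )

    def mean_value(self, values: GenotypeValueMap) -> float:
        """Expected flowering time of a seed from this batch."""
        return sum(p * values.value(g) for g, p in self.offspring_dist.items())


def cross_distribution(dam_line: str, sire_pool: SirePool) -> Dict[str, float]:
    """Offspring genotype distribution for a homozygous dam and a sire pool.

    The dam transmits its line allele; the sire allele is E with
    probability ``p_EE`` and L with probability ``p_LL`` (both sire lines
    are homozygous, so every gamete carries the line allele).
    """
    if dam_line not in _LINE_ALLELE:
        raise ValueError(f"dam_line must be 'EE' or 'LL', got {dam_line!r}")
    dam_allele = _LINE_ALLELE[dam_line]
    dist = {g: 0.0 for g in GENOTYPES}
    for sire_allele, p in (("E", sire_pool.p_EE), ("L", sire_pool.p_LL)):
        alleles = "".join(sorted(dam_allele + sire_allele))
        genotype = {"EE": "EE", "EL": "EL", "LL": "LL"}[alleles]
        dist[genotype] += p
    return {g: p for g, p in dist.items() if p > 0.0}


def assortative_batches(
    mix_first_on_LL: float = 0.5,
    mix_last_on_EE: float = 0.5,
    weights: Optional[Sequence[float]] = None,
    survival: Optional[Mapping[str, float]] = None,
) -> list:
    """Build the four seed batches produced under temporally assortative mating.

    The flowering season orders the batches' sire pools: first seeds on
    early (EE) dams are sired only by early plants, last seeds on early
    dams by a mixed pool (``mix_last_on_EE`` = late share), first seeds on
    late (LL) dams by a mixed pool (``mix_first_on_LL`` = early share),
    and last seeds on late dams only by late plants.

    Parameters
    ----------
    mix_first_on_LL, mix_last_on_EE
        Share of the *other* line in the two mixed pools; 0.5 is the
        symmetric default.
    weights
        Seed share of the four batches in order (EE,first), (EE,last),
        (LL,first), (LL,last); defaults to equal (0.25 each).
    survival
        Optional mapping ``{"first": p, "last": p}`` applied as each
        batch's storage-survival probability (default 1.0 everywhere).
    """
    for name, p in (("mix_first_on_LL", mix_first_on_LL),
                    ("mix_last_on_EE", mix_last_on_EE)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if weights is None:
        weights = (0.25, 0.25, 0.25, 0.25)
    if len(weights) != 4:
        raise ValueError("weights must have length 4")
    pools = [
        ("EE", "first", SirePool(p_EE=1.0, p_LL=0.0)),
        ("EE", "last", SirePool(p_EE=1.0 - mix_last_on_EE, p_LL=mix_last_on_EE)),
        ("LL", "first", SirePool(p_EE=mix_first_on_LL, p_LL=1.0 - mix_first_on_LL)),
        ("LL", "last", SirePool(p_EE=0.0, p_LL=1.0)),
    ]
    batches = []
    for (dam, prio, pool), w in zip(pools, weights):
        s = 1.0 if survival is None else float(survival[prio])
        batches.append(
            SeedBatch(
                dam_line=dam,
                priority=prio,
                offspring_dist=cross_distribution(dam, pool),
                weight=w,
                survival=s,
            )
        )
    return batches


SurvivalSpec = Union[None, Mapping[str, float], str]


def _batch_survival(batch: SeedBatch, survival: SurvivalSpec) -> float:
    if survival is None:
        return 1.0
    if survival == "batch":
        return batch.survival
    return float(survival[batch.priority])


def expected_mean(
    batches: Iterable[SeedBatch],
    values: GenotypeValueMap,
    survival: SurvivalSpec = None,
) -> float:
    """Survival-weighted expected mean flowering time over seed batches.

    Computes ``sum_b w_b s_b sum_g P_b(g) v(g) / sum_b w_b s_b``.

    ``survival=None`` treats every seed as surviving (the full-cohort,
    "true" mean); a mapping ``{"first": ..., "last": ...}`` applies
    priority-specific storage survival; the string ``"batch"`` uses each
    batch's own ``survival`` attribute.
    """
    num = 0.0
    den = 0.0
    for b in batches:
        w = b.weight * _batch_survival(b, survival)
        num += w * b.mean_value(values)
        den += w
    if den == 0.0:
        raise ValueError("degenerate population: all effective batch weights are zero")
    return num / den


def invisible_fraction_bias(
    batches: Iterable[SeedBatch],
    values: GenotypeValueMap,
    survival: SurvivalSpec = "batch",
) -> float:
    """Full-cohort mean minus storage-survivor mean, in days.

    Positive when survivors flower earlier than the cohort that entered
    storage would have — the survivors then understate the ancestral mean
    and inflate apparent evolution toward later flowering.
    """
    batches = list(batches)
    return expected_mean(batches, values, None) - expected_mean(
        batches, values, survival
    )
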