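"""Flowering-season simulator: densities, pollen pools, sieve draws."""

import numpy as np
import pandas as pd
import pytest

from seedsieve.phenology import (
    FloweringSchedule,
    Plant,
    SurvivalModel,
    add_phenotypes,
    apply_storage,
    assign_priority,
    open_flower_density,
    phenotype,
    pollen_pool_fraction_L,
    simulate_seed_cohort,
)
from seedsieve.toy_model import GenotypeValueMap


@pytest.mark.parametrize(
    "shape, onset, duration, t, expected",
    [
        ("uniform", 30.0, 30.0, 29.0, 0.0),
        ("uniform", 30.0, 30.0, 45.0, 1 / 30),
        ("uniform", 30.0, 30.0, 61.0, 0.0),
        ("triangular", 0.0, 25.0, 12.5, 2 / 25),
        ("triangular", 0.0, 25.0, 0.0, 0.0),
    ],
)
def test_open_flower_density_values(shape, onset, duration, t, expected):
    plant = Plant("p", "EE", "EE", FloweringSchedule(onset, duration, shape))
    assert open_flower_density(plant, t) == pytest.approx(expected)


@pytest.mark.parametrize("shape", ["uniform", "triangular"])
def test_density_integrates_to_one(shape):
    sched = FloweringSchedule(10.0, 25.0, shape)
    t = np.linspace(0.0, 50.0, 20001)
    assert np.trapezoid(sched.density(t), t) == pytest.approx(1.0, abs=1e-4)


@pytest.mark.parametrize(
    "t, expected",
    [(35.0, 0.0), (70.0, 1.0), (52.0, 0.5)],
)
def test_pool_fraction_through_season(offset_population, t, expected):
    """Late-line pollen share shifts 0 -> 0.5 -> 1 over the season."""
    assert pollen_pool_fraction_L(offset_population, t) == pytest.approx(expected)


def test_pool_fraction_no_flowers_sentinel(offset_population):
    assert np.isnan(pollen_pool_fraction_L(offset_population, 5.0))
    with pytest.raises(ValueError):
        pollen_pool_fraction_L(offset_population, 5.0, missing="raise")
    with pytest.raises(ValueError):
        pollen_pool_fraction_L([], 5.0)


def test_pool_fraction_excludes_dam():
    pop = [
        Plant("E1", "EE", "EE", FloweringSchedule(0.0, 10.0)),
        Plant("L1", "LL", "LL", FloweringSchedule(0.0, 10.0)),
    ]
    # with the early dam's own flowers removed, only late pollen remains
    assert pollen_pool_fraction_L(pop, 5.0, exclude_dam="E1") == pytest.approx(1.0)
    assert pollen_pool_fraction_L(pop, 5.0) == pytest.approx(0.5)


def test_cohort_no_compatible_sire_skips():
    pop = [
        Plant("A", "EE", "EE", FloweringSchedule(0.0, 5.0)),
        Plant("B", "LL", "LL", FloweringSchedule(20.0, 5.0)),
    ]
    cohort, skipped = simulate_seed_cohort(pop, 10, rng_seed=0)
    assert len(cohort) == 0 and skipped == 20


def test_cohort_single_line_all_early_genotype():
    pop = [
        Plant(f"E{i}", "EE", "EE", FloweringSchedule(0.0, 10.0)) for i in range(4)
    ]
    cohort, skipped = simulate_seed_cohort(pop, 25, rng_seed=1)
    assert skipped == 0
    assert (cohort["genotype"] == "EE").all()
    assert (cohort["sire_genotype"] == "EE").all()


def test_cohort_reproducible_and_ranked(offset_population):
    a, _ = simulate_seed_cohort(offset_population, 30, rng_seed=42)
    b, _ = simulate_seed_cohort(offset_population, 30, rng_seed=42)
    pd.testing.assert_frame_equal(a, b)
    for _, grp in a.groupby("dam_id"):
        assert sorted(grp["birth_rank"]) == list(range(1, len(grp) + 1))
        assert grp.sort_values("birth_rank")["birth_time"].is_monotonic_increasing


def test_late_born_seeds_have_later_line_sires(offset_population):
    """On early-line dams the late-line sire share rises with birth order,
    the mechanism that loads last seeds with late alleles."""
    cohort, _ = simulate_seed_cohort(offset_population, 2000, rng_seed=7)
    ee = cohort[cohort["dam_line"] == "EE"]
    late_sire = (ee["sire_genotype"] == "LL").astype(float)
    n = 2000
    first_decile = ee["birth_rank"] <= n // 10
    last_decile = ee["birth_rank"] > n - n // 10
    assert late_sire[last_decile].mean() > late_sire[first_decile].mean() + 0.2


@pytest.mark.parametrize(
    "n, fractions, expected",
    [
        (8, (0.25, 0.25), {"first": 2, "middle": 4, "last": 2}),
        (8, (0.5, 0.5), {"first": 4, "last": 4}),
        (5, (0.25, 0.25), {"first": 2, "middle": 1, "last": 2}),
    ],
)
def test_assign_priority_ceiling_rule(n, fractions, expected):
    cohort = pd.DataFrame(
        {
            "dam_id": "d",
            "birth_rank": np.arange(1, n + 1),
            "priority": "unassigned",
        }
    )
    out = assign_priority(cohort, *fractions)
    assert out["priority"].value_counts().to_dict() == expected
    by_rank = out.sort_values("birth_rank")["priority"].tolist()
    assert by_rank[0] == "first" and by_rank[-1] == "last"


def test_assign_priority_rejects_overlap():
    cohort = pd.DataFrame({"dam_id": "d", "birth_rank": [1, 2], "priority": "unassigned"})
    with pytest.raises(ValueError):
        assign_priority(cohort, 0.6, 0.6)


def _priority_cohort(n):
    return pd.DataFrame(
        {
            "dam_id": "d",
            "birth_rank": np.arange(1, n + 1),
            "priority": np.repeat(["first", "middle", "last"], n // 3 + 1)[:n],
            "survived_storage": True,
        }
    )


def test_apply_storage_edge_probabilities():
    cohort = _priority_cohort(300)
    all_live = SurvivalModel(probs={("aged", "first"): 1.0, ("aged", "last"): 1.0})
    assert apply_storage(cohort, all_live, "aged", 0)["survived_storage"].all()
    kill_last = SurvivalModel(probs={("aged", "first"): 1.0, ("aged", "last"): 0.0})
    out = apply_storage(cohort, kill_last, "aged", 0)
    assert not out.loc[out["priority"] == "last", "survived_storage"].any()
    assert out.loc[out["priority"] == "first", "survived_storage"].all()
    # middle seeds use the mean of the first/last probabilities
    mid = out.loc[out["priority"] == "middle", "survived_storage"]
    assert abs(mid.mean() - 0.5) < 3 * np.sqrt(0.25 / len(mid))


def test_apply_storage_binomial_rates():
    """Survivor proportions sit within 3 binomial SEs of the model."""
    n = 10_000
    cohort = pd.DataFrame(
        {
            "dam_id": "d",
            "birth_rank": np.arange(1, 2 * n + 1),
            "priority": ["first"] * n + ["last"] * n,
            "survived_storage": True,
        }
    )
    model = SurvivalModel.default()
    out = apply_storage(cohort, model, "aged", rng_seed=3)
    for prio, p in (("first", 0.78), ("last", 0.68)):
        obs = out.loc[out["priority"] == prio, "survived_storage"].mean()
        assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_apply_storage_requires_priorities(offset_population):
    cohort, _ = simulate_seed_cohort(offset_population[:4], 5, rng_seed=0)
    with pytest.raises(ValueError, match="assign_priority"):
        apply_storage(cohort, SurvivalModel.default(), "aged", 0)


def test_phenotype_deterministic_without_noise(values):
    assert phenotype("EL", values, env_sd=0.0) == 20.0
    assert phenotype("EE", values, env_sd=0.0) == 10.0
    assert phenotype("LL", values, env_sd=0.0) == 30.0


def test_phenotype_noise_is_zero_mean(values):
    n = 100_000
    rng = np.random.default_rng(5)
    draws = phenotype(np.repeat("EL", n), values, env_sd=2.0, rng=rng)
    assert abs(draws.mean() - 20.0) < 3 * 2.0 / np.sqrt(n)
    assert abs(draws.std() - 2.0) < 0.05


def test_add_phenotypes_reduces_to_genetic_values(offset_population, values):
    cohort, _ = simulate_seed_cohort(offset_population, 10, rng_seed=2)
    out = add_phenotypes(cohort, values, env_sd=0.0)
    expected = out["genotype"].map(values.as_dict())
    assert (out["flowering_day"] == expected).all()
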