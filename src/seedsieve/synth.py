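"""Synthetic three-generation greenhouse experiment tables.

Emulates the statistical structure of a resurrection-style experiment:
an F0 parental population of early/late flowering lines, an F1
"refresher" generation grown from aged vs control seed of first vs last
provisioning priority, and a balanced F2 test generation.  The generated
long-format tables carry the experiment's printed effect sizes as
generator parameters: 99% control germination against 78%/68% aged
first/last (a 26-point aging gap with a ~10-point priority gap), a
+1-day plastic storage shift in aged F1 flowering, a 2-day aged
first-vs-last gap in the F2, and rare right-censoring (3/695 in F1,
20/941 in F2).

Baseline flowering-day means and spread are placeholders (21 d, SD 3) —
configurable, not experiment-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from seedsieve.phenology import FloweringSchedule, Plant

SCHEMA_COLUMNS = [
    "plant_id",
    "generation",
    "line",
    "block",
    "treatment",
    "priority",
    "germinated",
    "flowering_day",
    "censored",
]

_GENERATIONS = {"F0", "F1", "F2"}
_LINES = {"EE", "LL"}
_TREATMENTS = {"aged", "control"}
_PRIORITIES = {"first", "last"}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic experiment generator.

    Sample sizes follow the balanced design (44 F1 plants per
    treatment x priority x line x block group = 704; 245 F2 positions per
    treatment x priority group = 980).  Germination probabilities and
    flowering-day shifts are the generator's effect sizes; baseline mean
    and SD are placeholders.
    """

    n_f1_per_group: int = 44
    n_f2_per_group: int = 245
    germ_control: float = 0.99
    germ_aged_first: float = 0.78
    germ_aged_last: float = 0.68
    germ_f2: float = 0.98
    f1_mean_control: float = 21.0
    f1_aged_shift: float = 1.0
    f2_mean: float = 21.0
    f2_aged_priority_gap: float = 2.0
    env_sd: float = 3.0
    censor_p_f1: float = 3 / 695
    censor_p_f2: float = 20 / 941
    study_end_day: int = 60
    onset_mean_early: float = 30.0
    line_onset_offset: float = 14.0
    duration: float = 30.0
    onset_jitter_sd: float = 2.0
    density_shape: str = "uniform"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("germ_control", "germ_aged_first", "germ_aged_last",
                     "germ_f2", "censor_p_f1", "censor_p_f2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.n_f1_per_group < 1 or self.n_f2_per_group < 1:
            raise ValueError("group sizes must be positive")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")

    def germination_p(self, generation: str, treatment: str, priority: str) -> float:
        if generation == "F2":
            return self.germ_f2
        if treatment == "control":
            return self.germ_control
        return self.germ_aged_first if priority == "first" else self.germ_aged_last

    def flowering_mean(self, generation: str, treatment: str, priority: str) -> float:
        if generation == "F1":
            shift = self.f1_aged_shift if treatment == "aged" else 0.0
            return self.f1_mean_control + shift
        # F2: no treatment main effect; the aged group carries the genetic
        # priority gap, centred so its mean matches control
        if treatment == "aged":
            half = self.f2_aged_priority_gap / 2.0
            return self.f2_mean + (half if priority == "last" else -half)
        return self.f2_mean


def generate_f0(params: GeneratorParams = GeneratorParams()) -> List[Plant]:
    """Parental population: 16 early + 16 late plants in each of 2 blocks.

    Late-line onsets sit ``line_onset_offset`` days after the early line;
    per-plant onsets are jittered with SD ``onset_jitter_sd``.
    """
    rng = np.random.default_rng([int(params.rng_seed), 11])
    plants: List[Plant] = []
    for block in ("1", "2"):
        for line in ("EE", "LL"):
            mean_onset = params.onset_mean_early + (
                params.line_onset_offset if line == "LL" else 0.0
            )
            for k in range(16):
                onset = float(rng.normal(mean_onset, params.onset_jitter_sd))
                plants.append(
                    Plant(
                        id=f"F0-{line}-{block}-{k + 1:02d}",
                        line=line,
                        genotype=line,
                        schedule=FloweringSchedule(
                            onset=onset,
                            duration=params.duration,
                            shape=params.density_shape,
                        ),
                        block=block,
                    )
                )
    return plants


def _generate_stratum(
    params: GeneratorParams,
    generation: str,
    groups: Sequence[Tuple[str, str, str, str]],
    n_per_group: int,
    censor_p: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for treatment, priority, line, block in groups:
        p_germ = params.germination_p(generation, treatment, priority)
        mean = params.flowering_mean(generation, treatment, priority)
        germinated = rng.random(n_per_group) < p_germ
        days = np.rint(
            rng.normal(mean, params.env_sd, size=n_per_group)
        ).astype(int)
        days = np.clip(days, 1, None)
        censored = rng.random(n_per_group) < censor_p
        if line is None:  # F2 seeds pooled across lines: labels drawn per row
            lines = np.where(rng.random(n_per_group) < 0.5, "EE", "LL")
            blocks = np.where(rng.random(n_per_group) < 0.5, "1", "2")
        else:
            lines = np.full(n_per_group, line, dtype=object)
            blocks = np.full(n_per_group, block, dtype=object)
        for i in range(n_per_group):
            g = bool(germinated[i])
            c = bool(censored[i]) and g
            line_i, block_i = lines[i], blocks[i]
            rows.append(
                {
                    "plant_id": f"{generation}-{treatment}-{priority}-{line_i}-{block_i}-{i + 1:03d}",
                    "generation": generation,
                    "line": line_i,
                    "block": block_i,
                    "treatment": treatment,
                    "priority": priority,
                    "germinated": int(g),
                    "flowering_day": (
                        params.study_end_day if c else (int(days[i]) if g else pd.NA)
                    ),
                    "censored": int(c),
                }
            )
    return pd.DataFrame(rows)


def generate_experiment(params: GeneratorParams = GeneratorParams()) -> pd.DataFrame:
    """Full synthetic experiment table (F1 and F2 strata).

    Group counts match the balanced design exactly; germination failures
    are retained as rows with ``germinated=0`` and no flowering day.
    Right-censored plants carry the study-end day as their observation
    time.  Byte-identical output for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng([int(params.rng_seed), 13])
    f1_groups = [
        (t, p, l, b)
        for t in ("aged", "control")
        for p in ("first", "last")
        for l in ("EE", "LL")
        for b in ("1", "2")
    ]
    f1 = _generate_stratum(
        params, "F1", f1_groups, params.n_f1_per_group, params.censor_p_f1, rng
    )
    # F2 seeds were pooled across maternal lines; line/block labels are
    # drawn per row, carrying no effect
    rng2 = np.random.default_rng([int(params.rng_seed), 17])
    f2_groups = [
        (t, p, None, None)
        for t in ("aged", "control")
        for p in ("first", "last")
    ]
    f2 = _generate_stratum(
        params, "F2", f2_groups, params.n_f2_per_group, params.censor_p_f2, rng2
    )
    return pd.concat([f1, f2], ignore_index=True)


class SchemaError(ValueError):
    """An experiment table violates the long-format schema."""


def validate_table(table: pd.DataFrame) -> None:
    """Check the experiment-table schema; raise SchemaError naming rows."""
    missing = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    def _bad_rows(mask) -> str:
        rows = list(table.index[mask][:5])
        return ", ".join(str(r) for r in rows)

    for col, allowed in (
        ("generation", _GENERATIONS),
        ("line", _LINES),
        ("treatment", _TREATMENTS),
        ("priority", _PRIORITIES),
    ):
        bad = ~table[col].astype(str).isin(allowed)
        if bad.any():
            raise SchemaError(
                f"column '{col}' has values outside {sorted(allowed)} "
                f"at row(s) {_bad_rows(bad)}"
            )
    for col in ("germinated", "censored"):
        bad = ~table[col].isin([0, 1, True, False])
        if bad.any():
            raise SchemaError(
                f"column '{col}' must be binary; bad row(s) {_bad_rows(bad)}"
            )
    days = pd.to_numeric(table["flowering_day"], errors="coerce")
    bad = table["flowering_day"].notna() & (days.isna() | (days <= 0))
    if bad.any():
        raise SchemaError(
            f"column 'flowering_day' must be a positive day or NA; "
            f"bad row(s) {_bad_rows(bad)}"
        )
    # a flowering day is required unless the plant never germinated or is censored
    bad = (
        table["flowering_day"].isna()
        & (table["germinated"].astype(int) == 1)
        & (table["censored"].astype(int) == 0)
    )
    if bad.any():
        raise SchemaError(
            f"germinated, uncensored plants need a flowering_day; "
            f"bad row(s) {_bad_rows(bad)}"
        )


def write_table(
    table: pd.DataFrame,
    path: Union[str, Path],
    header_lines: Optional[Sequence[str]] = None,
) -> None:
    """Validate and write an experiment table as CSV (missing days as NA).

    ``header_lines`` are prepended as ``#``-prefixed provenance comments.
    """
    validate_table(table)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or ():
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, na_rep="NA")


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an experiment-table CSV (``#`` comments skipped).

    Unknown columns are preserved; schema violations raise ``SchemaError``
    with the offending column and row numbers.
    """
    df = pd.read_csv(
        path,
        comment="#",
        na_values=["NA"],
        keep_default_na=True,
        dtype={"block": str, "plant_id": str},
    )
    validate_table(df)
    df["flowering_day"] = pd.to_numeric(df["flowering_day"], errors="coerce").astype(
        "Int64"
    )
    return df
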