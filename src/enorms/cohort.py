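"""Synthetic series and stratified mixed cohorts.

The reference clinical dataset behind the stratified BMI analysis (34,384
first-visit records from a carpal-tunnel-syndrome referral population) is
not publicly deposited, so this module generates cohorts with the same
statistical structure: per (sex x age-bin) stratum, a dominant near-Gaussian
"healthy" component plus a right-shifted, wider "pathological" component,
mixed at a configurable contamination fraction.  The defaults reproduce the
source cohort's demographics (per-stratum counts) and the qualitative
ordering of its stratified results: male means above female means in every
age bin, means rising with age to a peak (50-69 in men, 70-79 in women) and
dropping in the oldest (80-98) bin.

All generation is driven by a single integer seed; per-stratum substreams
are spawned deterministically so the cohort is reproducible record for
record.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .core import InvalidInputError, ObservationSeries, ParameterError

__all__ = [
    "Sex",
    "StratumSpec",
    "CohortRecord",
    "simulate_gaussian",
    "simulate_mixed_cohort",
    "default_bmi_cohort_spec",
    "write_cohort_csv",
    "load_spec_file",
]

Sex = Literal["male", "female"]
_SEXES = ("male", "female")


@dataclass(frozen=True)
class StratumSpec:
    """Generative parameters for one (sex, age-range) stratum.

    The healthy component is N(healthy_mean, healthy_sd).  The pathological
    component is Gaussian, located ``pathological_shift`` healthy-SDs above
    the healthy mean with SD ``pathological_scale * healthy_sd``; a fraction
    ``contamination_fraction`` of the stratum is drawn from it.  Ages are
    uniform integers over ``[age_low, age_high]``.
    """

    sex: Sex
    age_low: int
    age_high: int
    n: int
    healthy_mean: float
    healthy_sd: float
    contamination_fraction: float = 0.57
    pathological_shift: float = 4.0
    pathological_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ParameterError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.age_low > self.age_high:
            raise ParameterError(
                f"age_low ({self.age_low}) > age_high ({self.age_high})"
            )
        if self.n < 1:
            raise ParameterError(f"stratum n must be >= 1, got {self.n}")
        if not (self.healthy_sd > 0):
            raise ParameterError(f"healthy_sd must be positive, got {self.healthy_sd}")
        if not (0 <= self.contamination_fraction < 1):
            raise ParameterError(
                f"contamination_fraction must be in [0, 1), got {self.contamination_fraction}"
            )
        if not (self.pathological_scale > 0):
            raise ParameterError(
                f"pathological_scale must be positive, got {self.pathological_scale}"
            )

    @property
    def n_healthy(self) -> int:
        # round-half-up so healthy + pathological always partition n
        return int(np.floor(self.n * (1 - self.contamination_fraction) + 0.5))

    @property
    def n_pathological(self) -> int:
        return self.n - self.n_healthy


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic subject: identifier, age (years), sex, measurement
    value, and whether the value was drawn from the pathological component."""

    subject_id: str
    age: int
    sex: Sex
    value: float
    condition: bool

    def __post_init__(self) -> None:
        if self.age < 0:
            raise InvalidInputError(f"record {self.subject_id}: negative age {self.age}")
        if not np.isfinite(self.value):
            raise InvalidInputError(
                f"record {self.subject_id}: non-finite value {self.value!r}"
            )


def simulate_gaussian(n: int, mean: float, sd: float, seed: int) -> ObservationSeries:
    """``n`` i.i.d. Gaussian draws, reproducible for a fixed seed.

    This is the canonical validation input for the plateau detector: 1,000
    draws from N(20, 1.5) should yield a plateau spanning roughly 17 to 23,
    the population mean +/- 2 SD.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not (sd > 0):
        raise ParameterError(f"sd must be positive, got {sd}")
    rng = np.random.default_rng(seed)
    return ObservationSeries(rng.normal(mean, sd, size=n))


def simulate_mixed_cohort(
    spec_list: Sequence[StratumSpec], seed: int
) -> list[CohortRecord]:
    """Generate a stratified contaminated-Gaussian cohort.

    Each stratum contributes ``round(n * (1 - contamination_fraction))``
    healthy draws and the remainder pathological draws (condition flag
    set); within a stratum the records are shuffled so healthy and
    pathological subjects are interleaved as they would be in a clinic
    ledger.  Subject ids are unique across the cohort.  One
    :class:`numpy.random.SeedSequence` is spawned per stratum from
    ``(seed, stratum index)``, so adding a stratum never perturbs the draws
    of earlier ones.
    """
    if len(spec_list) == 0:
        raise ParameterError("spec_list must contain at least one stratum")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(spec_list))
    records: list[CohortRecord] = []
    counter = 0
    for idx, (spec, child) in enumerate(zip(spec_list, children)):
        if not isinstance(spec, StratumSpec):
            raise ParameterError(f"stratum {idx}: expected StratumSpec, got {type(spec)}")
        rng = np.random.default_rng(child)
        n_h, n_p = spec.n_healthy, spec.n_pathological
        values = np.concatenate(
            [
                rng.normal(spec.healthy_mean, spec.healthy_sd, size=n_h),
                rng.normal(
                    spec.healthy_mean + spec.pathological_shift * spec.healthy_sd,
                    spec.pathological_scale * spec.healthy_sd,
                    size=n_p,
                ),
            ]
        )
        condition = np.concatenate([np.zeros(n_h, bool), np.ones(n_p, bool)])
        order = rng.permutation(spec.n)
        ages = rng.integers(spec.age_low, spec.age_high + 1, size=spec.n)
        for j in order:
            counter += 1
            records.append(
                CohortRecord(
                    subject_id=f"S{counter:06d}",
                    age=int(ages[j]),
                    sex=spec.sex,
                    value=float(values[j]),
                    condition=bool(condition[j]),
                )
            )
    return records


# Per-stratum counts of the reference cohort's demographics table
# (males 4053/5016/1726/928, females 8777/9129/2776/1979 across age bins
# 17-49 / 50-69 / 70-79 / 80-98; totals 11,723 and 22,661, grand 34,384).
_TABLE1_N = {
    ("male", (17, 49)): 4053,
    ("male", (50, 69)): 5016,
    ("male", (70, 79)): 1726,
    ("male", (80, 98)): 928,
    ("female", (17, 49)): 8777,
    ("female", (50, 69)): 9129,
    ("female", (70, 79)): 2776,
    ("female", (80, 98)): 1979,
}

# Healthy-component BMI means (kg/m^2) per stratum.  Free parameters of the
# generator chosen to encode the qualitative stratified findings: men above
# women in every bin; a male peak at 50-69 and a female peak at 70-79; a
# marked drop in the oldest bin for both sexes.
_DEFAULT_HEALTHY_MEAN = {
    ("male", (17, 49)): 26.0,
    ("male", (50, 69)): 27.0,
    ("male", (70, 79)): 26.8,
    ("male", (80, 98)): 25.2,
    ("female", (17, 49)): 25.0,
    ("female", (50, 69)): 25.8,
    ("female", (70, 79)): 26.2,
    ("female", (80, 98)): 24.4,
}

_DEFAULT_HEALTHY_SD = 2.0


def default_bmi_cohort_spec(
    contamination_fraction: float = 0.57,
    pathological_shift: float = 4.0,
    pathological_scale: float = 2.0,
) -> list[StratumSpec]:
    """The default eight-stratum BMI cohort specification.

    Stratum sizes copy the reference demographics table; the contamination
    fraction defaults to 0.57, mirroring the 57% disease-positive share of
    the source referral population.
    """
    return [
        StratumSpec(
            sex=sex,
            age_low=lo,
            age_high=hi,
            n=_TABLE1_N[(sex, (lo, hi))],
            healthy_mean=_DEFAULT_HEALTHY_MEAN[(sex, (lo, hi))],
            healthy_sd=_DEFAULT_HEALTHY_SD,
            contamination_fraction=contamination_fraction,
            pathological_shift=pathological_shift,
            pathological_scale=pathological_scale,
        )
        for sex in _SEXES
        for (lo, hi) in [(17, 49), (50, 69), (70, 79), (80, 98)]
    ]


_CSV_HEADER = ["subject_id", "age", "sex", "value", "condition"]


def write_cohort_csv(records: Sequence[CohortRecord], path: str | Path) -> None:
    """Write a cohort as CSV with header subject_id, age, sex, value, condition."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for rec in records:
            writer.writerow(
                [rec.subject_id, rec.age, rec.sex, repr(rec.value), int(rec.condition)]
            )


def load_spec_file(path: str | Path) -> list[StratumSpec]:
    """Read a list of stratum specifications from a JSON or YAML file.

    The file holds a list of mappings whose keys are the
    :class:`StratumSpec` field names.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, list):
        raise ParameterError("spec file must contain a list of stratum mappings")
    return [StratumSpec(**entry) for entry in raw]
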