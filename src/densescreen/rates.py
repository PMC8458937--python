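"""Age-indexed rate tables: packaged fixtures and a synthetic generator.

Two annual-probability tables drive the cohort model: breast-cancer
incidence (how fast healthy women acquire undetected tumors) and all-cause
female mortality.  The packaged fixtures emulate the public US reference
tables for 2017 over ages 55-75; the generator produces structurally valid
synthetic tables (monotone-increasing mortality, linear-trend incidence)
for property testing without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RateTable",
    "RateProfile",
    "FIXTURE_NAMES",
    "load_fixture_rates",
    "load_default_rates",
    "generate_rate_tables",
    "read_rate_table",
    "write_rate_table",
]

FIXTURE_NAMES = ("breast_incidence_2017_like", "female_mortality_2017_like")


@dataclass(frozen=True)
class RateTable:
    """Annual event probabilities indexed by integer age.

    ``ages`` must be contiguous (step 1) and ``rates`` in [0, 1].
    """

    ages: np.ndarray
    rates: np.ndarray
    name: str = ""

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.ndim != 1 or ages.shape != rates.shape or ages.size == 0:
            raise ValueError("ages and rates must be matching non-empty 1-d arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be strictly increasing with step 1")
        if np.any(rates < 0) or np.any(rates > 1) or not np.all(np.isfinite(rates)):
            raise ValueError("rates must lie in [0, 1]")

    def prob(self, age: int) -> float:
        """Annual event probability at ``age``; ages outside the table raise
        (no silent extrapolation)."""
        if not self.ages[0] <= age <= self.ages[-1]:
            raise KeyError(
                f"age {age} outside table {self.name or '<unnamed>'} "
                f"coverage [{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(self.rates[int(age) - int(self.ages[0])])

    def covers(self, lo: int, hi: int) -> bool:
        return self.ages[0] <= lo and hi <= self.ages[-1]


def _read_csv(text_source, name: str) -> RateTable:
    df = pd.read_csv(text_source, comment="#")
    if not {"age", "annual_probability"} <= set(df.columns):
        raise ValueError(f"rate table {name} needs columns age, annual_probability")
    return RateTable(df["age"].to_numpy(), df["annual_probability"].to_numpy(), name)


def load_fixture_rates(name: str) -> RateTable:
    """Load a packaged rate fixture by name.

    Known names: ``breast_incidence_2017_like`` and
    ``female_mortality_2017_like`` (ages 55-75).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    ref = resources.files("densescreen") / "data" / f"{name}.csv"
    with ref.open() as fh:
        return _read_csv(fh, name)


def load_default_rates() -> tuple[RateTable, RateTable]:
    """Return the packaged (incidence, mortality) fixture pair."""
    return (
        load_fixture_rates("breast_incidence_2017_like"),
        load_fixture_rates("female_mortality_2017_like"),
    )


def read_rate_table(path: str | Path, name: str = "") -> RateTable:
    """Read a rate table CSV (columns ``age``, ``annual_probability``;
    ``#`` comment lines allowed)."""
    return _read_csv(path, name or str(path))


def write_rate_table(table: RateTable, path: str | Path, provenance: str = "") -> None:
    """Write a rate table in the fixture CSV format."""
    lines = []
    if provenance:
        lines += [f"# {ln}" for ln in provenance.splitlines()]
    lines.append("age,annual_probability")
    lines += [f"{a},{r:.6f}" for a, r in zip(table.ages, table.rates)]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RateProfile:
    """Closed-form curves from which synthetic rate tables are generated.

    Incidence follows a linear trend in age,
    ``incidence_base + incidence_slope * (age - age_lo)``; mortality an
    exponential (Gompertz-like) curve
    ``mortality_base * exp(mortality_slope * (age - age_lo))``.
    ``noise_cv`` adds multiplicative lognormal-free noise (Gaussian factor
    ``1 + cv * z``) to both curves, clipped to [0, 1].
    """

    age_lo: int = 55
    age_hi: int = 75
    incidence_base: float = 0.0025
    incidence_slope: float = 0.0001
    mortality_base: float = 0.0042
    mortality_slope: float = 0.086
    noise_cv: float = 0.0

    def __post_init__(self):
        if self.age_hi <= self.age_lo:
            raise ValueError("age_hi must exceed age_lo")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_rate_tables(
    profile: RateProfile, seed: int
) -> tuple[RateTable, RateTable]:
    """Generate a synthetic (incidence, mortality) table pair.

    Deterministic given ``seed``.  At ``noise_cv = 0`` the tables are the
    exact closed-form curves, and mortality is strictly increasing whenever
    ``mortality_slope > 0``.
    """
    rng = np.random.default_rng(seed)
    ages = np.arange(profile.age_lo, profile.age_hi + 1)
    rel = ages - profile.age_lo
    inc = profile.incidence_base + profile.incidence_slope * rel
    mort = profile.mortality_base * np.exp(profile.mortality_slope * rel)
    if np.any(inc < 0) or np.any(inc > 1) or np.any(mort < 0) or np.any(mort > 1):
        raise ValueError("profile produces out-of-range probabilities")
    if profile.noise_cv > 0:
        inc = inc * (1.0 + profile.noise_cv * rng.standard_normal(ages.size))
        mort = mort * (1.0 + profile.noise_cv * rng.standard_normal(ages.size))
        inc = np.clip(inc, 0.0, 1.0)
        mort = np.clip(mort, 0.0, 1.0)
    return (
        RateTable(ages, inc, "synthetic_incidence"),
        RateTable(ages, mort, "synthetic_mortality"),
    )
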