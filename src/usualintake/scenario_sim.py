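"""Simulation scenarios and synthetic two-day intake data.

The generating model for a daily-consumed nutrient is a one-way
random-effects model on a Box-Cox transformed scale:

    b_i   ~ Normal(mu, sigma_u^2)          (person-level usual intake)
    y_ij  ~ Normal(b_i, sigma_eps^2)       (daily observation, j = 1..k)
    x_ij  = inverse Box-Cox of y_ij        (original intake scale)

Twelve built-in scenarios cross sample sizes n in {150, 300, 500} with
within/between variance ratios rvar in {4, 9} at two variance magnitudes,
all with mu = 7.5 and lam = 0.2.

Random numbers use counter-based per-person substreams keyed by
``(seed, person_id)`` so a dataset is reproducible, independent of
iteration order, and the first n persons do not change when n grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .boxcox import BoxCoxParams, inverse

__all__ = [
    "ScenarioSpec",
    "IntakeDataset",
    "builtin_scenarios",
    "get_scenario",
    "generate_dataset",
    "load_scenario_config",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger(__name__)

#: maximum number of out-of-domain (lam*y + 1 <= 0) redraws per dataset
#: before the scenario is declared pathological.
MAX_RESAMPLES = 1000


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario (a row of the built-in scenario table).

    All variance parameters live on the transformed scale.

    Parameters
    ----------
    label : str
        Roman numeral I..XII for built-ins, free-form otherwise.
    n : int
        Number of persons (>= 2).
    sigma_eps_sq : float
        Within-person (day-to-day) variance, > 0.
    sigma_u_sq : float
        Between-person variance, >= 0.
    mu : float
        Overall mean on the transformed scale.
    lam : float
        Box-Cox exponent of the generating model.
    days_per_person : int
        Replicates per person (>= 2; the study design uses 2).
    """

    label: str
    n: int
    sigma_eps_sq: float
    sigma_u_sq: float
    mu: float = 7.5
    lam: float = 0.2
    days_per_person: int = 2

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sigma_eps_sq <= 0:
            raise ValueError("sigma_eps_sq must be > 0")
        if self.sigma_u_sq < 0:
            raise ValueError("sigma_u_sq must be >= 0")
        if self.days_per_person < 2:
            raise ValueError("days_per_person must be >= 2")

    @property
    def rvar(self) -> float:
        """Ratio of within- to between-person variance."""
        return self.sigma_eps_sq / self.sigma_u_sq

    @property
    def total_variance(self) -> float:
        return self.sigma_eps_sq + self.sigma_u_sq


@dataclass(frozen=True)
class IntakeDataset:
    """Long-format repeated daily intakes on the original scale."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"person", "day", "amount"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        if (self.frame["amount"] <= 0).any():
            raise ValueError("all amounts must be > 0")
        counts = self.frame.groupby("person")["day"].count()
        if counts.nunique() != 1:
            raise ValueError("unbalanced design: persons differ in day count")

    @property
    def n_persons(self) -> int:
        return self.frame["person"].nunique()

    @property
    def days_per_person(self) -> int:
        return int(self.frame.groupby("person")["day"].count().iloc[0])

    def amounts_by_person(self) -> np.ndarray:
        """Return an (n_persons, k) array, rows ordered by person id."""
        wide = self.frame.pivot(index="person", columns="day", values="amount")
        return wide.to_numpy(dtype=float)


# -- built-in scenarios -------------------------------------------------------

_BUILTIN_ROWS = [
    # label, n, sigma_eps_sq, sigma_u_sq
    ("I", 150, 1.0, 0.25),
    ("II", 150, 1.0, 0.11),
    ("III", 300, 1.0, 0.25),
    ("IV", 300, 1.0, 0.11),
    ("V", 500, 1.0, 0.25),
    ("VI", 500, 1.0, 0.11),
    ("VII", 150, 1.2, 0.3),
    ("VIII", 150, 2.7, 0.3),
    ("IX", 300, 1.2, 0.3),
    ("X", 300, 2.7, 0.3),
    ("XI", 500, 1.2, 0.3),
    ("XII", 500, 2.7, 0.3),
]


def builtin_scenarios() -> list[ScenarioSpec]:
    """The 12 built-in scenarios (mu = 7.5, lam = 0.2, two days)."""
    return [
        ScenarioSpec(label=lab, n=n, sigma_eps_sq=se, sigma_u_sq=su)
        for lab, n, se, su in _BUILTIN_ROWS
    ]


def get_scenario(label: str) -> ScenarioSpec:
    """Look a built-in scenario up by its Roman-numeral label."""
    for spec in builtin_scenarios():
        if spec.label == label:
            return spec
    raise KeyError(f"unknown scenario label {label!r}")


# -- generation ---------------------------------------------------------------

def _person_rng(seed: int, person_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(person_id)]))


def generate_dataset(spec: ScenarioSpec, seed: int) -> IntakeDataset:
    """Generate one synthetic dataset under `spec`, deterministically.

    Each person gets their own substream keyed by ``(seed, person_id)``.
    Daily transformed values whose back-transform argument
    ``lam*y + 1`` would be non-positive are redrawn (logged); more than
    ``MAX_RESAMPLES`` such events raise, signalling a pathological spec.
    """
    params = BoxCoxParams(lam=spec.lam)
    su = np.sqrt(spec.sigma_u_sq)
    se = np.sqrt(spec.sigma_eps_sq)
    k = spec.days_per_person

    resamples = 0
    persons = np.empty((spec.n, k))
    for i in range(spec.n):
        rng = _person_rng(seed, i)
        b_i = spec.mu + su * rng.standard_normal()
        y = b_i + se * rng.standard_normal(k)
        if spec.lam > 0:
            bad = spec.lam * y + 1.0 <= 0.0
            while bad.any():
                resamples += int(bad.sum())
                if resamples > MAX_RESAMPLES:
                    raise RuntimeError(
                        "too many out-of-domain transformed values; "
                        "scenario parameters are pathological"
                    )
                logger.debug(
                    "redrawing %d out-of-domain day(s) for person %d", bad.sum(), i
                )
                y[bad] = b_i + se * rng.standard_normal(int(bad.sum()))
                bad = spec.lam * y + 1.0 <= 0.0
        persons[i] = y

    amounts = inverse(persons, params)
    frame = pd.DataFrame(
        {
            "person": np.repeat(np.arange(spec.n), k),
            "day": np.tile(np.arange(1, k + 1), spec.n),
            "amount": amounts.ravel(),
        }
    )
    return IntakeDataset(frame)


# -- external interfaces ------------------------------------------------------

def load_scenario_config(path) -> ScenarioSpec:
    """Read a scenario from a YAML key-value file.

    A file containing only ``label: <builtin label>`` resolves to the
    built-in scenario; otherwise the keys mirror :class:`ScenarioSpec`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("scenario config must be a key-value mapping")
    if set(raw) == {"label"}:
        return get_scenario(raw["label"])
    return ScenarioSpec(**raw)


def write_dataset(data: IntakeDataset, path) -> None:
    """Write the long-format ``person,day,amount`` table (UTF-8, header)."""
    data.frame.to_csv(path, index=False, encoding="utf-8")


def read_dataset(path) -> IntakeDataset:
    """Read a long-format delimited intake table (header row required)."""
    frame = pd.read_csv(path, encoding="utf-8")
    return IntakeDataset(frame)
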