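"""Synthetic *C. elegans* cohorts with tunable neuron-loss/lifespan coupling.

A cohort is one row per animal: genotype, day-resolution lifespan (days from
the L4 molt, which is age 0), and the present/absent state of each of the
four cephalic neurons scored at a fixed observation day (default day 7 of
adulthood). The generator draws continuous lifespans from a Gompertz law,
latent neuron-loss times ("neuron-spans") from per-neuron Weibull laws with
age-increasing hazard, and couples each loss time to lifespan through a
Gaussian copula at a prescribed Spearman rank correlation. Setting the
coupling to zero reproduces a world where neuron loss is age-dependent but
carries no information about when the animal dies.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy import stats as sps

from .neurons import NEURONS, Neuron

__all__ = [
    "GompertzParams",
    "LossHazard",
    "Scenario",
    "Individual",
    "Cohort",
    "CalibrationError",
    "CohortParseError",
    "calibrate_gompertz",
    "sample_lifespans",
    "discretize_to_days",
    "calibrate_loss_scale",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "SCENARIOS",
]


class CalibrationError(RuntimeError):
    """Raised when a marginal distribution cannot be calibrated to its targets."""


class CohortParseError(ValueError):
    """Raised on malformed cohort CSV input; carries the offending row number."""


# --------------------------------------------------------------------------
# Lifespan marginal: Gompertz mortality
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GompertzParams:
    """Gompertz mortality law, hazard h(t) = a * exp(g t).

    Survival is S(t) = exp(-(a/g)(e^{g t} - 1)); ``g == 0`` degenerates to an
    exponential with rate ``a``. Time unit is days throughout.
    """

    a: float
    g: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"baseline hazard a must be > 0, got {self.a}")
        if self.g < 0:
            raise ValueError(f"hazard growth rate g must be >= 0, got {self.g}")

    def _frozen(self):
        if self.g == 0:
            return sps.expon(scale=1.0 / self.a)
        return sps.gompertz(self.a / self.g, scale=1.0 / self.g)

    def sf(self, t):
        return self._frozen().sf(t)

    def cdf(self, t):
        return self._frozen().cdf(t)

    def ppf(self, q):
        return self._frozen().ppf(q)

    def mean(self) -> float:
        return float(self._frozen().mean())

    def cv(self) -> float:
        d = self._frozen()
        return float(d.std() / d.mean())


def _gompertz_cv_of_beta(beta: float) -> float:
    """CV of the Gompertz with a/g = beta (scale-free: CV is invariant to g)."""
    d = sps.gompertz(beta)
    return float(d.std() / d.mean())


def calibrate_gompertz(target_mean: float, target_cv: float) -> GompertzParams:
    """Find Gompertz parameters with the requested mean and coefficient of variation.

    The CV of a Gompertz depends only on the shape ratio ``beta = a/g`` and
    increases from 0 towards 1 (the exponential limit) as ``beta`` grows, so
    calibration is a 1-D root find on ``beta`` followed by a rescale of ``g``
    to hit the mean. ``target_cv == 1`` returns the exponential limit
    (``g = 0``, ``a = 1/mean``) exactly.

    Raises
    ------
    CalibrationError
        If no ``beta`` in the searchable range attains ``target_cv`` (e.g.
        a CV too close to but below 1, or unrealistically small).
    """
    if target_mean <= 0:
        raise ValueError(f"target_mean must be > 0, got {target_mean}")
    if not 0 < target_cv <= 1:
        raise ValueError(f"target_cv must be in (0, 1], got {target_cv}")
    if target_cv == 1.0:
        return GompertzParams(a=1.0 / target_mean, g=0.0)

    lo, hi = 1e-10, 1e10
    f = lambda logb: _gompertz_cv_of_beta(math.exp(logb)) - target_cv
    flo, fhi = f(math.log(lo)), f(math.log(hi))
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"cannot calibrate Gompertz to mean={target_mean}, cv={target_cv}: "
            f"CV out of attainable range [{target_cv + flo:.4f}, {target_cv + fhi:.4f}]"
        )
    logb = optimize.brentq(f, math.log(lo), math.log(hi), xtol=1e-13, rtol=1e-14)
    beta = math.exp(logb)
    # With g=1 the mean is mean_unit(beta); rescale time so the mean matches.
    mean_unit = float(sps.gompertz(beta).mean())
    g = mean_unit / target_mean
    params = GompertzParams(a=beta * g, g=g)
    if not (
        math.isclose(params.mean(), target_mean, rel_tol=1e-6)
        and math.isclose(params.cv(), target_cv, rel_tol=1e-6)
    ):
        raise CalibrationError(
            f"Gompertz calibration did not converge for mean={target_mean}, "
            f"cv={target_cv} (got mean={params.mean():.8g}, cv={params.cv():.8g})"
        )
    return params


def sample_lifespans(
    params: GompertzParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. continuous lifespans (days) by inverse-CDF sampling."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return np.asarray(params.ppf(rng.uniform(size=n)), dtype=float)


def discretize_to_days(lifespans: Iterable[float]) -> np.ndarray:
    """Ceiling to whole days: death is recorded at the first daily check at or
    after the true death time, producing the heavy ties of daily scoring."""
    arr = np.asarray(lifespans, dtype=float)
    if np.any(arr < 0):
        raise ValueError("lifespans must be nonnegative")
    return np.ceil(arr).astype(int)


# --------------------------------------------------------------------------
# Neuron-loss marginal: Weibull with age-increasing risk
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LossHazard:
    """Weibull neuron-loss time: shape ``k`` >= 1 (risk rising with age),
    scale ``lam`` > 0 days. P(loss <= 0) = 0 by construction, so animals at
    the start of adulthood never show loss."""

    k: float
    lam: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"Weibull shape must be >= 1, got {self.k}")
        if self.lam <= 0:
            raise ValueError(f"Weibull scale must be > 0, got {self.lam}")

    def cdf(self, t):
        return sps.weibull_min.cdf(t, self.k, scale=self.lam)

    def ppf(self, q):
        return sps.weibull_min.ppf(q, self.k, scale=self.lam)


def calibrate_loss_scale(shape_k: float, target_fraction: float, day: float) -> float:
    """Closed-form Weibull scale such that P(loss time <= day) = target_fraction.

    Inverts ``1 - exp(-(day/lam)^k)`` exactly: ``lam = day / (-ln(1-f))^{1/k}``.
    """
    if shape_k < 1:
        raise ValueError(f"shape_k must be >= 1, got {shape_k}")
    if day <= 0:
        raise ValueError(f"day must be > 0, got {day}")
    if not 0 < target_fraction < 1:
        raise ValueError(
            f"target_fraction must be strictly inside (0, 1), got {target_fraction}: "
            "fractions of 0 or 1 are unattainable with a finite scale"
        )
    return day / (-math.log1p(-target_fraction)) ** (1.0 / shape_k)


# --------------------------------------------------------------------------
# Scenarios and cohorts
# --------------------------------------------------------------------------

_WT_MEAN = 10.5  # days; day-7 adults have lived two thirds of mean lifespan
_WT_FRACTIONS = {
    Neuron.CEPDL: 0.07,
    Neuron.CEPDR: 0.07,
    Neuron.CEPVL: 0.17,
    Neuron.CEPVR: 0.17,
}
_AGE1_FRACTIONS = {
    Neuron.CEPDL: 0.07,
    Neuron.CEPDR: 0.07,
    Neuron.CEPVL: 0.45,
    Neuron.CEPVR: 0.45,
}


@dataclasses.dataclass(frozen=True)
class Scenario:
    """Generator parameters for one genotype.

    ``absent_fraction_day7`` is the marginal probability that each neuron is
    absent in a day-7 adult; ``coupling_rho_s`` is the Spearman rank
    correlation between each neuron's latent loss time and lifespan (0 means
    neuron loss carries no information about death timing).
    """

    name: str
    lifespan_mean: float
    lifespan_cv: float
    absent_fraction_day7: Mapping[Neuron, float]
    coupling_rho_s: float = 0.0
    loss_shape: float = 3.0
    observation_day: int = 7

    def __post_init__(self) -> None:
        if self.lifespan_mean <= 0:
            raise ValueError(f"lifespan_mean must be > 0, got {self.lifespan_mean}")
        if not 0 < self.lifespan_cv <= 1:
            raise ValueError(f"lifespan_cv must be in (0, 1], got {self.lifespan_cv}")
        if not abs(self.coupling_rho_s) < 1:
            raise ValueError(
                f"coupling_rho_s must satisfy |rho| < 1, got {self.coupling_rho_s}"
            )
        if self.observation_day < 0:
            raise ValueError("observation_day must be >= 0")
        fracs = dict(self.absent_fraction_day7)
        if set(fracs) != set(NEURONS):
            raise ValueError("absent_fraction_day7 must cover all four neurons")
        for nid, f in fracs.items():
            if not 0 <= f < 1:
                raise ValueError(f"absent fraction for {nid} must be in [0, 1), got {f}")
        object.__setattr__(self, "absent_fraction_day7", fracs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["absent_fraction_day7"] = {
            str(k): v for k, v in self.absent_fraction_day7.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        d["absent_fraction_day7"] = {
            Neuron(k): float(v) for k, v in dict(d["absent_fraction_day7"]).items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


#: Built-in genotype scenarios. Lifespans: wild type mean 10.5 d; *age-1*
#: reduction-of-function extends lifespan 2.6-fold; *daf-16;age-1* double
#: mutants revert to wild-type lifespan; intestinal daf-16(+) rescue extends
#: the double mutant by 40%. Ventral neurons are lost more often than dorsal
#: by day 7, and *age-1* worsens the ventral (not dorsal) phenotype.
SCENARIOS: dict[str, Scenario] = {
    "wild_type": Scenario("wild_type", _WT_MEAN, 0.25, _WT_FRACTIONS),
    "age1": Scenario("age1", 2.6 * _WT_MEAN, 0.25, _AGE1_FRACTIONS),
    "daf16_age1": Scenario("daf16_age1", _WT_MEAN, 0.25, _WT_FRACTIONS),
    "daf16_age1_gut_rescue": Scenario(
        "daf16_age1_gut_rescue", 1.4 * _WT_MEAN, 0.25, _WT_FRACTIONS
    ),
}


@dataclasses.dataclass
class Individual:
    """One animal: day-resolution lifespan plus day-7 neuron states.

    ``neuron_state`` maps each neuron to ``True`` (present) / ``False``
    (absent); it is ``None`` for animals that died before the observation day
    and were therefore never imaged.
    """

    id: str
    genotype: str
    lifespan_days: int
    neuron_state: Mapping[Neuron, bool] | None
    observation_day: int = 7

    def __post_init__(self) -> None:
        if self.lifespan_days < 0:
            raise ValueError("lifespan_days must be >= 0")
        if self.neuron_state is not None:
            if set(self.neuron_state) != set(NEURONS):
                raise ValueError("neuron_state must cover all four neurons")
            if self.lifespan_days < self.observation_day:
                raise ValueError(
                    "an animal scored at the observation day must have lived to it"
                )

    @property
    def scorable(self) -> bool:
        return self.neuron_state is not None

    def n_absent(self, neurons: Iterable[Neuron] = NEURONS) -> int:
        if self.neuron_state is None:
            raise ValueError(f"animal {self.id} has no recorded neuron states")
        return sum(not self.neuron_state[nid] for nid in neurons)


@dataclasses.dataclass
class Cohort:
    """A nonempty list of animals sharing an observation day, plus metadata."""

    individuals: list[Individual]
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValueError("empty cohort")
        days = {ind.observation_day for ind in self.individuals}
        if len(days) > 1:
            raise ValueError(f"individuals mix observation days: {sorted(days)}")

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def observation_day(self) -> int:
        return self.individuals[0].observation_day

    def lifespans(self, scorable_only: bool = False) -> np.ndarray:
        return np.array(
            [
                ind.lifespan_days
                for ind in self.individuals
                if ind.scorable or not scorable_only
            ],
            dtype=int,
        )

    def scorable(self) -> list[Individual]:
        """Animals alive at the observation day, i.e. with recorded states."""
        return [ind for ind in self.individuals if ind.scorable]

    def absent_counts(self) -> dict[Neuron, int]:
        """Number of scorable animals missing each neuron."""
        counts = {nid: 0 for nid in NEURONS}
        for ind in self.scorable():
            for nid in NEURONS:
                counts[nid] += not ind.neuron_state[nid]
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row = {
                "id": ind.id,
                "genotype": ind.genotype,
                "lifespan_days": ind.lifespan_days,
                "observation_day": ind.observation_day,
            }
            for nid in NEURONS:
                if ind.neuron_state is None:
                    row[nid.value] = ""
                else:
                    row[nid.value] = "present" if ind.neuron_state[nid] else "absent"
            rows.append(row)
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


_CSV_COLUMNS = ["id", "genotype", "lifespan_days", "observation_day"] + [
    n.value for n in NEURONS
]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV with the fixed column layout; round-trip lossless."""
    cohort.to_dataframe().to_csv(path, index=False)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV; raises :class:`CohortParseError` with the row number
    of the first malformed entry (1-based, excluding the header)."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CohortParseError("empty cohort") from None
    if list(df.columns) != _CSV_COLUMNS:
        raise CohortParseError(
            f"malformed header: expected {_CSV_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise CohortParseError("empty cohort")
    individuals = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            lifespan = int(row.lifespan_days)
            obs_day = int(row.observation_day)
        except ValueError:
            raise CohortParseError(
                f"row {i}: non-integer lifespan_days/observation_day"
            ) from None
        states: dict[Neuron, bool] | None = {}
        tokens = [getattr(row, nid.value) for nid in NEURONS]
        if all(t == "" for t in tokens):
            states = None
        else:
            for nid, tok in zip(NEURONS, tokens):
                if tok == "present":
                    states[nid] = True
                elif tok == "absent":
                    states[nid] = False
                else:
                    raise CohortParseError(
                        f"row {i}: unknown state token {tok!r} for {nid.value}"
                    )
        individuals.append(
            Individual(
                id=row.id,
                genotype=row.genotype,
                lifespan_days=lifespan,
                neuron_state=states,
                observation_day=obs_day,
            )
        )
    return Cohort(individuals)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def generate_cohort(
    scenario: Scenario,
    n: int,
    seed: int | np.random.Generator,
    return_latent: bool = False,
) -> Cohort | tuple[Cohort, pd.DataFrame]:
    """Generate a cohort under ``scenario``.

    A single standard-normal latent ``Z0`` drives lifespan; each neuron's
    latent ``Z_i`` has Pearson correlation ``r = 2 sin(pi rho_s / 6)`` with
    ``Z0`` (the exact Gaussian-copula mapping from the target Spearman
    correlation), and the neurons are conditionally independent given ``Z0``.
    Latents map through the marginal inverse CDFs: Gompertz for lifespan,
    per-neuron Weibull (scale calibrated so that P(loss <= 7 d) equals the
    scenario's day-7 absent fraction) for loss times. A neuron is scored
    absent iff its loss time is at or before the observation day. Lifespans
    are ceiling-discretized to whole days; animals dying before the
    observation day are retained but carry no neuron states.

    With ``return_latent=True`` also returns a DataFrame of the continuous
    lifespans and loss times (useful for validating the coupling).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    gomp = calibrate_gompertz(scenario.lifespan_mean, scenario.lifespan_cv)
    hazards = {
        nid: LossHazard(
            scenario.loss_shape,
            calibrate_loss_scale(scenario.loss_shape, frac, 7.0),
        )
        for nid, frac in scenario.absent_fraction_day7.items()
    }

    from .power import spearman_to_pearson  # local import to avoid cycle

    r = spearman_to_pearson(scenario.coupling_rho_s)
    z0 = rng.standard_normal(n)
    lifespan_cont = np.asarray(gomp.ppf(sps.norm.cdf(z0)), dtype=float)
    loss_times = {}
    for nid in NEURONS:
        zi = r * z0 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
        loss_times[nid] = np.asarray(
            hazards[nid].ppf(sps.norm.cdf(zi)), dtype=float
        )

    days = discretize_to_days(lifespan_cont)
    obs = scenario.observation_day
    individuals = []
    for i in range(n):
        if days[i] < obs:
            states = None
        else:
            states = {nid: bool(loss_times[nid][i] > obs) for nid in NEURONS}
        individuals.append(
            Individual(
                id=f"{scenario.name}-{i:06d}",
                genotype=scenario.name,
                lifespan_days=int(days[i]),
                neuron_state=states,
                observation_day=obs,
            )
        )
    seed_repr = seed if isinstance(seed, int) else "generator"
    cohort = Cohort(
        individuals,
        metadata={
            "scenario": scenario.to_dict(),
            "seed": seed_repr,
            "n": n,
            "gompertz": {"a": gomp.a, "g": gomp.g},
            "loss_hazards": {
                str(nid): {"k": h.k, "lam": h.lam} for nid, h in hazards.items()
            },
        },
    )
    if return_latent:
        latent = pd.DataFrame({"lifespan": lifespan_cont})
        for nid in NEURONS:
            latent[f"loss_{nid.value}"] = loss_times[nid]
        return cohort, latent
    return cohort
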