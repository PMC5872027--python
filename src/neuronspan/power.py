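"""Copula-based Monte-Carlo power analysis for lifespan/neuron-span coupling.

The experiment observes, for each animal, a lifespan and the present/absent
state of each neuron at a fixed day — never the latent neuron-loss time
itself. To ask "how strong would a rank correlation between loss time and
lifespan have to be before the experiment would detect it?", the engine:

1. draws joint (lifespan, neuron-span) rank samples from a Gaussian copula
   at a target Spearman correlation;
2. labels the ``k_absent`` lowest neuron-span ranks "absent" (those are the
   animals that would have lost the neuron by the observation day);
3. maps lifespan ranks back onto the empirical lifespan distribution, which
   splits the observed lifespans into synthetic "present" and "absent"
   survival curves;
4. compares the two curves with the Peto-Prentice Wilcoxon test.

Repeating over many replicates and a grid of correlations yields power as a
function of the Spearman correlation, and the smallest correlation magnitude
detectable at a target power (the detection threshold).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression

from .survival import TestResult

__all__ = [
    "JointRankSample",
    "GroupBand",
    "PowerPoint",
    "PowerCurve",
    "PowerTargetError",
    "spearman_to_pearson",
    "sample_joint_ranks",
    "synthesize_survival_groups",
    "correlation_grid",
    "power_at",
    "multi_neuron_power_at",
    "power_curve",
    "detection_threshold",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula achieving Spearman ``rho_s``.

    Exact closed form ``r = 2 sin(pi rho_s / 6)``; odd and strictly
    increasing on [-1, 1].
    """
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError(f"|rho_s| must be <= 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclasses.dataclass(frozen=True)
class JointRankSample:
    """n simulated animals as (lifespan-rank, neuron-span-rank) pairs.

    Ranks are a permutation of 1..n (the copula sample is continuous, so ties
    have probability zero). The ``k_absent`` animals with the lowest
    neuron-span ranks are labelled absent.
    """

    n: int
    rho_s: float
    lifespan_rank: np.ndarray
    neuronspan_rank: np.ndarray
    absent: np.ndarray
    k_absent: int

    def __post_init__(self) -> None:
        if int(self.absent.sum()) != self.k_absent:
            raise ValueError("absent label count does not match k_absent")


def _ranks(x: np.ndarray) -> np.ndarray:
    """Ordinal ranks 1..n of a continuous sample."""
    out = np.empty(x.size, dtype=np.int64)
    out[np.argsort(x, kind="stable")] = np.arange(1, x.size + 1)
    return out


def sample_joint_ranks(
    n: int, rho_s: float, k_absent: int, seed: int | np.random.Generator
) -> JointRankSample:
    """Draw a joint rank sample from the Gaussian copula at Spearman ``rho_s``."""
    if not 0 < k_absent < n:
        raise ValueError(f"k_absent must be in (0, n); got k={k_absent}, n={n}")
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson(rho_s)
    z_life = rng.standard_normal(n)
    z_span = r * z_life + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    span_rank = _ranks(z_span)
    return JointRankSample(
        n=n,
        rho_s=rho_s,
        lifespan_rank=_ranks(z_life),
        neuronspan_rank=span_rank,
        absent=span_rank <= k_absent,
        k_absent=k_absent,
    )


def synthesize_survival_groups(
    sample: JointRankSample, empirical_lifespans
) -> tuple[np.ndarray, np.ndarray]:
    """Map lifespan ranks back onto the empirical lifespans.

    The animal with lifespan-rank j receives the j-th smallest empirical
    lifespan; returns ``(absent_lifespans, present_lifespans)`` whose union
    equals the empirical multiset exactly.
    """
    emp = np.sort(np.asarray(empirical_lifespans, dtype=float))
    if emp.size != sample.n:
        raise ValueError(
            f"need exactly n={sample.n} empirical lifespans, got {emp.size}"
        )
    assigned = emp[sample.lifespan_rank - 1]
    return assigned[sample.absent], assigned[~sample.absent]


def correlation_grid(
    n_points: int = 75, max_abs: float = 0.5, densify: str = "signed_square"
) -> np.ndarray:
    """Symmetric correlation grid on [-max_abs, max_abs], denser near zero.

    ``signed_square`` maps a uniform grid u in [-1, 1] to ``max_abs *
    sign(u) * u**2``, so spacing grows with |rho|; ``linear`` is uniform.
    Contains 0 exactly when ``n_points`` is odd.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if not 0 < max_abs <= 1:
        raise ValueError("max_abs must be in (0, 1]")
    u = np.linspace(-1.0, 1.0, n_points)
    if densify == "signed_square":
        return max_abs * np.sign(u) * u * u
    if densify == "linear":
        return max_abs * u
    raise ValueError(f"unknown densification rule {densify!r}")


@dataclasses.dataclass(frozen=True)
class GroupBand:
    """Central value and 2.5/97.5 percentile band of a group summary across
    replicates."""

    central: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.central <= self.upper:
            raise ValueError("band must bracket its central value")


@dataclasses.dataclass(frozen=True)
class PowerPoint:
    """Estimated power at one Spearman correlation."""

    rho_s: float
    power: float
    replicates: int
    alpha: float
    n: int
    group_means: Mapping[str, GroupBand]

    def __post_init__(self) -> None:
        if not 0 <= self.power <= 1:
            raise ValueError("power must be in [0, 1]")


@dataclasses.dataclass
class PowerCurve:
    """Power over a correlation grid, with provenance for reproducibility."""

    points: list[PowerPoint]
    grid: np.ndarray
    replicates: int
    alpha: float
    n: int
    k_absent: tuple[int, ...]
    seed: int | None
    marginal: str = "empirical lifespans"

    def powers(self) -> np.ndarray:
        return np.array([p.power for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"rho_s": p.rho_s, "power": p.power}
            for name, band in p.group_means.items():
                row[f"mean_{name}"] = band.central
                row[f"mean_{name}_lo"] = band.lower
                row[f"mean_{name}_hi"] = band.upper
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "grid": [float(g) for g in self.grid],
            "replicates": self.replicates,
            "alpha": self.alpha,
            "n": self.n,
            "k_absent": list(self.k_absent),
            "seed": self.seed,
            "marginal": self.marginal,
            "points": [
                {
                    "rho_s": p.rho_s,
                    "power": p.power,
                    "group_means": {
                        k: dataclasses.asdict(b) for k, b in p.group_means.items()
                    },
                }
                for p in self.points
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


class _PetoEngine:
    """Precomputed Peto-Prentice machinery for a fixed uncensored lifespan
    multiset.

    Across power replicates the pooled sample never changes — only the
    partition into absent/present does — so the pooled event table, weights
    and hypergeometric variance core are computed once. Per replicate the
    two-group statistic needs only a bincount of the absent group's death
    days and cumulative sums over the distinct times.
    """

    def __init__(self, lifespans):
        s = np.sort(np.asarray(lifespans, dtype=float))
        if s.size < 2:
            raise ValueError("need at least two lifespans")
        vals, counts = np.unique(s, return_counts=True)
        self.n = s.size
        self.sorted_lifespans = s
        self.n_times = vals.size
        # distinct-time index of the j-th smallest lifespan
        self.time_of_pos = np.repeat(np.arange(vals.size), counts)
        self.d = counts.astype(float)
        self.n_risk = self.n - np.concatenate(([0.0], np.cumsum(self.d)[:-1]))
        self.w = np.cumprod(1.0 - self.d / (self.n_risk + 1.0))
        nm1 = np.where(self.n_risk > 1, self.n_risk - 1.0, 1.0)
        self.vcore = self.w**2 * self.d * (self.n_risk - self.d) / nm1
        self.vcore[self.n_risk <= 1] = 0.0
        self.total = float(s.sum())

    def two_group_p(self, time_idx_absent: np.ndarray, k: int) -> float:
        """p-value of the Peto-Prentice test, absent group given by the
        distinct-time indices of its members' lifespans."""
        d_a = np.bincount(time_idx_absent, minlength=self.n_times).astype(float)
        n_a = k - np.concatenate(([0.0], np.cumsum(d_a)[:-1]))
        frac = n_a / self.n_risk
        U = float(np.sum(self.w * (d_a - frac * self.d)))
        V = float(np.sum(self.vcore * frac * (1.0 - frac)))
        if V <= 0:
            return 1.0
        return float(sps.chi2.sf(U * U / V, 1))


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def multi_neuron_power_at(
    empirical_lifespans,
    k_absent: int | Sequence[int],
    rho_s: float,
    replicates: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> PowerPoint:
    """Union power across one to four neurons at one Spearman correlation.

    Each replicate draws a single lifespan latent and, per neuron, a
    conditionally independent neuron-span latent at Spearman ``rho_s`` to the
    lifespan; a replicate counts as a detection when at least one of the
    per-neuron Peto-Prentice tests has p < ``alpha``. With a single neuron
    this is exactly :func:`power_at`.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ks = [int(k_absent)] if np.isscalar(k_absent) else [int(k) for k in k_absent]
    if not 1 <= len(ks) <= 4:
        raise ValueError("between one and four neurons supported")
    engine = _PetoEngine(empirical_lifespans)
    n = engine.n
    for k in ks:
        if not 0 < k < n:
            raise ValueError(f"k_absent must be in (0, n); got k={k}, n={n}")
    r = spearman_to_pearson(rho_s)
    rt = math.sqrt(1.0 - r * r)
    rng = _resolve_rng(seed)

    hits = 0
    means = {f"absent_{m}": np.empty(replicates) for m in range(len(ks))}
    means.update({f"present_{m}": np.empty(replicates) for m in range(len(ks))})
    time_assigned = np.empty(n, dtype=np.int64)
    value_assigned = np.empty(n, dtype=float)
    for rep in range(replicates):
        z_life = rng.standard_normal(n)
        order = np.argsort(z_life, kind="stable")
        time_assigned[order] = engine.time_of_pos
        value_assigned[order] = engine.sorted_lifespans
        detected = False
        for m, k in enumerate(ks):
            z_span = r * z_life + rt * rng.standard_normal(n)
            idx_absent = np.argpartition(z_span, k)[:k]
            p = engine.two_group_p(time_assigned[idx_absent], k)
            if p < alpha:
                detected = True
            mean_abs = float(value_assigned[idx_absent].mean())
            means[f"absent_{m}"][rep] = mean_abs
            means[f"present_{m}"][rep] = (engine.total - mean_abs * k) / (n - k)
        hits += detected

    def band(x: np.ndarray) -> GroupBand:
        lo, hi = np.percentile(x, [2.5, 97.5])
        c = float(np.clip(x.mean(), lo, hi))
        return GroupBand(central=c, lower=float(lo), upper=float(hi))

    if len(ks) == 1:
        group_means = {"absent": band(means["absent_0"]), "present": band(means["present_0"])}
    else:
        group_means = {name: band(vals) for name, vals in sorted(means.items())}
    return PowerPoint(
        rho_s=rho_s,
        power=hits / replicates,
        replicates=replicates,
        alpha=alpha,
        n=n,
        group_means=group_means,
    )


def power_at(
    empirical_lifespans,
    k_absent: int,
    rho_s: float,
    replicates: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> PowerPoint:
    """Power of the single-neuron present-vs-absent comparison at one
    Spearman correlation: the fraction of replicates in which the synthetic
    absent and present survival curves differ at p < ``alpha``."""
    return multi_neuron_power_at(
        empirical_lifespans, int(k_absent), rho_s, replicates, alpha, seed
    )


def power_curve(
    empirical_lifespans,
    k_absent: int | Sequence[int],
    grid=None,
    replicates: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PowerCurve:
    """Power over a correlation grid.

    A root ``seed`` spawns one deterministic child seed per grid point, so
    any single point can be recomputed in isolation. ``k_absent`` may be a
    single count (one neuron) or a sequence of up to four (union power).
    """
    grid = correlation_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a nonempty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    children = np.random.SeedSequence(seed).spawn(grid.size)
    ks = (int(k_absent),) if np.isscalar(k_absent) else tuple(int(k) for k in k_absent)
    points = [
        multi_neuron_power_at(
            empirical_lifespans, ks if len(ks) > 1 else ks[0], float(rho),
            replicates, alpha, np.random.default_rng(child),
        )
        for rho, child in zip(grid, children)
    ]
    n = len(np.asarray(empirical_lifespans))
    return PowerCurve(
        points=points,
        grid=grid,
        replicates=replicates,
        alpha=alpha,
        n=n,
        k_absent=ks,
        seed=seed,
    )


class PowerTargetError(RuntimeError):
    """Raised when the target power is not reached anywhere on the grid."""


def detection_threshold(curve: PowerCurve, target_power: float = 0.95) -> float:
    """Smallest correlation magnitude with (interpolated) power >= target.

    Powers at matching +/- magnitudes are averaged, isotonic regression in
    |rho| tames Monte-Carlo noise, and the crossing is located by linear
    interpolation between the adjacent grid magnitudes.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    mags = np.abs(np.round(curve.grid, 12))
    powers = curve.powers()
    uniq = np.unique(mags)
    avg = np.array([powers[mags == m].mean() for m in uniq])
    weights = np.array([(mags == m).sum() for m in uniq], dtype=float)
    iso = IsotonicRegression(increasing=True).fit(uniq, avg, sample_weight=weights)
    smooth = iso.predict(uniq)
    reached = smooth >= target_power
    if not reached.any():
        raise PowerTargetError(
            f"target power {target_power} not reached on the grid; "
            f"maximum achieved is {smooth.max():.3f} at |rho|={uniq[np.argmax(smooth)]:.3f}"
        )
    i = int(np.argmax(reached))
    if i == 0:
        return float(uniq[0])
    p0, p1 = smooth[i - 1], smooth[i]
    m0, m1 = uniq[i - 1], uniq[i]
    return float(m0 + (target_power - p0) / (p1 - p0) * (m1 - m0))
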