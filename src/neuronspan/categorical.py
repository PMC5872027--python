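"""Categorical statistics: Fisher's exact test, Pearson chi-square,
Bonferroni adjustment, and proportional-odds ordinal logistic regression.

These back the cross-sectional analyses: comparing neuron-loss fractions
between groups (exact for 2x2, chi-square for larger tables), adjusting
families of p-values, and modelling how the ordinal extent of neuron loss
depends on age and on neuron position/side.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .survival import TestResult

__all__ = [
    "ContingencyTable",
    "OrdinalModelFit",
    "OrdinalFitError",
    "fisher_exact_2x2",
    "pearson_chi_square",
    "bonferroni_adjust",
    "fit_proportional_odds",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """r x c table of nonnegative integer counts with positive margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("table must be at least 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
            raise ValueError("all row and column margins must be positive")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            df.to_numpy(dtype=int),
            tuple(map(str, df.index)),
            tuple(map(str, df.columns)),
        )


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p-value is the total hypergeometric probability of all
    tables with the observed margins whose probability does not exceed that
    of the observed table (the minimum-likelihood convention).
    """
    counts = _as_table(table)
    if counts.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2x2 table, got {counts.shape}")
    odds_ratio, p = sps.fisher_exact(counts, alternative="two-sided")
    return TestResult("fisher-exact", float(odds_ratio), 1, float(p))


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = _as_table(table)
    stat, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult("pearson-chi-square", float(stat), int(dof), float(p))


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, m p) elementwise."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return np.minimum(1.0, p.size * p)


class OrdinalFitError(RuntimeError):
    """Raised when the proportional-odds fit fails (rank deficiency,
    separation, or non-convergence)."""


@dataclasses.dataclass(frozen=True)
class OrdinalModelFit:
    """Proportional-odds (cumulative-logit) maximum-likelihood fit.

    ``coefficients`` are on the log-odds scale, oriented so a positive value
    means higher predictor values push probability mass towards higher
    outcome levels. ``cutpoints`` are the strictly increasing intercepts.
    """

    coefficients: dict[str, float]
    cutpoints: tuple[float, ...]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        for p in self.p_values.values():
            if not 0 <= p <= 1:
                raise ValueError("p-values must be in [0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "coefficients": self.coefficients,
                "cutpoints": list(self.cutpoints),
                "std_errors": self.std_errors,
                "p_values": self.p_values,
                "log_likelihood": self.log_likelihood,
            },
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_proportional_odds(outcome, design) -> OrdinalModelFit:
    """Fit a proportional-odds model P(Y <= j | x) = logistic(theta_j - x'b).

    ``outcome`` is an ordinal level per observation (ints or an ordered
    pandas Categorical); ``design`` a DataFrame (or 2-D array) of predictors,
    which must be full rank. With a binary outcome the fit coincides with
    binary logistic regression.
    """
    y = pd.Series(outcome)
    if isinstance(design, pd.DataFrame):
        X = design.copy()
    else:
        X = pd.DataFrame(np.asarray(design, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    if len(y) != len(X):
        raise ValueError("outcome and design lengths differ")
    if y.nunique() < 2:
        raise OrdinalFitError("outcome has fewer than two observed levels")
    rank = np.linalg.matrix_rank(np.asarray(X, dtype=float))
    if rank < X.shape[1]:
        corr = np.corrcoef(np.asarray(X, dtype=float), rowvar=False)
        dup = "unknown"
        for i in range(X.shape[1]):
            for j in range(i + 1, X.shape[1]):
                if abs(corr[i, j]) > 1 - 1e-10:
                    dup = f"{X.columns[i]!r} vs {X.columns[j]!r}"
        raise OrdinalFitError(f"design matrix is rank deficient ({dup})")
    model = OrderedModel(y.to_numpy(), X, distr="logit")
    with np.errstate(all="ignore"):
        res = model.fit(method="bfgs", disp=False, maxiter=500)
    if not res.mle_retvals.get("converged", False):
        raise OrdinalFitError(
            f"proportional-odds fit did not converge for predictors "
            f"{list(X.columns)} (possible separation)"
        )
    k = X.shape[1]
    params = np.asarray(res.params)
    cutpoints = model.transform_threshold_params(params)[1:-1]
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    names = list(X.columns)
    return OrdinalModelFit(
        coefficients={name: float(params[i]) for i, name in enumerate(names)},
        cutpoints=tuple(float(c) for c in cutpoints),
        std_errors={name: float(bse[i]) for i, name in enumerate(names)},
        p_values={name: float(pvals[i]) for i, name in enumerate(names)},
        log_likelihood=float(res.llf),
    )
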