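"""End-to-end independence analysis: does neuron loss predict lifespan?

For a cohort of animals scored at the observation day, the pipeline compares
the lifespans of animals with and without each neuron (Peto-Prentice
Wilcoxon), repeats the comparison for four coarser groupings (any neuron
missing, number of dorsal missing, number of ventral missing, total
missing), Bonferroni-adjusts each family of p-values, and then runs the
copula power engine on the cohort's own lifespans to report the smallest
loss/lifespan rank correlation the experiment could have detected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .cohort import SCENARIOS, Cohort, Scenario, generate_cohort, write_cohort
from .neurons import DORSAL, NEURONS, VENTRAL, Neuron
from .categorical import bonferroni_adjust
from .power import PowerTargetError, detection_threshold, power_curve
from .survival import TestResult, mean_lifespan, peto_prentice_test

__all__ = [
    "AnalysisConfig",
    "IndependenceReport",
    "stratify",
    "run_independence_analysis",
    "run_scenario_suite",
]

logger = logging.getLogger("neuronspan")

GROUPING_MODES = ("any_missing", "n_dorsal", "n_ventral", "n_total")


def stratify(
    cohort: Cohort, mode: str, neuron: Neuron | None = None
) -> dict[str, np.ndarray]:
    """Group the scorable animals' lifespans by neuron state.

    Modes: ``per_neuron`` (requires ``neuron``; labels present/absent),
    ``any_missing``, ``n_dorsal``, ``n_ventral``, ``n_total`` (labels are
    missing-neuron counts). Animals never imaged (dead before the
    observation day) are excluded. Empty groups are dropped.
    """
    scorable = cohort.scorable()
    if not scorable:
        raise ValueError("cohort has no scorable animals")

    def label(ind) -> str:
        if mode == "per_neuron":
            if neuron is None:
                raise ValueError("per_neuron mode requires a neuron")
            return "present" if ind.neuron_state[neuron] else "absent"
        if mode == "any_missing":
            return "any_missing" if ind.n_absent() > 0 else "none_missing"
        if mode == "n_dorsal":
            return str(ind.n_absent(DORSAL))
        if mode == "n_ventral":
            return str(ind.n_absent(VENTRAL))
        if mode == "n_total":
            return str(ind.n_absent())
        raise ValueError(f"unknown stratification mode {mode!r}")

    groups: dict[str, list[int]] = {}
    for ind in scorable:
        groups.setdefault(label(ind), []).append(ind.lifespan_days)
    return {k: np.array(v, dtype=float) for k, v in sorted(groups.items())}


@dataclasses.dataclass
class AnalysisConfig:
    """Knobs for :func:`run_independence_analysis`.

    Defaults reproduce the full design (5000 replicates over a 75-point
    correlation grid); scale ``power_replicates``/``grid_points`` down for
    interactive use.
    """

    alpha: float = 0.05
    run_power: bool = True
    power_replicates: int = 5000
    grid_points: int = 75
    grid_max: float = 0.5
    target_power: float = 0.95
    seed: int | None = None

    def grid(self) -> np.ndarray:
        from .power import correlation_grid

        return correlation_grid(self.grid_points, self.grid_max)


@dataclasses.dataclass
class IndependenceReport:
    """Machine-readable result bundle of one cohort analysis."""

    n_total: int
    n_scorable: int
    observation_day: int
    per_neuron: dict
    groupings: dict
    power: dict | None
    warnings: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _test_entry(groups: Mapping[str, np.ndarray]) -> dict:
    result = peto_prentice_test(list(groups.values()))
    return {
        "groups": {
            name: {"n": int(g.size), "mean_lifespan": float(mean_lifespan(g))}
            for name, g in groups.items()
        },
        "test": result.to_dict(),
    }


def run_independence_analysis(
    cohort: Cohort, config: AnalysisConfig | None = None
) -> IndependenceReport:
    """Run the full independence analysis on one cohort.

    Two Bonferroni families: the four per-neuron present-vs-absent tests,
    and the four grouping tests. The power stage reuses the scorable
    animals' lifespans as the empirical marginal and the observed absent
    counts as the group sizes, mirroring the actual experiment's design.
    """
    config = config or AnalysisConfig()
    if len(cohort) < 2:
        raise ValueError("cohort too small to analyze")
    warnings: list[str] = []

    per_neuron: dict[str, dict] = {}
    for nid in NEURONS:
        groups = stratify(cohort, "per_neuron", neuron=nid)
        if len(groups) < 2:
            msg = f"per-neuron comparison for {nid.value} skipped: single group"
            warnings.append(msg)
            logger.warning(msg)
            continue
        per_neuron[nid.value] = _test_entry(groups)
    ps = [v["test"]["p_value"] for v in per_neuron.values()]
    for entry, adj in zip(per_neuron.values(), bonferroni_adjust(ps)):
        entry["p_adjusted"] = float(adj)

    groupings: dict[str, dict] = {}
    for mode in GROUPING_MODES:
        groups = stratify(cohort, mode)
        if len(groups) < 2:
            msg = f"grouping {mode!r} skipped: fewer than two nonempty groups"
            warnings.append(msg)
            logger.warning(msg)
            continue
        groupings[mode] = _test_entry(groups)
    ps = [v["test"]["p_value"] for v in groupings.values()]
    for entry, adj in zip(groupings.values(), bonferroni_adjust(ps)):
        entry["p_adjusted"] = float(adj)

    power_section = None
    if config.run_power:
        lifespans = cohort.lifespans(scorable_only=True)
        counts = cohort.absent_counts()
        grid = config.grid()
        power_section = {}
        seeds = np.random.SeedSequence(config.seed).spawn(len(NEURONS))
        for nid, child in zip(NEURONS, seeds):
            k = counts[nid]
            if not 0 < k < lifespans.size:
                msg = f"power analysis for {nid.value} skipped: k_absent={k}"
                warnings.append(msg)
                logger.warning(msg)
                continue
            seed_int = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            curve = power_curve(
                lifespans, k, grid, config.power_replicates, config.alpha, seed_int
            )
            try:
                rho_star = detection_threshold(curve, config.target_power)
            except PowerTargetError as exc:
                rho_star = None
                warnings.append(f"{nid.value}: {exc}")
            power_section[nid.value] = {
                "k_absent": int(k),
                "detection_threshold": rho_star,
                "target_power": config.target_power,
                "curve": curve.to_dict(),
            }

    return IndependenceReport(
        n_total=len(cohort),
        n_scorable=len(cohort.scorable()),
        observation_day=cohort.observation_day,
        per_neuron=per_neuron,
        groupings=groupings,
        power=power_section,
        warnings=warnings,
    )


def is_independent(report: IndependenceReport, alpha: float = 0.05) -> bool:
    """True when no Bonferroni-adjusted p-value in either family falls
    below ``alpha`` — the cohort shows no detectable loss/lifespan coupling."""
    adj = [e["p_adjusted"] for e in report.per_neuron.values()]
    adj += [e["p_adjusted"] for e in report.groupings.values()]
    return all(p >= alpha for p in adj)


def run_scenario_suite(config: Mapping, out_dir: str | Path) -> dict:
    """Generate cohorts for the configured scenarios, analyze each, and
    write cohort CSVs, report JSONs, and a run log.

    ``config`` keys: ``seed`` (root seed, int), ``scenarios`` (list of
    ``{"name": ..., "n": ...}``, optionally with ``rho_s`` overriding the
    coupling and any ``analysis`` overrides), ``analysis`` (global
    :class:`AnalysisConfig` fields). Reruns with the same config are
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries: Sequence[Mapping] = config.get("scenarios", [])
    if not entries:
        raise ValueError("config lists no scenarios")
    for entry in entries:  # validate everything before any computation
        name = entry.get("name")
        if name not in SCENARIOS and "scenario" not in entry:
            raise ValueError(f"unknown scenario {name!r}")
        if int(entry.get("n", 0)) < 1:
            raise ValueError(f"scenario {name!r}: n must be >= 1")

    root = np.random.SeedSequence(config.get("seed", 0))
    children = root.spawn(len(entries))
    analysis_kwargs = dict(config.get("analysis", {}))
    bundle = {"seed": config.get("seed", 0), "version": __version__, "reports": {}}
    for entry, child in zip(entries, children):
        name = entry["name"]
        n = int(entry["n"])
        if "scenario" in entry:
            scenario = Scenario.from_dict(entry["scenario"])
        else:
            scenario = SCENARIOS[name]
        if "rho_s" in entry:
            scenario = dataclasses.replace(
                scenario, coupling_rho_s=float(entry["rho_s"])
            )
        sub = child.generate_state(2, dtype=np.uint32) % (2**31)
        cohort = generate_cohort(scenario, n, int(sub[0]))
        write_cohort(cohort, out / f"{name}_cohort.csv")
        cfg = AnalysisConfig(**{**analysis_kwargs, **entry.get("analysis", {})})
        cfg.seed = int(sub[1])
        logger.info("analyzing scenario %s (n=%d)", name, n)
        report = run_independence_analysis(cohort, cfg)
        report.to_json(out / f"{name}_report.json")
        bundle["reports"][name] = report.to_dict()
    log = {
        "seed": bundle["seed"],
        "version": __version__,
        "python": platform.python_version(),
        "scenarios": [dict(e) for e in entries],
    }
    (out / "run_log.json").write_text(json.dumps(log, sort_keys=True, indent=1))
    return bundle
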