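"""Virtual candidate cohorts and the scenario grid.

A candidate is one (KD, T0, t1/2) triple drawn log-uniformly over the
screening ranges (1 pM - 1000 nM binding affinity and target baseline,
1 min - 300 h target half-life).  A scenario fixes the experimental axes —
dose, regimen, antibody net charge, target form and evaluation site — and
the same candidate table is reused across the scenarios of a sweep so that
cutoff differences between scenarios are not confounded by sampling noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform

from . import endpoints as ep
from .batch import run_cohort_batch
from .model_core import SITES, PhysiologyParams

__all__ = [
    "REGIMENS", "Scenario", "sample_candidates", "build_scenarios",
    "results_scenarios", "run_cohort", "label_dataset",
]

#: dosing interval in days per regimen name (None = single bolus)
REGIMENS: dict[str, float | None] = {
    "bolus": None, "Q1W": 7.0, "Q2W": 14.0, "Q4W": 28.0}

ALLOWED = {
    "dose": (0.1, 1.0, 10.0),
    "regimen": tuple(REGIMENS),
    "charge": (-5, 0, 5),
    "form": ("soluble", "membrane"),
    "site": SITES,
}


@dataclass(frozen=True)
class Scenario:
    """One point of the experimental grid."""

    dose: float = 1.0
    regimen: str = "Q2W"
    charge: int = 0
    form: str = "soluble"
    site: str = "plasma"

    def __post_init__(self) -> None:
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")
        if self.form not in ALLOWED["form"]:
            raise ValueError(f"unknown target form {self.form!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if not self.dose > 0:
            raise ValueError("dose must be > 0")

    @property
    def interval_days(self) -> float | None:
        return REGIMENS[self.regimen]

    @property
    def scenario_id(self) -> str:
        return (f"d{self.dose:g}_{self.regimen}_c{self.charge:+d}_"
                f"{self.form}_{self.site}")

    @property
    def physical_key(self) -> tuple:
        """Axes that change the simulation (site is evaluation-only)."""
        return (self.dose, self.regimen, self.charge, self.form)

    def as_dict(self) -> dict:
        return asdict(self)


def sample_candidates(n: int, ranges: Mapping[str, Sequence[float]],
                      seed: int) -> pd.DataFrame:
    """Draw *n* candidates, each axis independently log-uniform on its range.

    Reproducible under ``seed``; returns columns candidate_id, kd_nM,
    t0_nM, thalf_h.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    for axis in ("kd", "t0", "t_half"):
        lo, hi = ranges[axis]
        if not 0 < lo < hi:
            raise ValueError(f"invalid range for {axis}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    cols = {}
    for axis, name in (("kd", "kd_nM"), ("t0", "t0_nM"),
                       ("t_half", "thalf_h")):
        lo, hi = ranges[axis]
        cols[name] = loguniform.rvs(lo, hi, size=n, random_state=rng)
    df = pd.DataFrame(cols)
    df.insert(0, "candidate_id", [f"c{i:06d}" for i in range(n)])
    return df


def build_scenarios(axes: Mapping[str, Iterable[Any]] | None = None,
                    validate: bool = True) -> list[Scenario]:
    """Cartesian product of the requested axis values.

    Missing axes default to the base scenario (1 mg/kg Q2W, charge 0,
    soluble, plasma).  ``validate`` restricts values to the study grid.
    """
    axes = dict(axes or {})
    grid = {}
    base = Scenario()
    for name in ("dose", "regimen", "charge", "form", "site"):
        values = list(axes.pop(name, [getattr(base, name)]))
        if not values:
            raise ValueError(f"empty axis {name!r}")
        if validate:
            for v in values:
                if v not in ALLOWED[name]:
                    raise ValueError(
                        f"{name}={v!r} outside the allowed set "
                        f"{ALLOWED[name]}; pass validate=False to override")
        grid[name] = values
    if axes:
        raise ValueError(f"unknown scenario axes: {sorted(axes)}")
    return [Scenario(**dict(zip(grid, combo)))
            for combo in itertools.product(*grid.values())]


def results_scenarios() -> list[Scenario]:
    """The default scenario set mirroring the headline sweeps:

    dose sweep (0.1/1/10 mg/kg at Q2W), regimen sweep (Q1W/Q2W/Q4W at
    1 mg/kg), charge sweep (-5/0/+5), target-form sweep read in leaky
    tissue, and site sweep (plasma/leaky/tight); duplicates collapsed.
    """
    scen: list[Scenario] = []
    scen += build_scenarios({"dose": [0.1, 1.0, 10.0]})
    scen += build_scenarios({"regimen": ["Q1W", "Q2W", "Q4W"]})
    scen += build_scenarios({"charge": [-5, 0, 5]})
    scen += build_scenarios({"form": ["soluble", "membrane"],
                             "site": ["leaky"]})
    scen += build_scenarios({"site": list(SITES)})
    seen, out = set(), []
    for s in scen:
        if s.scenario_id not in seen:
            seen.add(s.scenario_id)
            out.append(s)
    return out


def label_dataset(sim: pd.DataFrame, site: str,
                  binary_threshold: float = 90.0,
                  multi_thresholds: Sequence[float] = (50.0, 90.0)
                  ) -> pd.DataFrame:
    """Attach per-site TO columns and class labels to a simulation table."""
    out = sim.copy()
    out["to_cmin_pct"] = sim[f"to_cmin_{site}"]
    out["to_cmax_pct"] = sim[f"to_cmax_{site}"]
    out["label_binary"] = np.where(out["to_cmin_pct"] > binary_threshold,
                                   "optimal", "non_optimal")
    lo, hi = multi_thresholds
    out["label_multi"] = np.select(
        [out["to_cmin_pct"] <= lo, out["to_cmin_pct"] <= hi],
        ["low", "medium"], default="high")
    return out


def run_cohort(candidates: pd.DataFrame, scenarios: Sequence[Scenario],
               phys: PhysiologyParams, config: Mapping[str, Any],
               max_failure_rate: float = 0.05,
               checkpoint_dir: str | None = None,
               progress: bool = False) -> dict[str, pd.DataFrame]:
    """Simulate the cohort under every scenario and label it.

    Scenarios sharing a physical key (dose, regimen, charge, form) are
    simulated once; the evaluation site only selects which TO columns feed
    the labels.  Returns ``{scenario_id: labeled DataFrame}``.  A fraction
    of solver failures above ``max_failure_rate`` aborts with a report.
    With ``checkpoint_dir`` each physical simulation is cached to CSV and
    reloaded on re-run.
    """
    import pathlib

    solver = config["solver"]
    ss = config["steady_state"]
    drug = config["drug_defaults"]
    labels_cfg = config["labels"]
    results: dict[str, pd.DataFrame] = {}
    if len(candidates) == 0:
        return {s.scenario_id: pd.DataFrame() for s in scenarios}

    groups: dict[tuple, list[Scenario]] = {}
    for s in scenarios:
        groups.setdefault(s.physical_key, []).append(s)

    for key, group in groups.items():
        dose, regimen, charge, form = key
        tag = f"d{dose:g}_{regimen}_c{charge:+d}_{form}"
        cache = (pathlib.Path(checkpoint_dir) / f"sim_{tag}.csv"
                 if checkpoint_dir else None)
        if cache is not None and cache.exists():
            sim = pd.read_csv(cache)
        else:
            if progress:
                print(f"[mtpa] simulating {tag} "
                      f"({len(candidates)} candidates)")
            sim = run_cohort_batch(
                candidates["kd_nM"].to_numpy(),
                candidates["t0_nM"].to_numpy(),
                candidates["thalf_h"].to_numpy(),
                form=form, dose_mg_kg=dose,
                interval_days=REGIMENS[regimen], charge=charge,
                phys=phys, mw=drug["mw"], kon=drug["kon"],
                rtol=solver["rtol"], atol=solver["atol"],
                n_points=solver["n_points_per_interval"],
                trough_rtol=ss["trough_rtol"],
                max_intervals=ss["max_intervals"],
                bolus_horizon_days=ss["bolus_horizon_days"])
            sim = pd.concat(
                [candidates.reset_index(drop=True), sim], axis=1)
            if cache is not None:
                cache.parent.mkdir(parents=True, exist_ok=True)
                sim.to_csv(cache, index=False)
        fail_rate = sim["failed"].mean()
        if fail_rate > max_failure_rate:
            bad = sim.loc[sim["failed"],
                          ["candidate_id", "kd_nM", "t0_nM", "thalf_h"]]
            raise RuntimeError(
                f"solver failure rate {fail_rate:.1%} exceeds budget "
                f"{max_failure_rate:.1%} for {tag}; failing candidates:\n"
                f"{bad.to_string(index=False)}")
        for s in group:
            results[s.scenario_id] = label_dataset(
                sim, s.site,
                binary_threshold=labels_cfg["binary_threshold"],
                multi_thresholds=labels_cfg["multi_thresholds"])
    return results
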