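"""Factorial scenario design, batch running, and summary contrasts.

The study design crosses reef habitat quality with mangrove-nursery access
and fishing: each healthy-reef crevice census and its degraded counterpart
is run with no nursery and with each of the mangrove supplements, at each
fishing level.  With 7 habitat pairs and 16 supplements this gives, per
fishing level, 14 non-nursery + 224 nursery = 238 scenarios.  Summaries
aggregate equilibrium metrics into cells (complexity x mangrove x fishing x
group) and report the cell means/variances and the headline contrasts:
percent change from mangrove access within a complexity level, and the
growth-rate ratio between low- and high-complexity mangrove reefs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import SizeGrid
from .habitat import CreviceDistribution, crevices_to_refuge_profile, degrade
from .model import EquilibriumResult, ReefEcosystemModel
from .nursery import NurserySupplement
from .params import FISH_GROUPS, ModelParams

__all__ = [
    "Scenario",
    "ScenarioSummary",
    "build_factorial",
    "run_all",
    "results_frame",
    "summarize",
]

COMPLEXITY_LEVELS = ("high", "low")


@dataclass(frozen=True)
class Scenario:
    """One habitat x nursery x fishing combination."""

    habitat_id: str
    complexity: str  # 'high' (healthy census) or 'low' (degraded)
    census: CreviceDistribution
    nursery: NurserySupplement | None
    fishing_F: float
    seed: int = 0

    def __post_init__(self):
        if self.complexity not in COMPLEXITY_LEVELS:
            raise ValueError(f"complexity must be one of {COMPLEXITY_LEVELS}")
        if self.fishing_F < 0:
            raise ValueError("fishing_F must be non-negative")

    @property
    def scenario_id(self) -> str:
        nurs = self.nursery.site_id if self.nursery else "none"
        return f"{self.habitat_id}|{self.complexity}|{nurs}|F{self.fishing_F:g}"

    def cache_key(self, params: ModelParams) -> str:
        """Hash of everything that determines the (deterministic) outcome."""
        payload = {
            "habitat": self.habitat_id,
            "complexity": self.complexity,
            "edges": self.census.class_edges.tolist(),
            "densities": self.census.densities.tolist(),
            "nursery": None
            if self.nursery is None
            else [self.nursery.site_id, self.nursery.predator_density, self.nursery.herbivore_density],
            "F": self.fishing_F,
            "params": params.to_dict(),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def build_factorial(
    healthy: list[CreviceDistribution],
    supplements: list[NurserySupplement],
    F_levels=(0.0,),
) -> list[Scenario]:
    """Enumerate the full factorial design.

    Each healthy census supplies a high-complexity scenario and, through the
    degradation transform, its low-complexity counterpart; both are crossed
    with {no nursery} + supplements and with the fishing levels, giving
    ``2 * n_habitats * (1 + n_supplements) * n_F`` scenarios.
    """
    if not healthy:
        raise ValueError("expected at least one healthy-reef crevice census, got 0")
    scenarios = []
    for F in F_levels:
        for census in healthy:
            for complexity in COMPLEXITY_LEVELS:
                for nursery in [None, *supplements]:
                    scenarios.append(
                        Scenario(
                            habitat_id=census.site_id,
                            complexity=complexity,
                            census=census,
                            nursery=nursery,
                            fishing_F=float(F),
                        )
                    )
    return scenarios


def run_all(
    scenarios: list[Scenario],
    params: ModelParams | None = None,
    grid: SizeGrid | None = None,
    cache: dict | None = None,
    progress: bool = False,
) -> list[tuple[Scenario, EquilibriumResult]]:
    """Run every scenario to equilibrium (deterministic; cached by hash).

    Non-converged runs are kept in the returned list but flagged; a warning
    is emitted and ``summarize`` excludes them.
    """
    params = params or ModelParams()
    grid = grid or SizeGrid.build()
    cache = cache if cache is not None else {}
    out = []
    for i, sc in enumerate(scenarios):
        key = sc.cache_key(params)
        if key not in cache:
            model = ReefEcosystemModel(
                habitat=sc.census,
                nursery=sc.nursery,
                params=params.replace(fishing_F=sc.fishing_F),
                grid=grid,
                degraded=(sc.complexity == "low"),
            )
            cache[key] = model.fit()
        res = cache[key]
        if not res.converged:
            warnings.warn(f"scenario {sc.scenario_id} did not converge", stacklevel=2)
        out.append((sc, res))
        if progress and (i + 1) % 25 == 0:  # pragma: no cover - cosmetics
            print(f"  ran {i + 1}/{len(scenarios)} scenarios")
    return out


def results_frame(results: list[tuple[Scenario, EquilibriumResult]]) -> pd.DataFrame:
    """Tidy per-scenario metrics table (one row per scenario)."""
    rows = []
    for sc, res in results:
        row = {
            "scenario_id": sc.scenario_id,
            "habitat_id": sc.habitat_id,
            "complexity": sc.complexity,
            "mangrove": sc.nursery is not None,
            "nursery_id": sc.nursery.site_id if sc.nursery else "",
            "fishing_F": sc.fishing_F,
        }
        row.update(res.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioSummary:
    """Cell-level summary of a factorial run.

    ``cells`` has one row per (fishing_F, complexity, mangrove) cell and
    group-wise mean / sample variance / standard error of standing stock
    and fisheries productivity, plus the mean specific growth rates.
    Contrast helpers compute the headline percent changes and ratios from
    matched cells; percent changes are ratios of cell means.
    """

    cells: pd.DataFrame
    n_excluded: int

    def _cell(self, F: float, complexity: str, mangrove: bool) -> pd.Series:
        m = self.cells[
            (self.cells["fishing_F"] == F)
            & (self.cells["complexity"] == complexity)
            & (self.cells["mangrove"] == mangrove)
        ]
        if m.empty:
            raise ValueError(
                f"no summary cell for F={F}, complexity={complexity!r}, mangrove={mangrove}"
            )
        return m.iloc[0]

    def cell_mean(self, metric: str, group: str, F: float, complexity: str, mangrove: bool) -> float:
        return float(self._cell(F, complexity, mangrove)[f"{metric}_{group}_mean"])

    def cell_variance(self, metric: str, group: str, F: float, complexity: str, mangrove: bool) -> float:
        return float(self._cell(F, complexity, mangrove)[f"{metric}_{group}_var"])

    def mangrove_percent_change(
        self, metric: str, group: str, complexity: str, F: float = 0.0
    ) -> float:
        """Percent change of a cell-mean metric when mangroves are present,
        within one complexity level: 100 * (with - without) / without."""
        without = self.cell_mean(metric, group, F, complexity, False)
        with_ = self.cell_mean(metric, group, F, complexity, True)
        if without == 0:
            raise ValueError("undefined percent change: reference cell mean is zero")
        return 100.0 * (with_ - without) / without

    def complexity_percent_change(self, metric: str, group: str, mangrove: bool, F: float = 0.0) -> float:
        """Percent change from low- to high-complexity reefs at fixed
        mangrove status: 100 * (high - low) / low."""
        low = self.cell_mean(metric, group, F, "low", mangrove)
        high = self.cell_mean(metric, group, F, "high", mangrove)
        if low == 0:
            raise ValueError("undefined percent change: low-complexity cell mean is zero")
        return 100.0 * (high - low) / low

    def growth_ratio_percent(self, group: str = "predators", F: float = 0.0, baseline: str = "high_mangrove") -> float:
        """Mean specific growth on low-complexity mangrove reefs relative to
        a baseline cell, as a percentage (100 = equal).

        ``baseline='high_mangrove'`` contrasts against high-complexity
        mangrove reefs; ``'low_no_mangrove'`` against low-complexity reefs
        without nurseries.
        """
        num = self.cell_mean("mean_growth", group, F, "low", True)
        if baseline == "high_mangrove":
            den = self.cell_mean("mean_growth", group, F, "high", True)
        elif baseline == "low_no_mangrove":
            den = self.cell_mean("mean_growth", group, F, "low", False)
        else:
            raise ValueError("baseline must be 'high_mangrove' or 'low_no_mangrove'")
        if den == 0:
            raise ValueError("undefined growth ratio: baseline mean growth is zero")
        return 100.0 * num / den

    def to_csv(self, path) -> None:
        self.cells.sort_values(["fishing_F", "complexity", "mangrove"]).to_csv(path, index=False)


def summarize(results) -> ScenarioSummary:
    """Aggregate per-scenario metrics into factorial cells.

    Accepts the output of :func:`run_all` or an already-tidy
    :func:`results_frame`.  Non-converged scenarios are excluded (counted in
    ``n_excluded``).  Variances are sample variances (ddof=1) over the
    scenario-level values within a cell; ordering of the input does not
    affect the output.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    n0 = len(df)
    if "converged" in df.columns:
        df = df[df["converged"]]
    if df.empty:
        raise ValueError("no converged scenarios to summarise")
    metrics = [f"{m}_{g}" for g in FISH_GROUPS for m in ("biomass", "productivity", "mean_growth")]
    rows = []
    for (F, complexity, mangrove), cell in df.groupby(["fishing_F", "complexity", "mangrove"]):
        row = {
            "fishing_F": F,
            "complexity": complexity,
            "mangrove": mangrove,
            "n_scenarios": len(cell),
        }
        for met in metrics:
            vals = cell[met].to_numpy(float)
            row[f"{met}_mean"] = vals.mean()
            row[f"{met}_var"] = vals.var(ddof=1) if len(vals) > 1 else 0.0
            row[f"{met}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
        rows.append(row)
    cells = pd.DataFrame(rows).sort_values(["fishing_F", "complexity", "mangrove"]).reset_index(drop=True)
    return ScenarioSummary(cells=cells, n_excluded=n0 - len(df))
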