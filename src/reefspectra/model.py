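"""Model and results objects for equilibrium reef-community analysis.

:class:`ReefEcosystemModel` binds data (a crevice census or refuge profile,
an optional mangrove nursery supplement, a parameter set) into a runnable
model; :meth:`ReefEcosystemModel.fit` integrates the community to
equilibrium and returns an :class:`EquilibriumResult` carrying standing
stocks, fisheries productivity, realised growth rates, convergence
diagnostics and a ``summary()`` table, in the style of a statsmodels
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import CommunityState, ReefDynamics, StepDiagnostics
from .grid import SizeGrid
from .habitat import CreviceDistribution, RefugeProfile, crevices_to_refuge_profile
from .habitat import degrade as degrade_census
from .nursery import NurserySupplement, subsidy_vector
from .params import FISH_GROUPS, GROUPS, ModelParams

__all__ = ["ReefEcosystemModel", "EquilibriumResult"]


class ReefEcosystemModel:
    """Size-based energy-flux model of a reef community on one habitat.

    Parameters
    ----------
    habitat : RefugeProfile, CreviceDistribution or None
        Refuge availability on the model mass grid.  A crevice census is
        converted automatically; ``None`` means a structureless reef.
    nursery : NurserySupplement, optional
        Mangrove nursery supplement; adds predator and herbivore inflow at
        the ontogenetic-migration size every time step.
    params : ModelParams, optional
        Model parameters (defaults used if omitted).
    grid : SizeGrid, optional
        Body-mass grid; defaults to 100 log bins over 0.025 g - 20 kg.
    degraded : bool
        If True and ``habitat`` is a crevice census, apply the habitat
        degradation transform before building the refuge profile.

    Examples
    --------
    >>> model = ReefEcosystemModel(census, nursery=supplement)
    >>> res = model.fit()
    >>> res.biomass("predators"), res.productivity("predators")
    """

    def __init__(self, habitat=None, nursery=None, params=None, grid=None, degraded=False):
        self.params = params if params is not None else ModelParams()
        self.grid = grid if grid is not None else SizeGrid.build()
        if isinstance(habitat, CreviceDistribution):
            census = degrade_census(habitat) if degraded else habitat
            habitat = crevices_to_refuge_profile(census, self.grid)
        elif degraded:
            raise ValueError("degraded=True requires a CreviceDistribution habitat")
        self.habitat = habitat if habitat is not None else RefugeProfile.zero(self.grid)
        self.nursery = nursery
        subsidy = None
        if nursery is not None:
            subsidy = {
                grp: subsidy_vector(nursery, self.grid, group=grp) for grp in FISH_GROUPS
            }
        self.dynamics = ReefDynamics(self.grid, self.params, self.habitat, subsidy)

    @classmethod
    def from_crevice_census(cls, census, degraded=False, **kwargs):
        """Build a model from a crevice census (optionally degraded)."""
        return cls(habitat=census, degraded=degraded, **kwargs)

    # ------------------------------------------------------------------

    def default_start(self) -> CommunityState:
        return CommunityState.seed(self.grid)

    def simulate(self, t_end: float, start: CommunityState | None = None, record_every: int = 1):
        """Integrate for a fixed duration; returns (state, trajectory frame)."""
        state = (start or self.default_start()).copy()
        rows = []
        n_steps = int(round(t_end / self.params.dt))
        for k in range(n_steps):
            state, diag = self.dynamics.step(state)
            if (k + 1) % record_every == 0:
                rows.append(self._trajectory_row(state, diag))
        return state, pd.DataFrame(rows)

    def _trajectory_row(self, state: CommunityState, diag: StepDiagnostics) -> dict:
        row = {"time": state.time}
        for grp in GROUPS:
            row[f"biomass_{grp}"] = state.biomass(self.grid, grp)
        row["algae"] = state.algae
        row["detritus"] = state.detritus
        row["residual"] = diag.residual
        row["clip_count"] = diag.clip_count
        return row

    def fit(self, start: CommunityState | None = None, record_every: int = 10) -> "EquilibriumResult":
        """Integrate to equilibrium and return the results object.

        The run is declared converged when the relative change of every
        group's standing stock over a trailing window of ``eq_window`` years
        falls below ``eq_tol``; integration stops then, or at ``t_max``
        with ``converged=False``.  Trajectory rows are recorded every
        ``record_every`` steps.
        """
        p = self.params
        state = (start or self.default_start()).copy()
        window_steps = max(1, int(round(p.eq_window / p.dt)))
        n_steps = int(round(p.t_max / p.dt))
        rows = []
        converged = False
        max_residual = 0.0
        clip_total = 0
        step_count = 0
        # convergence on the within-window *spread* of each group's biomass:
        # (max - min) / mean < eq_tol over a trailing window, which a slow
        # drift or an oscillation cannot satisfy at one lucky instant
        win_lo = np.full(len(GROUPS), np.inf)
        win_hi = np.full(len(GROUPS), -np.inf)
        for k in range(n_steps):
            state, diag = self.dynamics.step(state)
            step_count += 1
            max_residual = max(max_residual, abs(diag.residual))
            clip_total += diag.clip_count
            cur = np.array([state.biomass(self.grid, grp) for grp in GROUPS])
            np.minimum(win_lo, cur, out=win_lo)
            np.maximum(win_hi, cur, out=win_hi)
            if (k + 1) % record_every == 0 or k == n_steps - 1:
                rows.append(self._trajectory_row(state, diag))
            if (k + 1) % window_steps == 0:
                mean = 0.5 * (win_hi + win_lo)
                denom = np.where(mean > 0, mean, 1.0)
                if np.all((win_hi - win_lo) / denom < p.eq_tol):
                    converged = True
                    break
                win_lo[:] = np.inf
                win_hi[:] = -np.inf
        return EquilibriumResult(
            model=self,
            final_state=state,
            converged=converged,
            n_steps=step_count,
            max_residual=max_residual,
            clip_count=clip_total,
            trajectory=pd.DataFrame(rows),
        )


@dataclass
class EquilibriumResult:
    """Equilibrium community metrics for one habitat x nursery x fishing run.

    Carries the final :class:`CommunityState`, convergence diagnostics and a
    per-step trajectory of group standing stocks; standing stock, fisheries
    productivity and mean growth are exposed as methods, ``summary()``
    renders them as a table.
    """

    model: ReefEcosystemModel
    final_state: CommunityState
    converged: bool
    n_steps: int
    max_residual: float
    clip_count: int
    trajectory: pd.DataFrame
    _growth: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self._growth = self.model.dynamics.growth_rates(self.final_state)

    # ------------------------------------------------------------------

    @property
    def grid(self) -> SizeGrid:
        return self.model.grid

    def biomass(self, group: str) -> float:
        """Equilibrium standing stock of one group, g m^-2."""
        return self.final_state.biomass(self.grid, group)

    @property
    def biomass_by_group(self) -> dict:
        return {grp: self.biomass(grp) for grp in GROUPS}

    def _fished_mask(self) -> np.ndarray:
        return self.grid.mass >= self.model.params.fished_min_mass

    def growth_rate(self, group: str) -> np.ndarray:
        """Realised per-capita somatic growth g(m) at equilibrium, g yr^-1."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        return self._growth[group]

    def productivity(self, group: str) -> float:
        """Fisheries productivity: growth x abundance over the fished range.

        Sum over fished bins of g(m) N(m), in g m^-2 yr^-1 — the rate of
        biomass production available to the fishery, not standing stock.
        """
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        mask = self._fished_mask()
        n = self.final_state.spectrum(group)
        return float((self._growth[group][mask] * n[mask]).sum())

    @property
    def productivity_by_group(self) -> dict:
        return {grp: self.productivity(grp) for grp in FISH_GROUPS}

    def mean_growth(self, group: str) -> float:
        """Abundance-weighted mean specific growth g(m)/m over the fished
        range, yr^-1 (a turnover rate)."""
        mask = self._fished_mask()
        n = self.final_state.spectrum(group)[mask]
        if n.sum() == 0:
            return 0.0
        spec = self._growth[group][mask] / self.grid.mass[mask]
        return float((spec * n).sum() / n.sum())

    @property
    def catch_rate(self) -> float:
        """Equilibrium fishery yield, g m^-2 yr^-1 (0 when unfished)."""
        p = self.model.params
        if p.fishing_F == 0:
            return 0.0
        mask = self._fished_mask()
        m = self.grid.mass[mask]
        total = 0.0
        for grp in FISH_GROUPS:
            total += float(p.fishing_F * (self.final_state.spectrum(grp)[mask] @ m))
        return total

    # ------------------------------------------------------------------

    def to_row(self) -> dict:
        """Flat metrics dict (one row of a scenario results table)."""
        row = {
            "converged": self.converged,
            "n_steps": self.n_steps,
            "max_residual": self.max_residual,
            "clip_count": self.clip_count,
            "algae": self.final_state.algae,
            "detritus": self.final_state.detritus,
            "catch_rate": self.catch_rate,
        }
        for grp in GROUPS:
            row[f"biomass_{grp}"] = self.biomass(grp)
        for grp in FISH_GROUPS:
            row[f"productivity_{grp}"] = self.productivity(grp)
            row[f"mean_growth_{grp}"] = self.mean_growth(grp)
        return row

    def summary(self) -> str:
        """Human-readable equilibrium summary table."""
        p = self.model.params
        lines = [
            "Reef ecosystem equilibrium summary",
            "=" * 54,
            f"converged: {self.converged}   steps: {self.n_steps}"
            f"   time: {self.final_state.time:.1f} yr",
            f"fishing F: {p.fishing_F:g} /yr   fished size: >= {p.fished_min_length:g} cm",
            f"nursery: {'yes' if self.model.nursery is not None else 'no'}"
            f"   refuges: {self.model.habitat.total_density:.3g} /m^2",
            f"max |mass-budget residual|: {self.max_residual:.3g} g/m^2"
            f"   clip events: {self.clip_count}",
            "-" * 54,
            f"{'group':<14}{'biomass':>12}{'productivity':>14}{'mean growth':>14}",
            f"{'':<14}{'g/m^2':>12}{'g/m^2/yr':>14}{'1/yr':>14}",
            "-" * 54,
        ]
        for grp in GROUPS:
            prod = self.productivity(grp) if grp in FISH_GROUPS else float("nan")
            mg = self.mean_growth(grp) if grp in FISH_GROUPS else float("nan")
            lines.append(f"{grp:<14}{self.biomass(grp):>12.3f}{prod:>14.3f}{mg:>14.3f}")
        lines.append("-" * 54)
        lines.append(
            f"{'algae pool':<14}{self.final_state.algae:>12.3f}"
            f"   {'detritus pool':<14}{self.final_state.detritus:>12.3f}"
        )
        return "\n".join(lines)
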