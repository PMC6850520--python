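"""Model parameters: definitions, defaults, and YAML round-trip.

All rates are annual; masses in grams; areal densities per m^2.  The default
values are the package's reference parameterisation for a Caribbean forereef:
allometric exponents and the predator-prey mass-ratio kernel follow standard
size-spectrum practice, and the remaining free coefficients were calibrated
once so that the unfished factorial of habitat x nursery scenarios produces
fish standing stocks of realistic magnitude and the documented qualitative
responses to complexity and nursery access (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

GROUPS = ("predators", "herbivores", "invertebrates")
FISH_GROUPS = ("predators", "herbivores")


@dataclass
class ModelParams:
    """Parameters of the three-spectrum reef community model.

    Attributes
    ----------
    ppmr_mean : float
        Preferred predator-prey mass ratio expressed in ln units
        (the default 4.158 means a predator prefers prey ~64x lighter).
    ppmr_sigma : float
        Width (SD) of the log-normal feeding kernel, ln-mass units.
    search_coeff, search_exp : float
        Volumetric search rate A(m) = search_coeff * m**search_exp,
        m^2 yr^-1 g^-search_exp.
    intake_max_coeff : float
        Satiation ceiling: ingestion cannot exceed
        intake_max_coeff * m**search_exp g yr^-1 per individual.
    interference : float
        Predator interference (Beddington-DeAngelis): realised predator
        encounter is divided by (1 + interference * total predator biomass),
        m^2 g^-1.  Represents contest behaviour among predators and damps
        predator-prey cycles.
    conversion_eff : float
        Fraction of ingested mass converted to somatic growth.
    defecation_frac : float
        Fraction of ingestion routed to the detritus pool; the remainder
        (1 - conversion_eff - defecation_frac) is respired.
    background_mort_coeff, background_mort_exp : float
        Intrinsic (non-predation) mortality mu_b = coeff * m**exp, yr^-1.
    senescence_coeff, senescence_exp : float
        Extra mortality rising with size, coeff * (m / m_senesce)**exp yr^-1,
        which closes the spectrum at each group's characteristic maximum size.
    m_senesce : dict
        Per-group senescence reference mass (g); invertebrates are small-bodied.
    larval_input : dict
        Boundary recruitment, individuals m^-2 yr^-1, entering each group's
        smallest bin.
    recruit_length : float
        Body length (cm) at which fish larvae settle onto the reef; fish
        recruitment enters the bin containing this length, invertebrates
        recruit at the base of the grid.
    algal_production : float
        Turf algae replenishment, g m^-2 yr^-1 (benthic primary productivity).
    algal_loss : float
        Background turf turnover (dislodgement/export), yr^-1.
    algal_halfsat, detritus_halfsat : float
        Half-saturation pool sizes (g m^-2) for grazing and detritivory.
    detritus_export : float
        Background detritus burial/export rate, yr^-1.
    fishing_F : float
        Instantaneous fishing mortality (yr^-1) on fish above the size limit.
    fished_min_length : float
        Lower length limit (cm) of the fished size range, for both F and the
        fisheries-productivity sum.
    dt : float
        Time step (yr) between rate evaluations; the linear update within
        a step is sub-stepped automatically where turnover is fast.
    t_max : float
        Integration horizon (yr).
    eq_tol : float
        Relative biomass change per trailing window below which a run is
        declared at equilibrium.
    eq_window : float
        Length (yr) of the trailing equilibrium-assessment window.
    """

    ppmr_mean: float = 4.158
    ppmr_sigma: float = 2.206
    search_coeff: float = 0.465
    search_exp: float = 0.8
    intake_max_coeff: float = 22.86
    interference: float = 0.042
    conversion_eff: float = 0.285
    defecation_frac: float = 0.25
    background_mort_coeff: float = 0.408
    background_mort_exp: float = -0.25
    senescence_coeff: float = 0.3
    senescence_exp: float = 1.0
    m_senesce: dict = field(
        default_factory=lambda: {"predators": 5000.0, "herbivores": 2000.0, "invertebrates": 50.0}
    )
    larval_input: dict = field(
        default_factory=lambda: {"predators": 13.0, "herbivores": 16.5, "invertebrates": 7.73e5}
    )
    recruit_length: float = 1.0
    algal_production: float = 1089.0
    algal_loss: float = 1.0
    algal_halfsat: float = 50.0
    detritus_halfsat: float = 50.0
    detritus_export: float = 0.2
    fishing_F: float = 0.0
    fished_min_length: float = 15.0
    dt: float = 0.05
    t_max: float = 400.0
    eq_tol: float = 1.0e-6
    eq_window: float = 10.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.conversion_eff < 1.0:
            raise ValueError("conversion_eff must be in (0, 1)")
        if not 0.0 <= self.defecation_frac < 1.0:
            raise ValueError("defecation_frac must be in [0, 1)")
        if self.conversion_eff + self.defecation_frac > 1.0:
            raise ValueError("conversion_eff + defecation_frac must not exceed 1")
        for name in (
            "ppmr_sigma",
            "search_coeff",
            "intake_max_coeff",
            "algal_production",
            "algal_halfsat",
            "detritus_halfsat",
            "recruit_length",
            "dt",
            "t_max",
            "eq_tol",
            "eq_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "background_mort_coeff",
            "senescence_coeff",
            "interference",
            "fishing_F",
            "algal_loss",
            "detritus_export",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for d in (self.m_senesce, self.larval_input):
            if set(d) != set(GROUPS):
                raise ValueError(f"per-group dict must have keys {GROUPS}")
            if any(v < 0 for v in d.values()):
                raise ValueError("per-group values must be non-negative")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    @property
    def fished_min_mass(self) -> float:
        from .grid import length_to_mass

        return length_to_mass(self.fished_min_length)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
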