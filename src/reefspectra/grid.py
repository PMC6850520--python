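"""Logarithmic body-mass grid and length-weight allometry.

The community model resolves abundance on a shared grid of body-mass bins,
logarithmically spaced so that a fixed predator-prey mass *ratio* spans a
fixed number of bins everywhere on the grid.  Field measurements (crevice
sizes, migration sizes, fished size limits) arrive as body lengths in cm and
are mapped to mass through the standard cubic length-weight allometry
W = a L^b with a = 0.025 g cm^-3 and b = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Length-weight coefficients for Caribbean reef fish, W[g] = A * L[cm]**B.
LW_A = 0.025
LW_B = 3.0


def length_to_mass(length_cm):
    """Convert fish body length (cm) to wet mass (g) via W = 0.025 L^3.

    Accepts scalars or arrays; raises ``ValueError`` on non-positive lengths.
    """
    length = np.asarray(length_cm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("body length must be positive")
    out = LW_A * length**LW_B
    return float(out) if np.isscalar(length_cm) else out


def mass_to_length(mass_g):
    """Inverse allometry: wet mass (g) to body length (cm)."""
    mass = np.asarray(mass_g, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("body mass must be positive")
    out = (mass / LW_A) ** (1.0 / LW_B)
    return float(out) if np.isscalar(mass_g) else out


@dataclass(frozen=True)
class SizeGrid:
    """Log-spaced body-mass grid shared by all trophic groups.

    Parameters
    ----------
    bin_edges : ndarray, shape (n_bins + 1,)
        Strictly increasing bin edges in grams, log-spaced.
    """

    bin_edges: np.ndarray
    mass: np.ndarray = field(init=False, repr=False)
    widths: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of >= 2 values")
        if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be positive and strictly increasing")
        ratios = np.diff(np.log(edges))
        if not np.allclose(ratios, ratios[0], rtol=1e-8):
            raise ValueError("bin_edges must be logarithmically spaced")
        object.__setattr__(self, "bin_edges", edges)
        # geometric-mean midpoints keep symmetry in log space
        object.__setattr__(self, "mass", np.sqrt(edges[:-1] * edges[1:]))
        object.__setattr__(self, "widths", np.diff(edges))

    @classmethod
    def build(cls, m_min: float = 1.0e-4, m_max: float = 2.0e4, n_bins: int = 120) -> "SizeGrid":
        """Construct a grid of ``n_bins`` log-spaced bins over [m_min, m_max] g.

        Defaults span small invertebrate prey (0.1 mg) to a 20-kg apex
        predator, so a 1-cm fish recruit (0.025 g) finds prey two orders of
        magnitude lighter than itself on the grid.
        """
        if m_min <= 0 or m_max <= m_min:
            raise ValueError("need 0 < m_min < m_max")
        edges = np.geomspace(m_min, m_max, n_bins + 1)
        return cls(edges)

    @property
    def n_bins(self) -> int:
        return self.mass.size

    @property
    def log_width(self) -> float:
        """Constant bin width in ln-mass."""
        return float(np.log(self.bin_edges[1] / self.bin_edges[0]))

    @property
    def lengths(self) -> np.ndarray:
        """Body length (cm) at bin midpoints."""
        return mass_to_length(self.mass)

    def bins_for_length_range(self, lo_cm: float, hi_cm: float) -> np.ndarray:
        """Indices of bins whose midpoint length lies in [lo_cm, hi_cm)."""
        ln = self.lengths
        return np.flatnonzero((ln >= lo_cm) & (ln < hi_cm))

    def bin_of_mass(self, mass_g: float) -> int:
        """Index of the bin containing the given mass."""
        if not self.bin_edges[0] <= mass_g <= self.bin_edges[-1]:
            raise ValueError(f"mass {mass_g:g} g is outside the grid")
        return int(np.clip(np.searchsorted(self.bin_edges, mass_g, side="right") - 1, 0, self.n_bins - 1))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_bins
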