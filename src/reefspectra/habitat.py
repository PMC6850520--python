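"""Reef structural complexity: crevice censuses, refuge profiles, vulnerability.

Structural complexity enters the community model through the density and size
distribution of reef crevices.  A crevice census records crevices per m^2 in
5-cm size classes; each class shelters fish whose body length matches the
crevice size (1:1 occupancy), so a class [L1, L2) cm maps onto body masses
[0.025 L1^3, 0.025 L2^3) g.  At each model time step the refuge density in a
mass bin determines the fraction of its occupants exposed to predation:
refuges are filled first and only the surplus is vulnerable, which makes the
realised vulnerability function density dependent and implicitly encodes
competition for refuge space.

Habitat degradation is represented by deleting the small crevices supplied by
branching corals (5-30 cm) and halving everything larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import SizeGrid, length_to_mass

# degradation transform boundaries (cm)
_DEGRADE_LO = 5.0
_DEGRADE_HI = 30.0
_DEGRADE_FACTOR = 0.5


@dataclass(frozen=True)
class CreviceDistribution:
    """Per-site crevice census in contiguous linear size classes.

    Parameters
    ----------
    site_id : str
        Site label.
    class_edges : ndarray, shape (n_classes + 1,)
        Strictly increasing class boundaries in cm (5-cm classes in the field
        protocol, e.g. [5, 10, 15, ...]).
    densities : ndarray, shape (n_classes,)
        Crevices per m^2 in each class; non-negative.
    """

    site_id: str
    class_edges: np.ndarray
    densities: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.class_edges, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("class_edges must be strictly increasing, length >= 2")
        if dens.shape != (edges.size - 1,):
            raise ValueError("densities must have one entry per class")
        if np.any(dens < 0):
            raise ValueError("crevice densities must be non-negative")
        object.__setattr__(self, "class_edges", edges)
        object.__setattr__(self, "densities", dens)

    @property
    def n_classes(self) -> int:
        return self.densities.size

    @property
    def total_density(self) -> float:
        """Total crevices per m^2 across all classes."""
        return float(self.densities.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "class_low_cm": self.class_edges[:-1],
                "class_high_cm": self.class_edges[1:],
                "density_per_m2": self.densities,
            }
        )


def degrade(dist: CreviceDistribution) -> CreviceDistribution:
    """Apply the habitat-degradation transform to a crevice census.

    Crevice classes lying within [5, 30) cm are removed entirely (branching
    corals erode first) and classes at or above 30 cm are halved (some large
    topographic structure persists).  A class straddling the 30-cm boundary is
    split proportionally by linear extent.  Classes below 5 cm, if present,
    pass through unchanged.  Returns a new distribution; the input is not
    modified.
    """
    lo = dist.class_edges[:-1]
    hi = dist.class_edges[1:]
    out = dist.densities.copy()
    for i in range(dist.n_classes):
        if hi[i] <= _DEGRADE_LO:
            continue  # below the measured range: untouched
        span = hi[i] - lo[i]
        removed = max(0.0, min(hi[i], _DEGRADE_HI) - max(lo[i], _DEGRADE_LO))
        halved = max(0.0, hi[i] - max(lo[i], _DEGRADE_HI))
        kept_whole = span - removed - halved  # any extent below 5 cm
        out[i] = dist.densities[i] * (kept_whole + _DEGRADE_FACTOR * halved) / span
    return CreviceDistribution(dist.site_id, dist.class_edges.copy(), out)


@dataclass(frozen=True)
class RefugeProfile:
    """Refuge density mapped onto the model's body-mass grid.

    ``refuge_density[i]`` is refuges per m^2 available to fish in mass bin i.
    """

    grid: SizeGrid
    refuge_density: np.ndarray
    site_id: str = ""

    def __post_init__(self):
        r = np.asarray(self.refuge_density, dtype=float)
        if r.shape != (self.grid.n_bins,):
            raise ValueError("refuge_density must have one entry per mass bin")
        if np.any(r < 0):
            raise ValueError("refuge densities must be non-negative")
        object.__setattr__(self, "refuge_density", r)

    @property
    def total_density(self) -> float:
        return float(self.refuge_density.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "mass_mid_g": self.grid.mass,
                "refuge_per_m2": self.refuge_density,
            }
        )

    @classmethod
    def zero(cls, grid: SizeGrid, site_id: str = "bare") -> "RefugeProfile":
        """A structureless reef: no refuges anywhere."""
        return cls(grid, np.zeros(grid.n_bins), site_id)


def crevices_to_refuge_profile(dist: CreviceDistribution, grid: SizeGrid) -> RefugeProfile:
    """Allocate a crevice census onto the model mass grid.

    Each class [L1, L2) cm shelters fish of mass [0.025 L1^3, 0.025 L2^3) g;
    its density is apportioned across the mass bins overlapping that range in
    proportion to overlap in log mass (the least-informative split), so the
    total refuge count is conserved exactly.

    Raises
    ------
    ValueError
        If the grid does not fully cover a class's mass range (names the
        offending class).
    """
    mass_lo = length_to_mass(dist.class_edges[:-1])
    mass_hi = length_to_mass(dist.class_edges[1:])
    log_edges = np.log(grid.bin_edges)
    refuge = np.zeros(grid.n_bins)
    for k in range(dist.n_classes):
        d = dist.densities[k]
        if d == 0:
            continue
        a, b = np.log(mass_lo[k]), np.log(mass_hi[k])
        if a < log_edges[0] - 1e-12 or b > log_edges[-1] + 1e-12:
            raise ValueError(
                f"mass grid does not cover crevice class "
                f"[{dist.class_edges[k]:g}, {dist.class_edges[k + 1]:g}) cm "
                f"({mass_lo[k]:.4g}-{mass_hi[k]:.4g} g)"
            )
        overlap = np.minimum(b, log_edges[1:]) - np.maximum(a, log_edges[:-1])
        overlap = np.clip(overlap, 0.0, None)
        refuge += d * overlap / (b - a)
    return RefugeProfile(grid, refuge, dist.site_id)


def vulnerability(abundance: np.ndarray, refuge: np.ndarray) -> np.ndarray:
    """Fraction of individuals per mass bin exposed to predation.

    With N individuals per m^2 in a bin and R refuges per m^2 allocated to it,
    refuges are occupied first and the surplus is exposed:

        V = max(0, (N - R) / N),   V = 0 where N = 0.

    V lies in [0, 1]; with no refuges V == 1 wherever the bin is occupied, and
    V == 0 wherever refuges outnumber occupants.
    """
    n = np.asarray(abundance, dtype=float)
    r = np.asarray(refuge, dtype=float)
    if np.any(n < 0):
        raise ValueError("abundance must be non-negative")
    occupied = n > 0
    safe_n = np.where(occupied, n, 1.0)
    with np.errstate(over="ignore"):
        v = np.where(occupied, 1.0 - np.minimum(r / safe_n, 1.0), 0.0)
    return np.clip(v, 0.0, 1.0)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

CREVICE_COLUMNS = ["site_id", "class_low_cm", "class_high_cm", "density_per_m2"]


def write_crevice_table(dists, path) -> None:
    """Write one or more crevice censuses to a tidy CSV."""
    if isinstance(dists, CreviceDistribution):
        dists = [dists]
    pd.concat([d.to_frame() for d in dists], ignore_index=True).to_csv(path, index=False)


def read_crevice_table(path) -> list[CreviceDistribution]:
    """Read crevice censuses from CSV (one distribution per site_id)."""
    df = pd.read_csv(path)
    missing = set(CREVICE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"crevice table missing columns: {sorted(missing)}")
    out = []
    for site, g in df.groupby("site_id", sort=False):
        g = g.sort_values("class_low_cm")
        lows = g["class_low_cm"].to_numpy(float)
        highs = g["class_high_cm"].to_numpy(float)
        if not np.allclose(lows[1:], highs[:-1]):
            raise ValueError(f"site {site!r}: crevice classes are not contiguous")
        edges = np.append(lows, highs[-1])
        out.append(CreviceDistribution(str(site), edges, g["density_per_m2"].to_numpy(float)))
    return out
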