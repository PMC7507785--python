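"""Height-to-biomass conversion via power-law allometry and Da Vinci's rule.

Field measurements of tree height H and diameter at breast height D
(DBH, measured 1.4 m above ground) are regressed as D = a H^b in log-log
space.  The above-ground woody biomass density of a stand then follows from
Da Vinci's rule — the cross-sectional area of all branches at any height
equals that of the trunk — as

    V = lambda * rho * H * pi * D(H)^2 / 4     [Mg m^-2]

with rho the fresh wood density (Mg m^-3) and lambda the stem density
(stems m^-2).  Foliage is neglected (a few percent of total biomass for
riparian species).  Plants shorter than 1.4 m carry no DBH and are
excluded.  Dimensionless biomass nu = V / V_scale maps the grid onto the
[0, 1] support of the stochastic biomass model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TreeMeasurement",
    "AllometricModel",
    "BiomassGrid",
    "REFERENCE_MODELS",
    "DBH_HEIGHT_M",
    "fit_allometry",
    "dbh_from_height",
    "biomass_density",
    "height_filter",
    "normalize_biomass",
    "height_from_biomass",
]

#: Height at which DBH is defined; plants below it are excluded.
DBH_HEIGHT_M = 1.4


@dataclass(frozen=True)
class TreeMeasurement:
    height_m: float
    dbh_m: float
    species: str = ""

    def __post_init__(self):
        if self.dbh_m <= 0:
            raise ValueError("DBH must be positive")
        if self.height_m <= DBH_HEIGHT_M:
            raise ValueError(
                f"a record carrying a DBH requires height > {DBH_HEIGHT_M} m"
            )


@dataclass(frozen=True)
class AllometricModel:
    """Power-law allometry D = a H^b plus stand parameters."""

    a: float  # m^(1-b)
    b: float  # dimensionless
    rho: float = 0.725  # fresh wood density, Mg m^-3
    lam: float = 0.2  # stems per m^2
    species: str = ""
    r2: float = float("nan")

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometric coefficients must be positive")
        if not 0.2 < self.rho < 1.2:
            raise ValueError("fresh wood density outside plausible range")
        if self.lam <= 0:
            raise ValueError("stem density must be positive")


#: Site-regressed allometries for the reference riparian stands
#: (poplars, willows, and the mixed tree population), with the fresh wood
#: densities used alongside them.
REFERENCE_MODELS: dict[str, AllometricModel] = {
    "poplar": AllometricModel(0.005680, 1.7337, rho=0.950, species="poplar"),
    "willow": AllometricModel(0.003345, 1.6807, rho=0.500, species="willow"),
    "mixed": AllometricModel(0.004312, 1.7784, rho=0.725, species="mixed"),
}


@dataclass(frozen=True)
class BiomassGrid:
    """Per-cell areal biomass density and its dimensionless form."""

    cell_id: np.ndarray
    V: np.ndarray  # Mg m^-2
    nu: np.ndarray | None = None
    v_scale: float | None = None

    def __post_init__(self):
        V = np.asarray(self.V, dtype=float)
        if np.any(V < 0):
            raise ValueError("biomass density must be non-negative")
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "cell_id", np.asarray(self.cell_id))


def fit_allometry(
    measurements: list[TreeMeasurement],
    rho: float = 0.725,
    lam: float = 0.2,
    species: str = "",
) -> AllometricModel:
    """Least-squares fit of ln D = ln a + b ln H.

    Ordinary least squares in log-log space (the standard estimator for
    power-law allometry under multiplicative error); returns the model with
    the R^2 of the log-log regression.
    """
    if len(measurements) < 3:
        raise ValueError("allometric fit needs at least 3 measurements")
    H = np.array([m.height_m for m in measurements])
    D = np.array([m.dbh_m for m in measurements])
    if np.allclose(H, H[0]):
        raise ValueError("degenerate fit: all heights equal")
    x, y = np.log(H), np.log(D)
    b, ln_a = np.polyfit(x, y, 1)
    resid = y - (ln_a + b * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return AllometricModel(float(np.exp(ln_a)), float(b), rho=rho, lam=lam,
                           species=species, r2=r2)


def dbh_from_height(H, model: AllometricModel):
    """Predicted DBH (m) at height H (m): D = a H^b."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("height must be non-negative")
    return model.a * H**model.b


def biomass_density(H, model: AllometricModel, cover=None):
    """Areal biomass density V (Mg m^-2) at canopy height H (m).

    Da Vinci's rule: V = lam * rho * H * pi D(H)^2 / 4.  Heights below the
    1.4-m DBH threshold contribute zero.  ``cover``, if given, is a canopy
    cover fraction that scales the stem density cell by cell.
    """
    H = np.asarray(H, dtype=float)
    lam = model.lam if cover is None else model.lam * np.asarray(cover, dtype=float)
    D = dbh_from_height(np.maximum(H, 0.0), model)
    V = lam * model.rho * H * math.pi * D**2 / 4.0
    return np.where(H >= DBH_HEIGHT_M, V, 0.0)


def height_from_biomass(V, model: AllometricModel):
    """Invert Da Vinci's rule: the H solving V = lam rho H (pi/4)(a H^b)^2.

    Closed form H = (V / (lam rho (pi/4) a^2))^(1/(1+2b)).  Heights landing
    below the 1.4-m threshold are returned as is (the caller decides whether
    to censor); V = 0 maps to H = 0.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("biomass density must be non-negative")
    coef = model.lam * model.rho * math.pi / 4.0 * model.a**2
    with np.errstate(divide="ignore"):
        H = (V / coef) ** (1.0 / (1.0 + 2.0 * model.b))
    return np.where(V > 0, H, 0.0)


def height_filter(height_grid):
    """Zero out canopy heights below the 1.4-m DBH threshold (closed: 1.4 kept)."""
    H = np.asarray(height_grid, dtype=float)
    return np.where(H >= DBH_HEIGHT_M, H, 0.0)


def normalize_biomass(grid: BiomassGrid, v_scale="auto") -> BiomassGrid:
    """Attach dimensionless biomass nu = min(V / V_scale, 1) to a grid.

    ``v_scale="auto"`` uses the maximum observed V over the site, so the
    site maximum maps to exactly 1.  The scale used is recorded on the
    returned grid because calibrated carrying capacities are defined
    relative to it.
    """
    if v_scale == "auto":
        v_scale = float(grid.V.max())
        if v_scale <= 0:
            v_scale = 1.0  # all-bare site: any positive scale gives nu = 0
    if not np.isfinite(v_scale) or v_scale <= 0:
        raise ValueError("v_scale must be positive")
    nu = np.minimum(grid.V / v_scale, 1.0)
    return replace(grid, nu=nu, v_scale=float(v_scale))
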