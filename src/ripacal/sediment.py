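"""Grain-size statistics and empirical Manning-roughness estimation.

Pebble-count data (e.g. Wolman counts or image-based grain censuses) give
*number* frequencies per size class.  Converting number frequencies to the
*weight* fractions a sieve analysis would produce uses the Fehr-type
transform s_i = S_i <d_i>^0.8 / sum_j S_j <d_j>^0.8, where S_i is the count
share of class i and <d_i> its mean diameter.  Characteristic percentiles
(d50, d90) of the resulting weight distribution then feed a battery of
classical empirical formulas for the Manning coefficient of a bare gravel
bed, whose average is a robust roughness estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrainCounts",
    "GrainSizeDistribution",
    "ManningEstimate",
    "fehr_weight_fractions",
    "percentile",
    "class_bounds",
    "manning_estimates",
    "combined_roughness",
    "MANNING_FORMULAS",
]

#: Empirical Manning formulas, n = coef * d^(1/6) with d in metres.
#: Keys identify the source relation; the second tuple entry says whether
#: the formula takes d50 or d90.
MANNING_FORMULAS: dict[str, tuple[float, str]] = {
    "fhwa": (0.0482, "d50"),
    "julien_d50": (0.062, "d50"),
    "strickler_d50": (1.0 / 21.1, "d50"),
    "julien_d90": (0.038, "d90"),
    "mpm_d90": (1.0 / 26.0, "d90"),
    "strickler_d90": (0.036, "d90"),
}


@dataclass(frozen=True)
class GrainCounts:
    """Number counts per grain-size class.

    Parameters
    ----------
    d_mm : mean diameter of each class, mm.
    counts : number of grains counted in each class.
    """

    d_mm: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d_mm, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "d_mm", d)
        object.__setattr__(self, "counts", c)
        if d.shape != c.shape or d.ndim != 1:
            raise ValueError("d_mm and counts must be 1-D arrays of equal length")
        if np.any(d <= 0):
            raise ValueError("class diameters must be positive")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def count_shares(self) -> np.ndarray:
        """S_i: count of class i over the total count."""
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("all-zero grain counts")
        return self.counts / total


@dataclass(frozen=True)
class GrainSizeDistribution:
    """Weight-fraction grain-size distribution over ascending diameters."""

    d_mm: np.ndarray
    weight_fractions: np.ndarray
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self):
        d = np.asarray(self.d_mm, dtype=float)
        s = np.asarray(self.weight_fractions, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly ascending")
        if not np.isclose(s.sum(), 1.0, atol=1e-9):
            raise ValueError("weight fractions must sum to 1")
        object.__setattr__(self, "d_mm", d)
        object.__setattr__(self, "weight_fractions", s)
        object.__setattr__(self, "cumulative", np.cumsum(s))

    @property
    def d50(self) -> float:
        return percentile(self, 0.5)

    @property
    def d90(self) -> float:
        return percentile(self, 0.9)


@dataclass(frozen=True)
class ManningEstimate:
    formula: str
    n_m: float  # s m^(-1/3)

    @property
    def n_m_rounded(self) -> float:
        return round(self.n_m, 4)


def fehr_weight_fractions(counts: GrainCounts) -> GrainSizeDistribution:
    """Convert number counts to weight fractions, s_i ∝ S_i <d_i>^0.8."""
    shares = counts.count_shares  # raises on all-zero counts
    order = np.argsort(counts.d_mm)
    d = counts.d_mm[order]
    w = shares[order] * d**0.8
    return GrainSizeDistribution(d, w / w.sum())


def class_bounds(d_mm: np.ndarray) -> np.ndarray:
    """Geometric class bounds around ascending mean diameters.

    Interior bounds are geometric midpoints; the outer bounds mirror the
    first/last class width geometrically.
    """
    d = np.asarray(d_mm, dtype=float)
    if len(d) == 1:
        return np.array([d[0], d[0]])
    inner = np.sqrt(d[:-1] * d[1:])
    lo = d[0] ** 2 / inner[0]
    hi = d[-1] ** 2 / inner[-1]
    return np.concatenate(([lo], inner, [hi]))


def percentile(dist: GrainSizeDistribution, q: float) -> float:
    """Diameter below which fraction ``q`` of the weight lies.

    The cumulative ("percent finer") curve is anchored at class upper
    bounds — the sieve convention — with bounds taken as geometric
    midpoints between the mean class diameters; interpolation is
    log-linear in diameter.  The result is clamped to the [min, max] mean
    class diameters.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("percentile fraction must lie in (0, 1)")
    d = dist.d_mm
    if len(d) == 1:
        return float(d[0])
    bounds = class_bounds(d)
    cum = np.concatenate(([0.0], dist.cumulative))
    d_q = float(np.exp(np.interp(q, cum, np.log(bounds))))
    return float(np.clip(d_q, d[0], d[-1]))


def manning_estimates(
    d50_mm: float, d90_mm: float
) -> tuple[list[ManningEstimate], float]:
    """Evaluate the six empirical Manning formulas and their mean.

    Diameters are given in mm and converted to metres inside the formulas
    (the convention under which the classical coefficients are quoted).
    Returns the per-formula estimates (full precision) and the arithmetic
    mean of the six values.
    """
    if d50_mm <= 0 or d90_mm <= 0:
        raise ValueError("grain diameters must be positive")
    d_m = {"d50": d50_mm / 1000.0, "d90": d90_mm / 1000.0}
    estimates = [
        ManningEstimate(name, coef * d_m[which] ** (1.0 / 6.0))
        for name, (coef, which) in MANNING_FORMULAS.items()
    ]
    average = float(np.mean([e.n_m for e in estimates]))
    return estimates, average


def combined_roughness(n_soil: float, n_veg: float) -> float:
    """Total Manning roughness as bare-soil plus vegetation-induced term."""
    if n_soil < 0 or n_veg < 0:
        raise ValueError("roughness terms must be non-negative")
    return n_soil + n_veg
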