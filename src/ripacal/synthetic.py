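"""Seeded generators for a fully synthetic riparian site.

Every input the calibration pipeline consumes in the field — a daily
discharge record, per-cell rating curves (normally exported from a 2-D
hydrodynamic model), bar topography, canopy heights, and pebble counts —
is emulated here with known ground truth, so each pipeline stage can be
validated end to end:

* discharge: exponential of a stationary AR(1) Gaussian process, hence a
  lognormal marginal with configured mean and CV and tunable day-to-day
  persistence;
* rating curves: per-cell power laws h = c Q^e with smooth spatial
  gradients and multiplicative heterogeneity (which scatters the
  elevation-P_I relation), tabulated at the discharge quantiles;
* topography: a monotone bank-to-crest transect whose elevations are
  placed at stage quantiles so the cells span inundation probabilities
  from the frequently flooded margin to the dry crest, plus correlated
  noise;
* vegetation: per P_I class, biomass is drawn from the model's own
  stationary law at ground-truth (k*, beta*) profiles — decreasing
  exponential k*(P_I), right-skewed beta*(P_I) peaking at P_I 0.7-0.8 —
  then converted to canopy heights by inverting the allometric biomass
  formula and censored below the 1.4-m DBH threshold;
* grain counts: lognormal grain sizes binned into half-phi classes.

Because vegetation is generated from the very family the calibrator fits,
parameter recovery is a well-posed test; real sites carry no such
guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import allometry as allo
from .calibration import CellState, VegetationClass, classify_pi
from .hydrology import (
    DischargeSeries,
    RatingCurve,
    compute_stage_statistics,
    discharge_quantiles,
)
from .sediment import GrainCounts
from .stochastic import SteadyStatePdf

__all__ = [
    "SyntheticSiteConfig",
    "SyntheticSite",
    "k_star_profile",
    "beta_star_profile",
    "make_discharge",
    "make_topography",
    "make_rating_curves",
    "make_vegetation",
    "make_grain_counts",
    "make_site",
]


def _snap(x, step):
    return np.maximum(np.round(np.asarray(x) / step) * step, step)


def k_star_profile(p_i, k0: float = 2.5, rate: float = 3.0,
                   grid_step: float = 0.1):
    """Ground-truth decay coefficient: decreasing exponential in P_I.

    Snapped to the calibration k grid so recovery is well-posed.
    """
    return _snap(k0 * np.exp(-rate * np.asarray(p_i)), grid_step)


def beta_star_profile(p_i, base: float = 0.2, amp: float = 0.7,
                      grid_step: float = 0.05):
    """Ground-truth carrying capacity: right-skewed, peaking near P_I 0.75.

    base + amp * p^3 (1-p) (peak-normalized), snapped to the beta grid.
    """
    p = np.asarray(p_i, dtype=float)
    shape = p**3 * (1.0 - p)
    peak = 0.75**3 * 0.25
    return np.minimum(_snap(base + amp * shape / peak, grid_step), 1.0)


@dataclass(frozen=True)
class SyntheticSiteConfig:
    """Study conditions for the synthetic site.

    Discharge emulates a regulated gravel-bed river (mean 71 m^3 s^-1);
    rating exponents/coefficients give wet stages of order 1-3 m; omega is
    the growth rate of the fast pioneer vegetation colonizing active bars.
    """

    n_cells: int = 20000
    n_rows: int = 100  # transect resolution; n_cells/n_rows columns
    # discharge model
    mean_q: float = 71.0  # m^3 s^-1
    cv_q: float = 0.8
    ar1: float = 0.97
    years: int = 30
    # rating-curve family h = c Q^e
    c0: float = 0.3
    e0: float = 0.25
    c_gradient: float = 0.2  # smooth spatial relative variation of c
    e_gradient: float = 0.15  # smooth spatial relative variation of e
    curve_noise: float = 0.05  # per-cell lognormal heterogeneity of c
    n_quantiles: int = 19
    # topography / P_I design
    p_i_min: float = 0.03
    p_i_max: float = 0.95
    elevation_noise_m: float = 0.02
    # vegetation truth
    class_delta: float = 0.1
    omega: float = 0.05  # day^-1; fast-growing pioneer stands
    v_scale: float = 0.43  # Mg m^-2
    allometry: allo.AllometricModel = field(
        default_factory=lambda: allo.REFERENCE_MODELS["mixed"]
    )
    # grain-size truth
    d50_mm: float = 111.0  # target weight-distribution median
    sigma_ln_d: float = 0.45
    n_grains: int = 520
    # shared stage histogram
    n_stage_bins: int = 100
    master_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        for name in ("mean_q", "cv_q", "c0", "e0", "v_scale", "omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _subseeds(config: SyntheticSiteConfig) -> dict:
    names = ["discharge", "topography", "curves", "vegetation", "grains"]
    seqs = np.random.SeedSequence(config.master_seed).spawn(len(names))
    return dict(zip(names, seqs))


def make_discharge(config: SyntheticSiteConfig, seed) -> DischargeSeries:
    """Daily lognormal AR(1) discharge with the configured mean and CV."""
    rng = np.random.default_rng(seed)
    n = int(config.years * 365)
    phi = config.ar1
    eps = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = eps[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + scale * eps[t]
    s2 = np.log1p(config.cv_q**2)
    mu = np.log(config.mean_q) - s2 / 2.0
    q = np.exp(mu + np.sqrt(s2) * z)
    dates = np.datetime64("1988-01-01", "D") + np.arange(n)
    return DischargeSeries(dates, q)


def make_topography(
    config: SyntheticSiteConfig, seed, discharge: DischargeSeries | None = None
) -> dict:
    """Cell positions, target inundation probabilities and bed elevations.

    The transect coordinate x runs from the channel margin (frequently
    flooded) to the bar crest (rarely flooded); target P_I decreases
    linearly along it with jitter, and the bed elevation is placed at the
    corresponding quantile of the reference-curve stage record, plus
    correlated vertical noise.  Returns arrays x, y, eta_star (m) and
    p_target, and the scaling stage h_bar_star (m).
    """
    rng = np.random.default_rng(seed)
    if discharge is None:
        discharge = make_discharge(config, np.random.SeedSequence(config.master_seed).spawn(1)[0])
    n = config.n_cells
    n_rows = min(config.n_rows, n)
    n_cols = int(np.ceil(n / n_rows))
    idx = np.arange(n)
    x = (idx // n_rows) / max(n_cols - 1, 1)  # 0 = margin, 1 = crest
    y = (idx % n_rows) / max(n_rows - 1, 1)
    # stratified design: each P_I class (width class_delta) receives an
    # equal share of cells; within a class the target is uniform over the
    # part of the bin inside [p_i_min, p_i_max]
    jitter = (rng.random(n) - 0.5) / max(n_cols - 1, 1)
    u = np.clip(1.0 - x + jitter, 0.0, 1.0 - 1e-12)  # descending along x
    d = config.class_delta
    n_classes = int(np.ceil(1.0 / d - 1e-9))
    j = np.minimum((u * n_classes).astype(int), n_classes - 1)
    frac = u * n_classes - j
    lo = np.maximum(j * d, config.p_i_min)
    hi = np.minimum((j + 1) * d, config.p_i_max)
    p_target = lo + frac * (hi - lo)
    # reference stage record (site-mean rating curve) sets the scaling stage
    h_ref = config.c0 * discharge.q**config.e0
    h_bar_star = float(h_ref.mean())
    eta_star = np.quantile(h_ref, 1.0 - p_target)
    # correlated noise along the transect: smooth random walk over columns
    col_noise = np.cumsum(rng.standard_normal(n_cols))
    col_noise = (col_noise - col_noise.mean()) / max(col_noise.std(), 1e-12)
    col_noise = col_noise * config.elevation_noise_m
    eta_noise = col_noise[idx // n_rows]
    return {
        "x": x,
        "y": y,
        "eta_star": eta_star + eta_noise,  # provisional (reference curve)
        "eta_noise": eta_noise,
        "p_target": p_target,
        "h_bar_star": h_bar_star,
    }


def make_rating_curves(
    config: SyntheticSiteConfig,
    topo: dict,
    discharge: DischargeSeries,
    seed,
) -> list[RatingCurve]:
    """Per-cell power-law rating curves tabulated at the discharge quantiles.

    c and e vary smoothly across the site (gradients along x and y) with
    small lognormal per-cell heterogeneity in c; guard knots slightly
    outside the observed discharge range avoid extrapolation.
    """
    rng = np.random.default_rng(seed)
    x, y = topo["x"], topo["y"]
    n = len(x)
    c = config.c0 * (1.0 + config.c_gradient * (x - 0.5)) * np.exp(
        config.curve_noise * rng.standard_normal(n)
    )
    e = config.e0 * (1.0 + config.e_gradient * (y - 0.5))
    qq = discharge_quantiles(discharge, config.n_quantiles)
    q_knots = np.unique(
        np.concatenate(([discharge.q.min() * 0.5], qq, [discharge.q.max() * 1.5]))
    )
    # anchor each cell's bed at its own curve's stage quantile so the
    # realized inundation probability tracks the design target; the
    # eta-P_I relation still scatters because c and e vary cell to cell
    q_at_p = np.quantile(discharge.q, 1.0 - topo["p_target"])
    topo["eta_star"] = c * q_at_p**e + topo["eta_noise"]
    return [
        RatingCurve(i, q_knots, c[i] * q_knots ** e[i]) for i in range(n)
    ]


def make_vegetation(
    config: SyntheticSiteConfig,
    cells: list[CellState],
    seed,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw biomass from the model's own stationary law, per P_I class.

    Cells are grouped into P_I classes (width ``class_delta``); each class
    gets ground-truth (k*, beta*) from the profiles, the class decay rate
    and integral scale from its aggregated stage statistics, and members
    draw nu i.i.d. from the resulting stationary law (an infeasible class
    — viability violated — yields nu = 0).  Returns (nu, heights_m, truth)
    where truth maps class label to the generating parameters.  Heights
    below the 1.4-m DBH threshold are censored to zero so the downstream
    filter is exercised.
    """
    rng = np.random.default_rng(seed)
    classes = classify_pi(cells, delta=config.class_delta)
    nu = np.zeros(len(cells))
    index = {c.cell_id: i for i, c in enumerate(cells)}
    truth: dict = {}
    for vc in classes:
        center = 0.5 * (vc.lo + vc.hi)
        k_star = float(k_star_profile(center))
        beta_star = float(beta_star_profile(center))
        alpha_star = vc.decay_rate(k_star)
        tau_star = vc.tau_rescaled(config.omega)
        pdf = SteadyStatePdf(beta_star, alpha_star, tau_star, vc.p_i)
        draws = pdf.rvs(vc.n_cells, rng)
        for c, v in zip(vc.cells, draws):
            nu[index[c.cell_id]] = v
        truth[vc.label] = {
            "p_i": vc.p_i,
            "k_star": k_star,
            "beta_star": beta_star,
            "alpha_star": alpha_star,
            "tau_star": tau_star,
            "viable": not pdf.atom_at_zero,
            "mu1_star": pdf.mean(),
            "n_cells": vc.n_cells,
        }
    V = nu * config.v_scale
    H = allo.height_from_biomass(V, config.allometry)
    H = np.where(H >= allo.DBH_HEIGHT_M, H, 0.0)
    return nu, H, truth


def _phi_edges(d_mm: np.ndarray) -> np.ndarray:
    """Half-phi class edges covering the sample range (phi = -log2 d)."""
    phi = -np.log2(d_mm)
    lo = np.floor(phi.min() * 2) / 2
    hi = np.ceil(phi.max() * 2) / 2
    return np.arange(lo, hi + 0.5, 0.5)


def make_grain_counts(config: SyntheticSiteConfig, seed) -> GrainCounts:
    """Pebble counts from a lognormal grain-size law, binned half-phi.

    The log-mean is shifted by -0.8 sigma^2 so that the *weight*
    distribution implied by the count-to-weight conversion has its median
    at the configured d50.
    """
    rng = np.random.default_rng(seed)
    s = config.sigma_ln_d
    mu = np.log(config.d50_mm) - 0.8 * s**2
    d = np.exp(mu + s * rng.standard_normal(config.n_grains))
    edges_phi = _phi_edges(d)
    # phi decreasing in d: convert to mm edges ascending
    edges_mm = np.sort(2.0 ** (-edges_phi))
    counts, _ = np.histogram(d, bins=edges_mm)
    mean_d = np.sqrt(edges_mm[:-1] * edges_mm[1:])  # geometric bin mean
    keep = counts > 0
    return GrainCounts(mean_d[keep], counts[keep])


@dataclass
class SyntheticSite:
    """A generated site bundle ready for the calibration pipeline."""

    config: SyntheticSiteConfig
    discharge: DischargeSeries
    curves: list[RatingCurve]
    cells: list[CellState]  # nu filled with generated biomass
    classes: list[VegetationClass]
    truth: dict
    heights_m: np.ndarray
    h_bar_star: float
    stage_bin_edges: np.ndarray


def make_site(config: SyntheticSiteConfig) -> SyntheticSite:
    """Generate the full synthetic site under the master seed."""
    seeds = _subseeds(config)
    discharge = make_discharge(config, seeds["discharge"])
    topo = make_topography(config, seeds["topography"], discharge)
    curves = make_rating_curves(config, topo, discharge, seeds["curves"])
    h_bar = topo["h_bar_star"]

    # shared dimensionless stage bins across cells (class pdfs average bin-wise)
    h_min = min(float(c.h_points[0]) for c in curves)
    h_max = max(float(c.h_points[-1]) for c in curves)
    edges = np.linspace((h_min - h_bar) / h_bar - 1e-9,
                        (h_max - h_bar) / h_bar + 1e-9,
                        config.n_stage_bins + 1)

    cells = []
    for i, curve in enumerate(curves):
        st = compute_stage_statistics(
            discharge, curve, topo["eta_star"][i], h_bar,
            bin_edges=edges, omega=config.omega,
        )
        cells.append(
            CellState(curve.cell_id, topo["x"][i], topo["y"][i], st.eta, st,
                      nu=0.0)
        )
    nu, heights, truth = make_vegetation(config, cells, seeds["vegetation"])
    for c, v in zip(cells, nu):
        c.nu = float(v)
    classes = classify_pi(cells, delta=config.class_delta)
    return SyntheticSite(config, discharge, curves, cells, classes, truth,
                         heights, h_bar, edges)
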