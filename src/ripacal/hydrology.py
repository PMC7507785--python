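"""From a discharge record to per-cell stage statistics.

The stochastic biomass model needs, for every grid cell: the probability
density p(h) of the dimensionless water stage, the inundation probability

    P_I = integral_eta^inf p(h) dh,

and the integral scale of the wet/dry alternation, obtained from the mean
exposure and inundation durations via 1/tau = 1/tau_E + 1/tau_I.  This
module derives them by pushing a daily discharge series through per-cell
rating curves (tabulated Q-h relations, e.g. exported from a 2-D
hydrodynamic model), nondimensionalizing stages and elevations with the
mean water stage h_bar_star ( h = (h* - h_bar*) / h_bar* ), and scanning
the resulting stage series.  It also provides the lognormal
quantile-mapping transform used to build altered-regime discharge series
for climate scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DRY",
    "DischargeSeries",
    "RatingCurve",
    "StageStatistics",
    "ClimateScenario",
    "truncate_stationary",
    "discharge_quantiles",
    "stage_series",
    "nondimensionalize",
    "inundation_probability",
    "residence_times",
    "climate_transform",
    "compute_stage_statistics",
    "read_discharge_csv",
    "read_rating_curves_csv",
    "stage_statistics_frame",
]

#: Sentinel stage for a dry cell (discharge below the rating curve's first
#: knot: the water surface sits below the cell bed).
DRY = -np.inf


@dataclass(frozen=True)
class DischargeSeries:
    """Daily discharge record.

    ``dates`` are calendar days (numpy datetime64[D]), strictly increasing;
    ``q`` is the discharge in m^3 s^-1, non-negative.  Missing days are
    flagged in ``n_gap_days`` but never interpolated.
    """

    dates: np.ndarray
    q: np.ndarray
    n_gap_days: int = field(init=False)

    def __post_init__(self):
        dates = np.asarray(self.dates, dtype="datetime64[D]")
        q = np.asarray(self.q, dtype=float)
        if dates.shape != q.shape or dates.ndim != 1 or len(q) == 0:
            raise ValueError("dates and q must be equal-length 1-D arrays")
        if np.any(q < 0):
            raise ValueError("discharge must be non-negative")
        steps = np.diff(dates).astype(int)
        if np.any(steps <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "n_gap_days", int(np.sum(steps - 1)))
        if self.n_gap_days:
            warnings.warn(
                f"discharge series has {self.n_gap_days} missing day(s); "
                "gaps are kept, not interpolated",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.q)

    @property
    def years(self) -> np.ndarray:
        return self.dates.astype("datetime64[Y]").astype(int) + 1970

    def mean(self) -> float:
        return float(self.q.mean())

    def cv(self) -> float:
        m = self.q.mean()
        return float(self.q.std() / m) if m > 0 else float("nan")


@dataclass(frozen=True)
class RatingCurve:
    """Tabulated Q-h relation for one cell; piecewise-linear in between.

    Below the first knot the cell is dry (stage ``DRY``); above the last
    knot the final segment is extrapolated linearly (with a warning).
    Stages are water-surface elevations in metres.
    """

    cell_id: object
    q_points: np.ndarray
    h_points: np.ndarray

    def __post_init__(self):
        qp = np.asarray(self.q_points, dtype=float)
        hp = np.asarray(self.h_points, dtype=float)
        if qp.shape != hp.shape or qp.ndim != 1 or len(qp) < 2:
            raise ValueError("rating curve needs >= 2 (Q, h) pairs")
        if np.any(np.diff(qp) <= 0):
            raise ValueError("rating-curve discharges must be strictly increasing")
        if np.any(np.diff(hp) < 0):
            raise ValueError("rating-curve stages must be non-decreasing")
        object.__setattr__(self, "q_points", qp)
        object.__setattr__(self, "h_points", hp)


@dataclass(frozen=True)
class StageStatistics:
    """Per-cell stage statistics in dimensionless form.

    ``bin_edges``/``masses`` describe the histogram density of the
    dimensionless stage over wet days; ``dry_mass`` is the probability of a
    dry cell (stage below the cell bed), so masses.sum() + dry_mass = 1.
    Durations are stored in days; the growth-rescaled values (tau_e etc.)
    require ``omega`` (day^-1).
    """

    cell_id: object
    eta: float  # dimensionless cell elevation
    bin_edges: np.ndarray
    masses: np.ndarray
    dry_mass: float
    p_i: float
    tau_e_days: float
    tau_i_days: float
    tau_days: float
    h_bar_star: float
    omega: float | None = None

    def __post_init__(self):
        total = float(np.sum(self.masses)) + self.dry_mass
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage pdf masses must sum to 1 (got {total})")
        if np.any(np.asarray(self.masses) < -1e-15):
            raise ValueError("stage pdf masses must be non-negative")
        if not 0.0 <= self.p_i <= 1.0:
            raise ValueError("P_I must lie in [0, 1]")

    def _rescaled(self, days: float) -> float:
        if self.omega is None:
            raise ValueError("omega not set; rescaled durations unavailable")
        return days * self.omega

    @property
    def tau_e(self) -> float:
        return self._rescaled(self.tau_e_days)

    @property
    def tau_i(self) -> float:
        return self._rescaled(self.tau_i_days)

    @property
    def tau(self) -> float:
        return self._rescaled(self.tau_days)

    def with_omega(self, omega: float) -> "StageStatistics":
        return replace(self, omega=omega)


@dataclass(frozen=True)
class ClimateScenario:
    """Multiplicative changes to the discharge marginal (and optionally beta)."""

    mean_factor: float = 0.6
    cv_factor: float = 1.15
    beta_factor: float = 1.0

    def __post_init__(self):
        if min(self.mean_factor, self.cv_factor, self.beta_factor) <= 0:
            raise ValueError("scenario factors must be positive")


# ---------------------------------------------------------------------------
# operations


def truncate_stationary(series: DischargeSeries, cutoff_year: int) -> DischargeSeries:
    """Keep only records strictly after 31 December of ``cutoff_year``.

    Used to restrict the record to the stationary (post-regulation) period.
    """
    keep = series.years > cutoff_year
    if not np.any(keep):
        raise ValueError(f"no data after cutoff year {cutoff_year}")
    if np.all(keep):
        return series
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gap warning already issued on load
        return DischargeSeries(series.dates[keep], series.q[keep])


def discharge_quantiles(series: DischargeSeries, n: int = 19) -> np.ndarray:
    """The i/(n+1) empirical quantiles of the daily discharge, i = 1..n."""
    if n < 2:
        raise ValueError("need at least 2 quantiles")
    probs = np.arange(1, n + 1) / (n + 1)
    return np.quantile(series.q, probs)


def stage_series(series: DischargeSeries, curve: RatingCurve) -> np.ndarray:
    """Per-day water-surface stage (m) at the cell; ``DRY`` when below the curve."""
    q = series.q
    qp, hp = curve.q_points, curve.h_points
    h = np.interp(q, qp, hp)
    above = q > qp[-1]
    if np.any(above):
        slope = (hp[-1] - hp[-2]) / (qp[-1] - qp[-2])
        h[above] = hp[-1] + slope * (q[above] - qp[-1])
        warnings.warn(
            f"cell {curve.cell_id}: {int(above.sum())} discharge(s) above the "
            "rating curve range; extrapolated linearly",
            stacklevel=2,
        )
    h[q < qp[0]] = DRY
    return h


def nondimensionalize(stage, h_bar_star: float):
    """h = (h* - h_bar*) / h_bar*; also applies to elevations and water tables."""
    if h_bar_star <= 0:
        raise ValueError("h_bar_star must be positive")
    stage = np.asarray(stage, dtype=float)
    out = (stage - h_bar_star) / h_bar_star
    # the dry sentinel is invariant under the affine map
    return np.where(np.isneginf(stage), DRY, out)


def inundation_probability(stats_pdf, eta: float) -> float:
    """P_I: probability mass of {h >= eta} of a discrete stage density.

    ``stats_pdf`` is a :class:`StageStatistics` or a ``(bin_edges, masses)``
    pair normalized to 1.  A bin straddling eta contributes the linear
    fraction of its mass above eta; dry mass never counts as inundated.
    """
    if isinstance(stats_pdf, StageStatistics):
        edges, masses, dry = stats_pdf.bin_edges, stats_pdf.masses, stats_pdf.dry_mass
    else:
        edges, masses = stats_pdf
        dry = 0.0
    edges = np.asarray(edges, dtype=float)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum() + dry
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"stage pdf is not normalized (sum = {total})")
    lo, hi = edges[:-1], edges[1:]
    width = np.where(hi > lo, hi - lo, 1.0)
    frac = np.clip((hi - eta) / width, 0.0, 1.0)
    return float(np.clip(np.sum(masses * frac), 0.0, 1.0))


def residence_times(stage_h, eta: float) -> tuple[float, float, float]:
    """Mean exposure/inundation run lengths (days) and their harmonic scale.

    tau_E is the mean length of maximal runs of consecutive days with
    h < eta, tau_I the same for h >= eta, and 1/tau = 1/tau_E + 1/tau_I.
    Runs truncated by the series boundary count as runs.  If one state
    never occurs its duration is infinite and tau equals the other mean
    (P_I = 0 or 1 semantics).
    """
    h = np.asarray(stage_h, dtype=float)
    if len(h) < 2:
        raise ValueError("need at least 2 days of stage data")
    wet = h >= eta
    n_wet = int(wet.sum())
    n_dry = len(h) - n_wet
    # number of maximal runs of each state
    starts_wet = int(wet[0]) + int(np.sum(~wet[:-1] & wet[1:]))
    starts_dry = int(~wet[0]) + int(np.sum(wet[:-1] & ~wet[1:]))
    tau_i = n_wet / starts_wet if starts_wet else np.inf
    tau_e = n_dry / starts_dry if starts_dry else np.inf
    inv = (0.0 if np.isinf(tau_e) else 1.0 / tau_e) + (
        0.0 if np.isinf(tau_i) else 1.0 / tau_i
    )
    tau = 1.0 / inv if inv > 0 else np.inf
    return tau_e, tau_i, tau


def climate_transform(
    series: DischargeSeries,
    scenario: ClimateScenario,
    seed=None,
) -> DischargeSeries:
    """Altered-regime discharge series via lognormal quantile mapping.

    A lognormal marginal is fitted to the positive daily discharges by
    moment matching, a target lognormal is built with mean and CV scaled by
    the scenario factors (mu = ln(m / sqrt(1 + c^2)), sigma^2 = ln(1+c^2)),
    and each day's discharge is mapped through the corresponding quantiles
    (a monotone log-affine map).  Rank order — hence the temporal
    correlation structure the integral scale depends on — is preserved.
    ``seed`` is accepted for interface uniformity; the map is deterministic.
    """
    q = series.q.copy()
    pos = q > 0
    if not np.all(pos):
        warnings.warn(
            f"{int((~pos).sum())} nonpositive discharge(s) excluded from the "
            "lognormal fit and left unchanged",
            stacklevel=2,
        )
    qp = q[pos]
    m = qp.mean()
    c = qp.std() / m
    if c == 0:
        q[pos] = qp * scenario.mean_factor
        return DischargeSeries(series.dates, q)
    s2 = np.log1p(c**2)
    mu = np.log(m) - s2 / 2.0
    c_new = c * scenario.cv_factor
    s2_new = np.log1p(c_new**2)
    mu_new = np.log(m * scenario.mean_factor) - s2_new / 2.0
    ratio = np.sqrt(s2_new / s2)
    q[pos] = np.exp(mu_new + ratio * (np.log(qp) - mu))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DischargeSeries(series.dates, q)


# ---------------------------------------------------------------------------
# per-cell pipeline


def compute_stage_statistics(
    series: DischargeSeries,
    curve: RatingCurve,
    eta_star_m: float,
    h_bar_star: float,
    bin_edges=None,
    n_bins: int = 100,
    omega: float | None = None,
) -> StageStatistics:
    """Full stage statistics of one cell.

    ``eta_star_m`` is the cell bed elevation (m) and ``h_bar_star`` the
    scaling mean stage (m).  ``bin_edges`` (dimensionless stage) may be
    shared across cells so class-level densities can be averaged bin-wise;
    by default ``n_bins`` equal-width bins span the cell's own wet range.
    """
    h_star = stage_series(series, curve)
    h = nondimensionalize(h_star, h_bar_star)
    eta = float(nondimensionalize(eta_star_m, h_bar_star))
    wet_vals = h[np.isfinite(h)]
    n = len(h)
    dry_mass = 1.0 - len(wet_vals) / n
    if bin_edges is None:
        if len(wet_vals):
            lo, hi = wet_vals.min(), wet_vals.max()
            pad = 1e-9 + 1e-9 * abs(hi)
            bin_edges = np.linspace(lo, hi + pad, n_bins + 1)
            # snap the nearest interior edge onto eta so the wet/dry split
            # is exact for this cell's own histogram
            if bin_edges[0] < eta < bin_edges[-1]:
                j = int(np.argmin(np.abs(bin_edges[1:-1] - eta))) + 1
                cand = bin_edges.copy()
                cand[j] = eta
                if np.all(np.diff(cand) > 0):
                    bin_edges = cand
        else:
            bin_edges = np.linspace(-1.0, 0.0, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(wet_vals, bins=bin_edges)
    n_binned = counts.sum()
    if len(wet_vals) and n_binned < len(wet_vals):
        raise ValueError("shared bin_edges do not cover this cell's stage range")
    masses = counts / n
    # mass above eta with linear splitting of the straddling bin; dry days
    # (mass 1 - masses.sum()) are never inundated
    lo, hi = bin_edges[:-1], bin_edges[1:]
    width = np.where(hi > lo, hi - lo, 1.0)
    frac = np.clip((hi - eta) / width, 0.0, 1.0)
    p_i = float(np.sum(masses * frac))
    tau_e_d, tau_i_d, tau_d = residence_times(h, eta)
    return StageStatistics(
        cell_id=curve.cell_id,
        eta=eta,
        bin_edges=bin_edges,
        masses=masses,
        dry_mass=dry_mass,
        p_i=float(p_i),
        tau_e_days=tau_e_d,
        tau_i_days=tau_i_d,
        tau_days=tau_d,
        h_bar_star=h_bar_star,
        omega=omega,
    )


# ---------------------------------------------------------------------------
# I/O


def read_discharge_csv(path) -> DischargeSeries:
    """Read a discharge CSV with columns ``date`` (ISO 8601) and ``q_m3s``."""
    df = pd.read_csv(path, parse_dates=["date"])
    return DischargeSeries(
        df["date"].to_numpy().astype("datetime64[D]"), df["q_m3s"].to_numpy(float)
    )


def write_discharge_csv(series: DischargeSeries, path) -> None:
    pd.DataFrame({"date": series.dates, "q_m3s": series.q}).to_csv(path, index=False)


def read_rating_curves_csv(path) -> dict:
    """Read a long-format rating-curve CSV: ``cell_id, q_m3s, h_m``."""
    df = pd.read_csv(path)
    curves = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("q_m3s")
        curves[cid] = RatingCurve(cid, grp["q_m3s"].to_numpy(float),
                                  grp["h_m"].to_numpy(float))
    return curves


def stage_statistics_frame(stats: list[StageStatistics]) -> pd.DataFrame:
    """Tabular export of per-cell stage statistics."""
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in stats],
            "eta": [s.eta for s in stats],
            "p_i": [s.p_i for s in stats],
            "tau_e_days": [s.tau_e_days for s in stats],
            "tau_i_days": [s.tau_i_days for s in stats],
            "tau_days": [s.tau_days for s in stats],
        }
    )
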