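"""Dichotomous-noise stochastic model of riparian biomass (CR06 family).

A river cell alternates randomly between *exposure* (the water stage h sits
below the cell elevation eta) and *inundation* (h >= eta).  With time
rescaled by the vegetation growth rate (t = omega * t_days), the
dimensionless biomass nu follows the two-phase dynamics

    d nu / dt = nu^m (beta - nu)^p        during exposure,
    d nu / dt = - alpha nu^n              during inundation,

with beta the local carrying capacity, alpha the flood-induced decay rate,
and m, n, p shape exponents (1, 1, 1 by default: logistic growth, linear
decay).  The decay rate is tied to the hydrology by

    alpha(k) = (k / P_I) * integral_eta^inf (h - eta) p(h) dh,

i.e. k times the mean submergence depth conditional on being inundated
(P_I is the inundation probability; an alternative k * P_I reading of the
prefactor is available).  Phase durations are taken exponential with means
tau_E and tau_I, whose harmonic combination is the integral scale tau:
1/tau = 1/tau_E + 1/tau_I.

For the default exponents the stationary density of nu has the closed form

    p(nu) = N nu^a (beta - nu)^b (alpha + beta - nu),   0 < nu < beta,
    a = [beta (1 - alpha tau) - (alpha + beta) P_I] / (alpha beta tau),
    b = P_I / (beta tau) - 1,

valid under the viability condition P_I < beta / (alpha + beta); otherwise
the stationary law is a Dirac atom at nu = 0 (bare state).  Because
(alpha + beta - nu) = alpha + (beta - nu), the density is an exact
two-component Beta mixture, which this module exploits for stable
normalization, CDF, moments and exact sampling.  A Monte-Carlo simulator of
the two-phase process doubles as an independent correctness oracle for the
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "phase_durations",
    "VegetationParams",
    "SteadyStatePdf",
    "DichotomicTrajectory",
    "submergence_integral",
    "decay_rate",
    "viability",
    "steady_pdf",
    "moments",
    "simulate_dichotomic",
    "growth_rate_from_Tg",
]


@dataclass(frozen=True)
class VegetationParams:
    """Biological parameters of the two-phase biomass model."""

    k: float  # decay coefficient (dimensionless)
    beta: float  # local carrying capacity in (0, 1]
    omega: float = 5.88 / 21000.0  # growth rate, day^-1 (slow woody default)
    m: float = 1.0
    n: float = 1.0
    p: float = 1.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("decay coefficient k must be >= 0")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("carrying capacity beta must lie in (0, 1]")
        if self.omega <= 0:
            raise ValueError("growth rate omega must be positive")
        if min(self.m, self.n, self.p) <= 0:
            raise ValueError("growth/decay exponents must be positive")


def phase_durations(tau: float, p_i: float) -> tuple[float, float]:
    """(tau_E, tau_I) consistent with an integral scale and wet fraction.

    Inverts 1/tau = 1/tau_E + 1/tau_I together with
    P_I = tau_I / (tau_E + tau_I):  tau_E = tau / P_I, tau_I = tau / (1 - P_I).
    """
    if not 0.0 < p_i < 1.0:
        raise ValueError("need 0 < P_I < 1 for finite phase durations")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return tau / p_i, tau / (1.0 - p_i)


def growth_rate_from_Tg(T_g: float) -> float:
    """Growth rate omega = 5.88 / T_g (day^-1).

    T_g is the time (days) for a logistically growing plant to pass from 5%
    to 95% of its maximum size; 5.88 = 2 ln(19) is the corresponding span in
    logistic time units.
    """
    if T_g <= 0:
        raise ValueError("growth timescale T_g must be positive")
    return 5.88 / T_g


def submergence_integral(bin_edges, masses, eta: float) -> float:
    """integral_eta^inf (h - eta) p(h) dh for a histogram density.

    Mass is uniform within each bin; a bin straddling eta contributes only
    its part above eta.
    """
    edges = np.asarray(bin_edges, dtype=float)
    m = np.asarray(masses, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    width = np.where(hi > lo, hi - lo, 1.0)
    # fraction of each bin's mass lying above eta
    top = np.maximum(hi - eta, 0.0)
    frac = np.clip(top / width, 0.0, 1.0)
    # mean of (h - eta) over the above-eta part: (lo+hi)/2 - eta if the bin
    # is fully above, else (hi - eta)/2 for the straddling bin
    mean_excess = np.where(lo >= eta, (lo + hi) / 2.0 - eta, top / 2.0)
    return float(np.sum(m * frac * np.maximum(mean_excess, 0.0)))


def _pdf_mass_above(bin_edges, masses, eta: float) -> float:
    edges = np.asarray(bin_edges, dtype=float)
    m = np.asarray(masses, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    width = np.where(hi > lo, hi - lo, 1.0)
    frac = np.clip((hi - eta) / width, 0.0, 1.0)
    return float(np.sum(m * frac))


def decay_rate(
    k: float,
    stage_pdf,
    eta: float,
    p_i: float,
    prefactor: str = "over_pi",
    check: bool = True,
) -> float:
    """Flood-induced decay rate alpha(k) from the stage histogram.

    ``stage_pdf`` is a ``(bin_edges, masses)`` pair or any object with
    those attributes.  ``prefactor`` selects the reading of the k/P_I
    scaling: ``"over_pi"`` (conditional mean submergence depth, default) or
    ``"times_pi"``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if hasattr(stage_pdf, "bin_edges"):
        edges, masses = stage_pdf.bin_edges, stage_pdf.masses
    else:
        edges, masses = stage_pdf
    integral = submergence_integral(edges, masses, eta)
    if p_i <= 0:
        if integral > 1e-12:
            raise AssertionError("P_I = 0 but the submergence integral is nonzero")
        return 0.0
    if check:
        pdf_pi = _pdf_mass_above(edges, masses, eta)
        if abs(pdf_pi - p_i) > 1e-6:
            raise ValueError(
                f"p_i={p_i:.8f} inconsistent with stage pdf mass above eta "
                f"({pdf_pi:.8f})"
            )
    if prefactor == "over_pi":
        return k * integral / p_i
    if prefactor == "times_pi":
        return k * integral * p_i
    raise ValueError(f"unknown eq3 prefactor convention: {prefactor!r}")


def viability(alpha: float, beta: float, p_i: float) -> bool:
    """True iff the vegetated stationary state exists: P_I < beta/(alpha+beta)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return p_i < beta / (alpha + beta)


class SteadyStatePdf:
    """Stationary law of the dimensionless biomass.

    Either an absolutely continuous density on (0, beta) — represented
    exactly as a two-component Beta mixture — or a Dirac atom at 0 (when
    the viability condition fails) or at beta (degenerate noise-free
    limits P_I = 0 or alpha = 0).
    """

    def __init__(self, beta: float, alpha: float, tau: float, p_i: float):
        if not 0.0 < beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= p_i <= 1.0:
            raise ValueError("P_I must lie in [0, 1]")
        self.beta = float(beta)
        self.alpha = float(alpha)
        self.tau = float(tau)
        self.p_i = float(p_i)
        self.atom_at_zero = 0
        self.atom_at_beta = 0
        self.a = self.b = math.nan
        self._w1 = self._log_total = math.nan

        if p_i == 0.0 or alpha == 0.0:
            self.atom_at_beta = 1
            return
        if not viability(alpha, beta, p_i):
            self.atom_at_zero = 1
            return
        if tau <= 0:
            raise ValueError("tau must be positive for a non-degenerate law")
        self.a = (beta * (1.0 - alpha * tau) - (alpha + beta) * p_i) / (
            alpha * beta * tau
        )
        self.b = p_i / (beta * tau) - 1.0
        # log unnormalized masses of the two Beta components:
        #   alpha * nu^a (beta-nu)^b   and   nu^a (beta-nu)^(b+1)
        log_w1 = (
            math.log(alpha)
            + (self.a + self.b + 1.0) * math.log(beta)
            + special.betaln(self.a + 1.0, self.b + 1.0)
        )
        log_w2 = (self.a + self.b + 2.0) * math.log(beta) + special.betaln(
            self.a + 1.0, self.b + 2.0
        )
        self._log_total = np.logaddexp(log_w1, log_w2)
        self._w1 = math.exp(log_w1 - self._log_total)

    # -- queries ---------------------------------------------------------

    @property
    def is_atomic(self) -> bool:
        return bool(self.atom_at_zero or self.atom_at_beta)

    @property
    def atom_location(self) -> float | None:
        if self.atom_at_zero:
            return 0.0
        if self.atom_at_beta:
            return self.beta
        return None

    @property
    def norm_constant(self) -> float:
        """N of the closed-form density (1 / integral of the unnormalized form)."""
        if self.is_atomic:
            return math.nan
        return math.exp(-self._log_total)

    def pdf(self, nu):
        nu = np.asarray(nu, dtype=float)
        if self.is_atomic:
            return np.zeros_like(nu)
        out = np.zeros_like(nu)
        inside = (nu > 0) & (nu < self.beta)
        v = nu[inside]
        with np.errstate(divide="ignore"):
            log_core = self.a * np.log(v) + self.b * np.log(self.beta - v)
        out[inside] = np.exp(log_core - self._log_total) * (
            self.alpha + self.beta - v
        )
        return out

    def cdf(self, nu):
        nu = np.asarray(nu, dtype=float)
        if self.atom_at_zero:
            return np.where(nu >= 0, 1.0, 0.0)
        if self.atom_at_beta:
            return np.where(nu >= self.beta, 1.0, 0.0)
        x = np.clip(nu / self.beta, 0.0, 1.0)
        c1 = special.betainc(self.a + 1.0, self.b + 1.0, x)
        c2 = special.betainc(self.a + 1.0, self.b + 2.0, x)
        return self._w1 * c1 + (1.0 - self._w1) * c2

    def binned_masses(self, edges) -> np.ndarray:
        """Probability mass in each [e_i, e_{i+1}) bin (atoms included)."""
        edges = np.asarray(edges, dtype=float)
        if self.is_atomic:
            loc = self.atom_location
            masses = np.zeros(len(edges) - 1)
            idx = np.searchsorted(edges, loc, side="right") - 1
            idx = min(max(idx, 0), len(masses) - 1)
            masses[idx] = 1.0
            return masses
        return np.diff(self.cdf(edges))

    def moment(self, order: int) -> float:
        """E[nu^order]; exact via Beta-moment products."""
        if order < 1:
            raise ValueError("moment order must be >= 1")
        if self.atom_at_zero:
            return 0.0
        if self.atom_at_beta:
            return self.beta**order
        p = self.a + 1.0

        def beta_raw_moment(q: float) -> float:
            val = 1.0
            for j in range(order):
                val *= (p + j) / (p + q + j)
            return val

        return self.beta**order * (
            self._w1 * beta_raw_moment(self.b + 1.0)
            + (1.0 - self._w1) * beta_raw_moment(self.b + 2.0)
        )

    def mean(self) -> float:
        return self.moment(1)

    def rvs(self, size: int, seed) -> np.ndarray:
        """Exact sampling via the Beta-mixture representation."""
        rng = np.random.default_rng(seed)
        if self.atom_at_zero:
            return np.zeros(size)
        if self.atom_at_beta:
            return np.full(size, self.beta)
        comp1 = rng.random(size) < self._w1
        out = np.empty(size)
        n1 = int(comp1.sum())
        out[comp1] = rng.beta(self.a + 1.0, self.b + 1.0, n1)
        out[~comp1] = rng.beta(self.a + 1.0, self.b + 2.0, size - n1)
        return self.beta * out


def steady_pdf(params, alpha: float, tau: float, p_i: float) -> SteadyStatePdf:
    """Stationary biomass law for carrying capacity from ``params``.

    ``params`` is a :class:`VegetationParams` (its exponents must be the
    default 1, 1, 1 for the closed form to apply) or a bare beta value.
    ``tau`` is the integral scale in growth-rescaled time units.
    """
    if isinstance(params, VegetationParams):
        for name in ("m", "n", "p"):
            if getattr(params, name) != 1.0:
                raise ValueError(
                    f"closed-form stationary density requires exponent {name} = 1; "
                    "use simulate_dichotomic for other exponents"
                )
        beta = params.beta
    else:
        beta = float(params)
    return SteadyStatePdf(beta, alpha, tau, p_i)


def moments(pdf: SteadyStatePdf, order: int) -> float:
    """r-th raw moment of a stationary biomass law."""
    return pdf.moment(order)


@dataclass(frozen=True)
class DichotomicTrajectory:
    """Biomass trajectory sampled on a regular grid of rescaled time."""

    times: np.ndarray
    nu: np.ndarray
    phase: np.ndarray  # True where inundated
    seed: object


def _grow_logistic(nu0: float, beta: float, t: np.ndarray) -> np.ndarray:
    # d nu/dt = nu (beta - nu); exact solution
    if nu0 <= 0:
        return np.zeros_like(t)
    r = (beta - nu0) / nu0
    return beta / (1.0 + r * np.exp(-beta * t))


def _rk4_phase(f, nu0: float, t: np.ndarray, dt_max: float) -> np.ndarray:
    """RK4 integration returning nu at each time in ascending ``t`` (t[0]=0)."""
    out = np.empty_like(t)
    nu, t_cur = nu0, 0.0
    for i, ti in enumerate(t):
        while t_cur < ti - 1e-15:
            h = min(dt_max, ti - t_cur)
            k1 = f(nu)
            k2 = f(nu + 0.5 * h * k1)
            k3 = f(nu + 0.5 * h * k2)
            k4 = f(nu + h * k3)
            nu += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t_cur += h
        out[i] = nu
    return out


def simulate_dichotomic(
    params: VegetationParams,
    alpha: float,
    tau_e: float,
    tau_i: float,
    horizon: float,
    dt: float,
    seed,
    nu0: float | None = None,
) -> DichotomicTrajectory:
    """Monte-Carlo realization of the two-phase biomass process.

    Exposure and inundation phases alternate with independent exponential
    durations of means ``tau_e`` and ``tau_i`` (growth-rescaled time).
    Within phases the dynamics are integrated exactly for the default
    exponents (logistic growth / exponential decay) and by RK4 otherwise.
    The trajectory is recorded on the regular grid j*dt, j = 0..horizon/dt,
    so time averages over the output are unweighted means.
    """
    if tau_e <= 0 or tau_i <= 0:
        raise ValueError("phase duration means must be positive")
    if dt <= 0 or horizon <= dt:
        raise ValueError("need 0 < dt < horizon")
    if dt > 0.5 * min(tau_e, tau_i):
        raise ValueError("dt must be small compared to the phase durations")
    rng = np.random.default_rng(seed)
    beta, m, n, p = params.beta, params.m, params.n, params.p
    exact = m == 1.0 and n == 1.0 and p == 1.0
    tol = 1e-8 if exact else 1e-4

    grid = np.arange(0.0, horizon, dt)
    nu_out = np.empty_like(grid)
    phase_out = np.empty_like(grid, dtype=bool)

    nu = beta / 2.0 if nu0 is None else float(nu0)
    t0 = 0.0
    inundated = rng.random() < tau_i / (tau_e + tau_i)  # stationary start phase
    i = 0
    n_pts = len(grid)
    while i < n_pts:
        dur = rng.exponential(tau_i if inundated else tau_e)
        t1 = t0 + dur
        j = np.searchsorted(grid, t1, side="left")
        t_rel = grid[i:j] - t0
        if j > i:
            if exact:
                if inundated:
                    nu_out[i:j] = nu * np.exp(-alpha * t_rel)
                else:
                    nu_out[i:j] = _grow_logistic(nu, beta, t_rel)
            else:
                if inundated:
                    f = lambda v: -alpha * max(v, 0.0) ** n
                else:
                    f = lambda v: max(v, 0.0) ** m * max(beta - v, 0.0) ** p
                step = min(dt, dur) / 4.0
                nu_out[i:j] = _rk4_phase(f, nu, t_rel, step)
            phase_out[i:j] = inundated
        # advance state to the end of the phase
        if exact:
            nu = nu * math.exp(-alpha * dur) if inundated else float(
                _grow_logistic(nu, beta, np.array([dur]))[0]
            )
        else:
            f = (lambda v: -alpha * max(v, 0.0) ** n) if inundated else (
                lambda v: max(v, 0.0) ** m * max(beta - v, 0.0) ** p
            )
            nu = float(_rk4_phase(f, nu, np.array([dur]), dur / 64.0)[0])
        if nu < -tol or nu > beta + tol:
            raise RuntimeError(
                f"integration left [0, beta]: nu = {nu} (integrator bug guard)"
            )
        nu = min(max(nu, 0.0), beta)
        t0, i, inundated = t1, j, not inundated
    np.clip(nu_out, 0.0, beta, out=nu_out)
    return DichotomicTrajectory(grid, nu_out, phase_out, seed)
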