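"""Single-file permeation kinetics for a two-site channel.

At large positive membrane potentials the outward flux of a permeant cation
X through the channel can be described by a continuous-time Markov model in
which backward (extracellular -> intracellular) crossing is neglected.  Two
variants are implemented:

* a **single-site** model (states empty E / occupied O) whose stationary
  flux is the Michaelis-Menten form ``J = kL X / (X kL / kR + 1)`` with
  half-activation constant ``kR / kL``;

* a **two-site** model (states E, L, R, D) in which the channel holds up to
  two ions in a left (inner) and right (outer) site.  Allowed transitions:
  ``E -> L`` (entry, rate kL*X), ``L <-> R`` (hops k+ / k-), ``R -> E``
  (single-ion exit, kR), ``R -> D`` (second entry, kL*X), ``D -> L``
  (exit from double occupancy, k~R).  Ion-ion repulsion makes
  ``k~R >> kR``, so conduction proceeds essentially only through the
  doubly occupied state, and the stationary flux retains the
  Michaelis-Menten *form* but with a half-activation constant
  ``X1/2 = (k- + k+) k~R / ((k+ + k~R) kL)`` unrelated to the single-ion
  dissociation constant kR/kL.

All rates are expressed as dimensionless multiples of a common Arrhenius
kinetic prefactor (``rate = exp(-barrier/kT)``); kL additionally carries
M^-1 so that kL*X is a rate.  Fluxes are therefore in prefactor units and
only rate ratios and X1/2 have absolute meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .profiles import FreeEnergyProfile, Minimum, barrier_height

__all__ = [
    "TwoSiteRates",
    "StationaryState",
    "OccupancyReport",
    "arrhenius_rate",
    "rates_from_profiles",
    "single_site_flux",
    "two_site_stationary",
    "two_site_flux",
    "two_site_flux_limit",
    "half_activation",
    "occupancy_ratio_check",
]


@dataclass(frozen=True)
class TwoSiteRates:
    """Rate constants of the two-site hopping scheme (prefactor units).

    Defaults are the barrier estimates extracted from the one- and two-ion
    free-energy profiles of the DMA/CNG-mimic system: hop barriers of 0.5
    and 1.5 kT between the sites, a 15 kT single-ion exit barrier, and a
    7.5 kT exit barrier once repulsion from a second ion destabilizes the
    bound state.  Entry is barrierless, so kL defaults to 1 prefactor/M.
    """

    kL: float = 1.0
    kR: float = math.exp(-15.0)
    kplus: float = math.exp(-0.5)
    kminus: float = math.exp(-1.5)
    kRtilde: float = math.exp(-7.5)

    def __post_init__(self) -> None:
        for name in ("kL", "kR", "kplus", "kminus", "kRtilde"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and non-negative")

    def replace(self, **kw) -> "TwoSiteRates":
        return replace(self, **kw)


@dataclass(frozen=True)
class StationaryState:
    """Stationary occupancies of the two-site scheme and the resulting flux.

    pE/pL/pR/pD are the probabilities of the empty, left-occupied,
    right-occupied and doubly occupied states; flux is in prefactor units
    (None for empirical estimates that carry no flux).
    """

    pE: float
    pL: float
    pR: float
    pD: float
    flux: float | None = None

    def __post_init__(self) -> None:
        ps = (self.pE, self.pL, self.pR, self.pD)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in ps):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(ps) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if self.flux is not None and self.flux < -1e-15:
            raise ValueError("flux must be non-negative")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([self.pE, self.pL, self.pR, self.pD])


def arrhenius_rate(barrier: float) -> float:
    """Transition rate ``exp(-barrier)`` for a barrier in kT units.

    All rates share one kinetic prefactor, which sets the time unit.
    """
    if not math.isfinite(barrier):
        raise ValueError("barrier must be finite")
    return math.exp(-barrier)


def rates_from_profiles(
    single: FreeEnergyProfile,
    double: FreeEnergyProfile,
    site_L: Minimum,
    site_R: Minimum,
    kL: float = 1.0,
) -> TwoSiteRates:
    """Arrhenius rate estimates from one- and two-ion free-energy profiles.

    * ``kR``: escape of the last ion over its full barrier toward bulk,
      from the single-ion profile at ``site_R``.
    * ``k~R``: the same escape when a second ion occupies the channel, from
      the bound well of the two-ion profile (its global minimum).
    * ``k+ / k-``: crossing of the saddle between ``site_L`` and ``site_R``
      on the single-ion profile, measured from each side.
    * ``kL`` is left at its configured value (entry is barrierless for a
      hydrophobic cation like DMA).

    Barriers are converted to kT units with kT = R*T at the profile's
    temperature (2.494 kJ/mol at 300 K).
    """
    from .profiles import global_minimum

    kT = single.kT
    for site in (site_L, site_R):
        if not (single.z[0] <= site.z_min <= single.z[-1]):
            raise ValueError(f"site {site.label!r} is not on the single-ion profile")
    kR = arrhenius_rate(barrier_height(single, site_R, "increasing") / kT)
    bound = global_minimum(double)
    kRtilde = arrhenius_rate(barrier_height(double, bound, "increasing") / double.kT)

    # saddle between the two sites on the single-ion profile
    i_lo = min(site_L.index, site_R.index)
    i_hi = max(site_L.index, site_R.index)
    if i_lo < 0 or i_hi < 0 or i_lo == i_hi:
        raise ValueError("site minima must be distinct minima of the single-ion profile")
    saddle = float(np.max(single.G[i_lo : i_hi + 1]))
    kplus = arrhenius_rate((saddle - site_L.G_min) / kT)
    kminus = arrhenius_rate((saddle - site_R.G_min) / kT)
    return TwoSiteRates(kL=kL, kR=kR, kplus=kplus, kminus=kminus, kRtilde=kRtilde)


def single_site_flux(kL: float, kR: float, X) -> float | np.ndarray:
    """Stationary Michaelis-Menten flux of the single-site model.

    ``J = kL X / (X kL / kR + 1)``, saturating at kR with half-activation
    at X = kR/kL.  kR = 0 gives an absorbing site and zero flux.
    """
    if kL < 0 or kR < 0:
        raise ValueError("rates must be non-negative")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("concentration must be non-negative")
    if kR == 0:
        out = np.zeros_like(X)
    else:
        out = kL * X / (X * kL / kR + 1.0)
    return out if out.ndim else float(out)


def _stationary_single(rates: TwoSiteRates, X: float) -> StationaryState:
    kLX = rates.kL * X
    if kLX == 0:
        return StationaryState(1.0, 0.0, 0.0, 0.0, 0.0)
    # balance equations for (pE, pL, pR, pD); first row replaced by
    # normalization because the generator matrix is rank-deficient
    A = np.array(
        [
            [1.0, 1.0, 1.0, 1.0],
            [kLX, -rates.kplus, rates.kminus, rates.kRtilde],
            [0.0, rates.kplus, -(rates.kminus + rates.kR + kLX), 0.0],
            [0.0, 0.0, kLX, -rates.kRtilde],
        ]
    )
    b = np.array([1.0, 0.0, 0.0, 0.0])
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate model: stationary state is not unique") from exc
    if not np.all(np.isfinite(p)):
        raise ValueError("degenerate model: stationary state is not unique")
    p = np.clip(p, 0.0, 1.0)
    p /= p.sum()
    J = rates.kR * p[2] + rates.kRtilde * p[3]
    return StationaryState(float(p[0]), float(p[1]), float(p[2]), float(p[3]), float(J))


def two_site_stationary(rates: TwoSiteRates, X) -> StationaryState | list[StationaryState]:
    """Stationary state of the two-site scheme by direct linear solve.

    Solves the four balance equations (one replaced by normalization) and
    returns occupancies plus the flux ``J = kR pR + k~R pD``.  Agrees with
    the closed form `two_site_flux` to machine precision.
    """
    X_arr = np.asarray(X, dtype=float)
    if np.any(X_arr < 0):
        raise ValueError("concentration must be non-negative")
    if X_arr.ndim == 0:
        return _stationary_single(rates, float(X_arr))
    return [_stationary_single(rates, float(x)) for x in X_arr]


def two_site_flux(rates: TwoSiteRates, X) -> float | np.ndarray:
    """Closed-form stationary flux of the two-site scheme.

    ``J = X kL k+ k~R (X kL + kR) /
    [(k+ + k~R) X^2 kL^2 + k~R (kR + k- + k+) X kL + kR k+ k~R]``
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("concentration must be non-negative")
    kL, kR, kp, km, krt = rates.kL, rates.kR, rates.kplus, rates.kminus, rates.kRtilde
    xk = X * kL
    num = xk * kp * krt * (xk + kR)
    den = (kp + krt) * xk**2 + krt * (kR + km + kp) * xk + kR * kp * krt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def two_site_flux_limit(rates: TwoSiteRates, X) -> float | np.ndarray:
    """Two-site flux with the slow single-ion exit kR neglected.

    ``J = [kL k+/(k- + k+)] X / ([(k+ + k~R) kL/((k- + k+) k~R)] X + 1)`` --
    exactly the Michaelis-Menten functional form, saturating at
    ``k+ k~R/(k+ + k~R)``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("concentration must be non-negative")
    kL, kp, km, krt = rates.kL, rates.kplus, rates.kminus, rates.kRtilde
    a = kL * kp / (km + kp)
    b = (kp + krt) * kL / ((km + kp) * krt)
    out = a * X / (b * X + 1.0)
    return out if out.ndim else float(out)


def half_activation(rates: TwoSiteRates) -> float:
    """Half-activation concentration X1/2 (mol/L) of the two-site model.

    ``X1/2 = (k- + k+) k~R / ((k+ + k~R) kL)``: the concentration at which
    the kR-neglected flux reaches half its saturation value.  With the
    default rates and kL = 1 /M this evaluates to 7.56e-4 M.
    """
    if rates.kL <= 0 or rates.kRtilde <= 0:
        raise ValueError("kL and kRtilde must be positive")
    if rates.kplus + rates.kminus <= 0:
        raise ValueError("k+ + k- must be positive")
    return (rates.kminus + rates.kplus) * rates.kRtilde / ((rates.kplus + rates.kRtilde) * rates.kL)


@dataclass(frozen=True)
class OccupancyReport:
    """How ion-ion repulsion reshapes the apparent affinity."""

    exit_enhancement: float  # k~R / kR
    one_site_kd: float  # kR / kL, mol/L
    x_half: float  # two-site X1/2, mol/L
    x_half_over_kd: float


def occupancy_ratio_check(rates: TwoSiteRates) -> OccupancyReport:
    """Quantify the repulsion-driven shift of the half-activation constant.

    The second ion raises the exit rate by k~R/kR (about exp(7.5) ~ 1.8e3
    for the defaults) and moves the half-activation point from the
    single-site dissociation constant kR/kL up to X1/2.
    """
    if rates.kR <= 0:
        raise ValueError("kR must be positive to form ratios")
    xh = half_activation(rates)
    kd = rates.kR / rates.kL
    return OccupancyReport(
        exit_enhancement=rates.kRtilde / rates.kR,
        one_site_kd=kd,
        x_half=xh,
        x_half_over_kd=xh / kd,
    )
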