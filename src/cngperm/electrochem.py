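"""Ionic activity corrections for 1:1 electrolytes.

Patch-clamp dose-response work on DMA (dimethylammonium) permeation is done
against the *thermodynamic activity* of the permeant salt, not its nominal
concentration: at the 20-250 mM DMACl concentrations used experimentally the
activity coefficient drops to 0.74-0.87 and ignoring it shifts any fitted
half-activation constant by tens of percent.

Two classical single-parameter models cover the working range:

* the extended Debye-Hueckel equation,
  ``log10(gamma) = -A z^2 sqrt(Ic) / (1 + B d sqrt(Ic))``,
  valid at low ionic strength, and
* the Davies equation,
  ``log10(gamma) = -A z^2 (sqrt(Ic)/(1 + sqrt(Ic)) - C Ic)``,
  an empirical extension for higher ionic strength.

with ``A = 0.509`` (water, ~25 C), ``B = 3.28 nm^-1 M^-1/2``, ion size
``d = 0.35 nm`` for DMA, ``C = 0.3``, and the crossover between the two
models at 100 mM.  All concentrations are in mol/L internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ActivityParams",
    "ionic_strength",
    "debye_huckel_log_gamma",
    "davies_log_gamma",
    "activity_coefficient",
    "activity",
    "concentration_from_activity",
]


@dataclass(frozen=True)
class ActivityParams:
    """Constants of the Debye-Hueckel / Davies activity models.

    Attributes
    ----------
    debye_A:
        Debye-Hueckel limiting-law coefficient (0.509 for water near 25 C),
        dimensionless for log10.
    charge_z:
        Integer ion charge; +1 for DMA.
    ion_size_d:
        Ion size parameter in nm (0.35 nm for DMA).
    size_B:
        Coefficient multiplying ``d * sqrt(Ic)`` in the extended law,
        nm^-1 M^-1/2; 3.28 so that ``d`` in nm applies directly.
    davies_C:
        Linear correction coefficient of the Davies equation.
    switch_conc:
        Concentration (mol/L) at which the conversion switches from
        Debye-Hueckel (below) to Davies (at and above).
    """

    debye_A: float = 0.509
    charge_z: int = 1
    ion_size_d: float = 0.35
    size_B: float = 3.28
    davies_C: float = 0.3
    switch_conc: float = 0.100

    def __post_init__(self) -> None:
        for name in ("debye_A", "ion_size_d", "size_B", "davies_C", "switch_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_PARAMS = ActivityParams()


def _check_nonneg(x: np.ndarray, name: str) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be non-negative")


def ionic_strength(conc, *, z: int = 1):
    """Ionic strength (mol/L) of a fully dissociated symmetric salt.

    ``Ic = 1/2 * sum_i c_i z_i^2``; for a 1:1 salt of concentration ``c``
    this is just ``c``.
    """
    conc = np.asarray(conc, dtype=float)
    _check_nonneg(conc, "concentration")
    Ic = 0.5 * (conc * z**2 + conc * 1**2)  # cation + monovalent counter-ion
    return Ic if Ic.ndim else float(Ic)


def debye_huckel_log_gamma(Ic, params: ActivityParams = DEFAULT_PARAMS):
    """log10 of the activity coefficient by the extended Debye-Hueckel law."""
    Ic = np.asarray(Ic, dtype=float)
    _check_nonneg(Ic, "ionic strength")
    s = np.sqrt(Ic)
    out = -params.debye_A * params.charge_z**2 * s / (1.0 + params.size_B * params.ion_size_d * s)
    return out if out.ndim else float(out)


def davies_log_gamma(Ic, params: ActivityParams = DEFAULT_PARAMS):
    """log10 of the activity coefficient by the Davies equation."""
    Ic = np.asarray(Ic, dtype=float)
    _check_nonneg(Ic, "ionic strength")
    s = np.sqrt(Ic)
    out = -params.debye_A * params.charge_z**2 * (s / (1.0 + s) - params.davies_C * Ic)
    return out if out.ndim else float(out)


def activity_coefficient(conc, params: ActivityParams = DEFAULT_PARAMS):
    """Activity coefficient gamma for a 1:1 salt at concentration `conc` (mol/L).

    Debye-Hueckel below ``params.switch_conc``, Davies at and above.
    """
    conc = np.asarray(conc, dtype=float)
    _check_nonneg(conc, "concentration")
    Ic = 0.5 * 2.0 * conc
    log_g = np.where(
        conc < params.switch_conc,
        debye_huckel_log_gamma(Ic, params),
        davies_log_gamma(Ic, params),
    )
    out = 10.0**log_g
    return out if out.ndim else float(out)


def activity(conc, params: ActivityParams = DEFAULT_PARAMS):
    """Thermodynamic activity (mol/L) of a 1:1 salt: ``conc * gamma(Ic(conc))``."""
    conc = np.asarray(conc, dtype=float)
    out = conc * activity_coefficient(conc, params)
    return out if out.ndim else float(out)


def concentration_from_activity(a: float, params: ActivityParams = DEFAULT_PARAMS) -> float:
    """Invert ``activity``: the concentration (mol/L) whose activity is `a`.

    Well defined because activity is strictly increasing in concentration
    over the working range; solved by bracketed root finding.  `a` must lie
    within the range attainable below 2 mol/L.
    """
    if a < 0:
        raise ValueError("activity must be non-negative")
    if a == 0:
        return 0.0
    # gamma <= 1 so conc >= a; gamma stays above ~0.4 well past 1 M.
    hi = min(2.0, a / 0.3)
    return float(brentq(lambda c: activity(c, params) - a, a, hi, xtol=1e-14))
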