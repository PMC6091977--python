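"""Synthetic free-energy profiles and conductance datasets.

The analysis pipeline is exercised end to end on generated data whose
structure mirrors the DMA/CNG-mimic study conditions:

* **Profiles.**  A one-ion profile with four binding minima (S3 the global
  minimum at 37.4 kJ/mol = 15 kT below bulk; S4 3 kJ/mol shallower; two
  shallow outer sites SX and S0) that flattens to the bulk plateau at 2 nm,
  and a two-ion profile whose single bound well is 25 kJ/mol shallower and
  flattens at 1 nm.  Wells are Gaussian; a weak long-range attraction
  (3 kJ/mol) decays to zero through a smoothstep ramp ending exactly at the
  plateau onset, which is what places the unbinding distance.  Minima
  positions are design choices; only the depth relations and plateau onsets
  carry physical meaning.

* **Conductance.**  A 4-concentration x 4-voltage x 4-replicate design
  (20/50/110/250 mM; +140..+200 mV) generated from the Michaelis-Menten
  law on the activity scale with an apparent Kd of 52 mM (specified on the
  concentration scale and converted), 5% multiplicative Gaussian noise,
  and normalization to the (+200 mV, 110 mM) cell mean.

Profile generation is deterministic; the conductance and AR(1) generators
are seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import electrochem
from .electrochem import ActivityParams
from .fitting import ConductanceDataset
from .profiles import FreeEnergyProfile

__all__ = [
    "ProfileSpec",
    "ConductanceSpec",
    "DEFAULT_SINGLE",
    "DEFAULT_DOUBLE",
    "DEFAULT_SINGLE_LABELS",
    "DEFAULT_FIG4",
    "make_profile",
    "make_conductance",
    "make_ar1_series",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for a synthetic 1-D free-energy profile.

    `wells` lists (center nm, depth kJ/mol, width nm); depth is the total
    well depth measured from the bulk plateau and must exceed `tail_depth`,
    the amplitude of the long-range attraction that persists between the
    wells and the plateau onset.  The attraction ramps smoothly to zero
    over `ramp_width` ending at `plateau_start`; beyond that the profile is
    exactly `baseline`.
    """

    wells: tuple[tuple[float, float, float], ...]
    plateau_start: float
    z_max: float
    grid_step: float = 0.01
    baseline: float = 0.0
    tail_depth: float = 3.0
    ramp_width: float = 0.05
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_start < self.z_max:
            raise ValueError("need 0 < plateau_start < z_max")
        if self.grid_step <= 0 or self.ramp_width <= 0 or self.tail_depth < 0:
            raise ValueError("grid_step and ramp_width must be positive, tail_depth >= 0")
        for c, d, w in self.wells:
            if not 0 <= c < self.plateau_start:
                raise ValueError("well centers must lie before plateau_start")
            if d <= self.tail_depth:
                raise ValueError("well depth must exceed tail_depth")
            if w <= 0:
                raise ValueError("well widths must be positive")


@dataclass(frozen=True)
class ConductanceSpec:
    """Recipe for a synthetic normalized-conductance dataset."""

    k_half_gen_mM: float = 52.0
    g_max_per_voltage: tuple[tuple[float, float], ...] = (
        (140.0, 0.7),
        (160.0, 0.8),
        (180.0, 0.9),
        (200.0, 1.0),
    )
    concentrations_mM: tuple[float, ...] = (20.0, 50.0, 110.0, 250.0)
    n_replicates: int = 4
    noise_cv: float = 0.05
    seed: int = 1234
    normalization_ref: tuple[float, float] = (200.0, 110.0)

    def __post_init__(self) -> None:
        if self.k_half_gen_mM <= 0:
            raise ValueError("k_half_gen_mM must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


# One-ion landscape: S3 global (15 kT), S4 3 kJ/mol shallower, shallow SX/S0,
# unbound beyond 2 nm.  Two-ion landscape: one bound well 25 kJ/mol shallower
# than S3, unbound beyond 1 nm.
DEFAULT_SINGLE = ProfileSpec(
    wells=(
        (0.25, 37.4, 0.06),  # S3
        (0.55, 34.4, 0.06),  # S4
        (0.90, 8.0, 0.06),  # SX
        (1.30, 12.0, 0.06),  # S0
    ),
    plateau_start=2.0,
    z_max=3.0,
)
DEFAULT_SINGLE_LABELS = ("S3", "S4", "SX", "S0")

DEFAULT_DOUBLE = ProfileSpec(
    wells=((0.30, 12.4, 0.06),),
    plateau_start=1.0,
    z_max=2.0,
)

DEFAULT_FIG4 = ConductanceSpec()


def make_profile(spec: ProfileSpec) -> FreeEnergyProfile:
    """Deterministic synthetic profile from a `ProfileSpec`.

    G(z) = baseline - sum of Gaussian wells - tail attraction, where the
    Gaussian amplitude of each well is (depth - tail_depth) so that the
    total depth below the plateau equals the specified depth.  Warns if
    wells overlap enough to merge below ~1 kJ/mol prominence.
    """
    n = int(round(spec.z_max / spec.grid_step)) + 1
    z = np.linspace(0.0, spec.z_max, n)
    # smoothstep ramp: 1 deep inside, 0 at and beyond plateau_start
    u = np.clip((spec.plateau_start - z) / spec.ramp_width, 0.0, 1.0)
    ramp = u * u * (3.0 - 2.0 * u)
    G = spec.baseline - spec.tail_depth * ramp
    for c, d, w in spec.wells:
        G -= (d - spec.tail_depth) * np.exp(-((z - c) ** 2) / (2.0 * w * w))
    centers = sorted(cw[0] for cw in spec.wells)
    for c1, c2 in zip(centers, centers[1:]):
        if c2 - c1 < 0.24:  # < ~4 sigma at the default width: minima may merge
            warnings.warn(
                f"wells at {c1} and {c2} nm overlap strongly; minima may merge",
                stacklevel=2,
            )
    return FreeEnergyProfile(z=z, G=G, temperature=spec.temperature)


def make_conductance(
    spec: ConductanceSpec = DEFAULT_FIG4,
    params: ActivityParams = electrochem.DEFAULT_PARAMS,
) -> ConductanceDataset:
    """Seeded synthetic conductance dataset from a `ConductanceSpec`.

    For each (voltage, concentration, replicate) a Michaelis-Menten value
    ``g_max(V) * a / (a + a_K)`` is drawn with multiplicative Gaussian
    noise of CV `noise_cv`, where activities come from the Debye-Hueckel /
    Davies conversion and ``a_K`` is the activity of the generating
    half-activation concentration.  The whole table is then normalized to
    the mean of the `normalization_ref` cell.
    """
    rng = np.random.default_rng(spec.seed)
    a_k = electrochem.activity(spec.k_half_gen_mM / 1000.0, params)
    rows = []
    for v, gmax in spec.g_max_per_voltage:
        for conc in spec.concentrations_mM:
            a = electrochem.activity(conc / 1000.0, params)
            g0 = gmax * a / (a + a_k)
            eps = rng.normal(0.0, spec.noise_cv, size=spec.n_replicates)
            for r in range(spec.n_replicates):
                rows.append((v, conc, r, g0 * (1.0 + eps[r]), a))
    df = pd.DataFrame(rows, columns=["voltage_mV", "conc_mM", "replicate", "g_norm", "activity_M"])
    v_ref, c_ref = spec.normalization_ref
    cell = df[(df["voltage_mV"] == v_ref) & (df["conc_mM"] == c_ref)]
    if cell.empty:
        raise ValueError("normalization reference cell not present in the design")
    df["g_norm"] = df["g_norm"] / cell["g_norm"].mean()
    df["g_norm"] = df["g_norm"].clip(lower=0.0)
    return ConductanceDataset(data=df, normalization_ref=spec.normalization_ref)


def make_ar1_series(n: int, rho: float, sigma: float, seed: int | None = None) -> np.ndarray:
    """Stationary AR(1) series: x[t+1] = rho x[t] + N(0, sigma).

    x[0] is drawn from the stationary distribution (variance
    sigma^2/(1-rho^2)); used as a correlated-series fixture for block
    analysis.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for stationarity")
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - rho * rho)) if sigma > 0 else 1.0
    innov = rng.normal(0.0, sigma, size=n - 1) if sigma > 0 else np.zeros(n - 1)
    for t in range(n - 1):
        x[t + 1] = rho * x[t] + innov[t]
    return x
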