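"""Global Michaelis-Menten fitting of normalized conductance data.

Dose-response electrophysiology for a permeant ion measures the macroscopic
conductance g at several voltages and bath concentrations, normalized to a
reference (voltage, concentration) cell.  Because the two-site hopping
model predicts a Michaelis-Menten *functional form* for the flux, the data
across all voltages are fitted simultaneously with

    g(a, V) = g_max(V) * a / (a + K_half)

where ``a`` is the ionic *activity* of the permeant (mol/L), each voltage
gets its own saturating conductance g_max(V), and a single shared K_half
(apparent dissociation constant, activity scale) is estimated.

The fit uses variable projection: for a trial K_half the optimal g_max(V)
are linear least-squares solutions in closed form, so the search reduces to
a one-dimensional bounded minimization over log K_half.  This is robust
(positivity is structural, no starting point needed) and fast enough for
bootstrap resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import electrochem
from .electrochem import ActivityParams

__all__ = ["ConductanceDataset", "FitResult", "attach_activities", "global_mm_fit", "bootstrap_khalf"]

_REQUIRED = ("voltage_mV", "conc_mM", "replicate", "g_norm")


@dataclass
class ConductanceDataset:
    """Normalized-conductance records across voltages and concentrations.

    `data` columns: voltage_mV, conc_mM, replicate, g_norm and (after
    `attach_activities`) activity_M.  `normalization_ref` names the
    (voltage mV, conc mM) cell whose mean conductance defines g = 1.
    """

    data: pd.DataFrame
    normalization_ref: tuple[float, float] = (200.0, 110.0)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.data["g_norm"] < 0).any():
            raise ValueError("conductances must be non-negative")
        if (self.data["conc_mM"] < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def has_activities(self) -> bool:
        return "activity_M" in self.data.columns

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "ConductanceDataset":
        return cls(pd.read_csv(path), **kw)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class FitResult:
    """Result of the global Michaelis-Menten fit.

    k_half is on the activity scale (mol/L); g_max maps voltage (mV) to the
    fitted saturating conductance.  `k_half_ci` is an optional bootstrap
    percentile interval.
    """

    k_half: float
    g_max: dict[float, float]
    rss: float
    n_obs: int
    converged: bool
    message: str = ""
    k_half_ci: tuple[float, float] | None = None

    def predict(self, activity, voltage: float):
        a = np.asarray(activity, dtype=float)
        return self.g_max[voltage] * a / (a + self.k_half)


def attach_activities(
    dataset: ConductanceDataset, params: ActivityParams = electrochem.DEFAULT_PARAMS
) -> ConductanceDataset:
    """Return a copy with the activity_M column filled from conc_mM.

    Idempotent: activities are recomputed from concentrations, so attaching
    twice gives identical values.
    """
    df = dataset.data.copy()
    df["activity_M"] = electrochem.activity(df["conc_mM"].to_numpy() / 1000.0, params)
    return replace(dataset, data=df)


def _profiled_rss(a, g, volt, voltages, k_half):
    """RSS and per-voltage g_max at fixed K_half (g_max profiled out)."""
    u = a / (a + k_half)
    rss = 0.0
    gmax = {}
    for v in voltages:
        m = volt == v
        uv, gv = u[m], g[m]
        denom = float(uv @ uv)
        gm = float(gv @ uv) / denom if denom > 0 else 0.0
        gmax[float(v)] = gm
        r = gv - gm * uv
        rss += float(r @ r)
    return rss, gmax


def global_mm_fit(dataset: ConductanceDataset) -> FitResult:
    """Simultaneous Michaelis-Menten fit with one shared K_half.

    Requires activities to be attached, at least 3 distinct activities
    overall, and at least 2 distinct concentrations per voltage.
    Non-convergence of the line search is reported through the `converged`
    flag rather than an exception.
    """
    if not dataset.has_activities:
        raise ValueError("attach activities first (attach_activities)")
    df = dataset.data
    a = df["activity_M"].to_numpy(dtype=float)
    g = df["g_norm"].to_numpy(dtype=float)
    volt = df["voltage_mV"].to_numpy(dtype=float)
    voltages = np.unique(volt)
    if len(np.unique(a)) < 3:
        raise ValueError("need at least 3 distinct activities")
    for v in voltages:
        if len(np.unique(df.loc[volt == v, "conc_mM"])) < 2:
            raise ValueError(f"need >= 2 distinct concentrations at {v} mV")

    pos = a[a > 0]
    lo, hi = np.log(pos.min()) - 8.0, np.log(pos.max()) + 8.0
    res = minimize_scalar(
        lambda lk: _profiled_rss(a, g, volt, voltages, np.exp(lk))[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    k_half = float(np.exp(res.x))
    rss, gmax = _profiled_rss(a, g, volt, voltages, k_half)
    at_bound = min(res.x - lo, hi - res.x) < 1e-6
    return FitResult(
        k_half=k_half,
        g_max=gmax,
        rss=rss,
        n_obs=len(df),
        converged=bool(res.success and not at_bound),
        message="" if res.success and not at_bound else "search hit bounds or failed",
    )


def bootstrap_khalf(
    dataset: ConductanceDataset,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Case-resampling percentile 95% CI for the shared K_half.

    Replicates are resampled with replacement within each (voltage, conc)
    cell, preserving the design.  If any cell has a single replicate the
    resampling falls back to the whole record set, with a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not dataset.has_activities:
        raise ValueError("attach activities first (attach_activities)")
    rng = np.random.default_rng(seed)
    df = dataset.data.reset_index(drop=True)
    groups = [idx.to_numpy() for _, idx in df.groupby(["voltage_mV", "conc_mM"]).groups.items()]
    cellwise = all(len(gidx) >= 2 for gidx in groups)
    if not cellwise:
        warnings.warn(
            "cells with a single replicate: resampling over all records", stacklevel=2
        )
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        for _attempt in range(100):
            if cellwise:
                take = np.concatenate([rng.choice(gidx, size=len(gidx)) for gidx in groups])
            else:
                take = rng.choice(len(df), size=len(df))
            boot = replace(dataset, data=df.iloc[take])
            try:
                estimates[b] = global_mm_fit(boot).k_half
                break
            except ValueError:  # degenerate resample (lost a concentration)
                continue
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)
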