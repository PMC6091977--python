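"""One-dimensional free-energy-profile analysis.

The permeation coordinate is the distance z (nm) of the permeant ion from
the center of mass of a reference filter residue (Val64 in the CNG-mimic
channel); G(z) is the free energy in kJ/mol projected on that coordinate by
enhanced-sampling MD.  This module reads/writes such profiles in the
whitespace-delimited text dialect produced by Plumed FES tools and extracts
the quantities the kinetic analysis needs: binding minima and their depths,
inter-site and escape barriers, and the distance at which the ion is
effectively unbound (profile flat within tolerance of the bulk plateau).

Error bars on block-averaged observables are estimated by block analysis,
the standard remedy for serial correlation in MD time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "FreeEnergyProfile",
    "Minimum",
    "ProfileFormatError",
    "read_profile",
    "write_profile",
    "bulk_reference",
    "find_minima",
    "global_minimum",
    "depth_difference",
    "unbinding_distance",
    "barrier_height",
    "block_error",
]


class ProfileFormatError(ValueError):
    """Malformed profile file (non-numeric rows, too few points, duplicate z)."""


@dataclass
class FreeEnergyProfile:
    """Tabulated free energy G(z) with optional per-point standard errors.

    z is strictly increasing, in nm; G and err in kJ/mol; temperature in K
    (used when converting barriers to thermal units).
    """

    z: np.ndarray
    G: np.ndarray
    err: np.ndarray | None = None
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if self.err.shape != self.z.shape:
                raise ValueError("err must have the same length as z")
        if self.z.ndim != 1 or self.G.shape != self.z.shape:
            raise ValueError("z and G must be 1-D arrays of equal length")
        if len(self.z) < 3:
            raise ValueError("a profile needs at least 3 points")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite everywhere")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def __len__(self) -> int:
        return len(self.z)

    @property
    def grid_step(self) -> float:
        """Median grid spacing (nm)."""
        return float(np.median(np.diff(self.z)))

    @property
    def kT(self) -> float:
        """Thermal energy R*T in kJ/mol."""
        from scipy.constants import R

        return R * self.temperature / 1000.0


@dataclass(frozen=True)
class Minimum:
    """A local free-energy minimum (binding site) of a profile."""

    label: str
    z_min: float
    G_min: float
    depth: float  # relative to the bulk plateau, >= 0
    prominence: float
    index: int = field(default=-1, compare=False)


def read_profile(path: str | Path, temperature: float = 300.0) -> FreeEnergyProfile:
    """Read a whitespace-delimited z/G[/err] profile.

    Lines starting with ``#`` (including Plumed's ``#! FIELDS`` headers) and
    blank lines are ignored.  Rows must have a consistent count of 2 or 3
    numeric columns.  The grid is sorted ascending; duplicate z values are
    rejected.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncols: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) not in (2, 3):
                raise ProfileFormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ProfileFormatError(
                    f"{path}:{lineno}: inconsistent column count ({len(parts)} vs {ncols})"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ProfileFormatError(f"{path}:{lineno}: non-numeric value") from exc
    if len(rows) < 3:
        raise ProfileFormatError(f"{path}: a profile needs at least 3 data rows")
    data = np.array(rows)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise ProfileFormatError(f"{path}: duplicate z values")
    err = data[:, 2] if data.shape[1] == 3 else None
    return FreeEnergyProfile(z=data[:, 0], G=data[:, 1], err=err, temperature=temperature)


def write_profile(profile: FreeEnergyProfile, path: str | Path) -> None:
    """Write a profile in the same text dialect `read_profile` accepts."""
    path = Path(path)
    cols = ["z_nm", "G_kJmol"] + (["err_kJmol"] if profile.err is not None else [])
    with path.open("w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for i in range(len(profile)):
            vals = [profile.z[i], profile.G[i]]
            if profile.err is not None:
                vals.append(profile.err[i])
            fh.write(" ".join(f"{v:.17g}" for v in vals) + "\n")


def bulk_reference(profile: FreeEnergyProfile, tail_fraction: float = 0.1) -> float:
    """Mean free energy over the last `tail_fraction` of the z range.

    This defines the unbound (bulk) plateau against which well depths and
    the unbinding distance are measured.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    z0 = profile.z[-1] - tail_fraction * (profile.z[-1] - profile.z[0])
    mask = profile.z >= z0
    return float(np.mean(profile.G[mask]))


def find_minima(
    profile: FreeEnergyProfile,
    prominence_min: float = 1.0,
    labels: Sequence[str] | None = None,
    tail_fraction: float = 0.1,
) -> list[Minimum]:
    """All interior local minima with topographic prominence >= `prominence_min`.

    Minima are returned in z order.  For a flat-bottomed well the leftmost
    grid point of the plateau is the representative position.  Labels are
    assigned in z order from `labels` if given, otherwise auto-numbered
    ``m0, m1, ...``.
    """
    if prominence_min <= 0:
        raise ValueError("prominence_min must be positive")
    idx, props = find_peaks(-profile.G, prominence=prominence_min, plateau_size=(1, None))
    idx = props["left_edges"]  # leftmost point of flat bottoms
    bulk = bulk_reference(profile, tail_fraction)
    out = []
    for k, i in enumerate(idx):
        name = labels[k] if labels is not None and k < len(labels) else f"m{k}"
        out.append(
            Minimum(
                label=name,
                z_min=float(profile.z[i]),
                G_min=float(profile.G[i]),
                depth=max(0.0, bulk - float(profile.G[i])),
                prominence=float(props["prominences"][k]),
                index=int(i),
            )
        )
    return out


def global_minimum(profile: FreeEnergyProfile, tail_fraction: float = 0.1) -> Minimum:
    """The deepest minimum of the profile; ties broken by smaller z.

    Falls back to the interior grid argmin, so a flat profile degenerates to
    depth 0 at the first interior point.
    """
    interior = profile.G[1:-1]
    i = int(np.argmin(interior)) + 1  # first occurrence -> smaller z on ties
    bulk = bulk_reference(profile, tail_fraction)
    depth = max(0.0, bulk - float(profile.G[i]))
    return Minimum(
        label="global",
        z_min=float(profile.z[i]),
        G_min=float(profile.G[i]),
        depth=depth,
        prominence=depth,
        index=i,
    )


def depth_difference(profile: FreeEnergyProfile, a: Minimum, b: Minimum) -> float:
    """Signed free-energy difference G(a) - G(b) between two minima (kJ/mol)."""
    for m in (a, b):
        if not (profile.z[0] <= m.z_min <= profile.z[-1]):
            raise ValueError(f"minimum {m.label!r} lies outside the profile range")
    return a.G_min - b.G_min


def unbinding_distance(
    profile: FreeEnergyProfile,
    tol: float = 1.0,
    tail_fraction: float = 0.1,
) -> float:
    """Distance beyond which the ion is unbound.

    Smallest grid z past the global minimum such that G stays within `tol`
    (kJ/mol) of the bulk plateau for every z' >= z.  If the profile never
    flattens, the profile end is returned with a warning.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    bulk = bulk_reference(profile, tail_fraction)
    gm = global_minimum(profile, tail_fraction)
    within = np.abs(profile.G - bulk) <= tol
    # suffix_ok[i] == True iff every point from i on is within tolerance
    suffix_ok = np.flip(np.logical_and.accumulate(np.flip(within)))
    candidates = np.nonzero(suffix_ok & (profile.z > gm.z_min))[0]
    if len(candidates) == 0:
        warnings.warn(
            "profile does not flatten within tolerance; returning profile end",
            stacklevel=2,
        )
        return float(profile.z[-1])
    return float(profile.z[candidates[0]])


def barrier_height(
    profile: FreeEnergyProfile,
    m: Minimum,
    direction: Literal["increasing", "decreasing"] = "increasing",
) -> float:
    """Escape barrier from minimum `m` toward one profile boundary (kJ/mol).

    Maximum of G on the path from z_min to the boundary in the requested
    direction, minus G at the minimum; always >= 0.
    """
    i = m.index if m.index >= 0 else int(np.argmin(np.abs(profile.z - m.z_min)))
    if direction == "increasing":
        path = profile.G[i:]
    elif direction == "decreasing":
        path = profile.G[: i + 1]
    else:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    return float(np.max(path) - profile.G[i])


def block_error(series, n_blocks: int) -> float:
    """Standard error of the mean of a (possibly correlated) series.

    Splits the series into `n_blocks` contiguous blocks and returns the
    sample standard deviation of the block means divided by sqrt(n_blocks).
    For correlated data the estimate grows with block size until blocks
    decorrelate, which is the usual convergence diagnostic.
    """
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be at least 2")
    if len(series) < 2 * n_blocks:
        raise ValueError("series too short: need at least 2 points per block")
    means = np.array([b.mean() for b in np.array_split(series, n_blocks)])
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))
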