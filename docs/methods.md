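# Methods

## The permeation model

The channel is modelled as a continuous-time Markov chain over occupancy
states of its selectivity filter. At large positive potentials the outward
ion flow dominates and backward (extracellular → intracellular) crossing is
neglected, which makes the chain irreversible in the conduction direction.

*Single-site model.* States E (empty) and O (occupied); entry at rate
k_L·X (X = intracellular permeant concentration, mol/L) and exit at k_R.
The stationary flux is the Michaelis–Menten form J = k_L·X/(X·k_L/k_R + 1)
with half-activation at X½ = k_R/k_L.

*Two-site model.* States E, L (inner site occupied), R (outer site
occupied), D (both). Transitions: E→L (k_L·X), L→R (k⁺), R→L (k⁻),
R→E (k_R), R→D (k_L·X), D→L (k̃_R). Solving the four balance equations
(one row replaced by normalization, since the generator matrix is
rank-deficient) gives the closed-form flux quoted in the README, with
J = k_R·p_R + k̃_R·p_D. When k_R is negligible the flux is again exactly of
Michaelis–Menten form with X½ = (k⁻+k⁺)·k̃_R/((k⁺+k̃_R)·k_L): the two
scenarios are indistinguishable by the *shape* of a dose–response curve,
only the value of X½ distinguishes them.

Rates are Arrhenius factors exp(−ΔG/kT) in units of one shared kinetic
prefactor; k_L additionally carries M⁻¹ and defaults to 1 (entry is
barrierless for a hydrophobic cation). Only rate ratios and X½ therefore
have absolute meaning; fluxes are reported in prefactor units. Barriers
from kJ/mol profiles are converted with kT = R·T (2.494 kJ/mol at 300 K).

Default rates: k⁺ = e^-0.5, k⁻ = e^-1.5, k_R = e^-15, k̃_R = e^-7.5.
With k_L = 1 /M these give X½ = 7.56e-4 M. Two printed figures in the
source estimates are mutually inconsistent and are surfaced, not resolved:
a ≈15 kT exit barrier corresponds to 37.4 kJ/mol (not "almost 50"), and a
25 kJ/mol well-depth reduction corresponds to e^10.0 (not e^7.5) rate
enhancement. The rate defaults use the printed exponents; profile-based
extraction (`rates_from_profiles`) reports whatever the profiles imply.

A consequence worth noting: flux is monotone in X only in the repulsive
regime k̃_R ≥ k_R. If double occupancy *slowed* the exit (k̃_R < k_R) the
model predicts self-block — flux peaks and then falls with concentration —
so the monotonicity property is asserted only for k̃_R ≥ k_R.

## Free-energy-profile analysis

Profiles are single-branch G(z) tables (z = distance from the filter
reference residue, nm; G in kJ/mol) in Plumed-FES-style text. Choices:

- **Minima** are detected by topographic prominence (default threshold
  1 kJ/mol) rather than raw sign changes, because realistic profiles carry
  ~kJ/mol error bars; flat-bottomed wells are represented by their leftmost
  grid point.
- **Depths** are measured from the bulk plateau, defined as the mean of G
  over the last 10% of the z range (`tail_fraction = 0.1`).
- **Unbinding distance** is the smallest grid point beyond the global
  minimum from which G stays within `tol` (default 1 kJ/mol) of the plateau
  for all larger z; a profile that never flattens returns its endpoint with
  a warning.
- **Escape barriers** are max-over-path minus the minimum's G, toward
  either boundary. No smoothing is applied by default.
- **Block analysis**: the series is split into n contiguous blocks and the
  SE is std(block means, ddof=1)/√n; for correlated series the estimate
  grows with block length until blocks decorrelate.

## Gillespie simulation

Direct method (two uniforms per event, exponential waiting times from the
total propensity), kept exact because the rates span ~7 orders of
magnitude. Uniforms are drawn in chunks from numpy's PCG64 generator, so a
fixed seed reproduces trajectories across platforms. Default trajectory
lengths are chosen to accumulate ≥ ~1000 permeation events, which puts the
Monte-Carlo SE of the flux near 3%.

Flux SE comes from block analysis of time-binned exit counts. Occupancy
SEs (`occupancy_se`) combine block scatter with a *single-visit resolution
floor*, the mean sojourn time of a state divided by the observation window
(computed from the generator's propensities, not from the analytic
solution). The floor matters for states the chain is expected to visit
less than about once per run — e.g. the empty state at millimolar
concentrations, reachable only through the very slow single-ion exit —
where block scatter alone would report zero uncertainty and any comparison
against the analytic occupancy would be ill-posed.

## Activity corrections

log₁₀ γ = −0.509·z²·√Ic/(1 + 3.28·d·√Ic) (extended Debye-Hückel, d in nm)
below 100 mM, and the Davies form −0.509·z²·(√Ic/(1+√Ic) − 0.3·Ic) at and
above (ties to Davies). Base-10 logarithms, as conventional with the 0.509
coefficient. The branch switch moves γ by < 0.02 at 100 mM. Only 1:1
salts are supported; ionic strength equals the salt concentration.

## Conductance fitting

g(a, V) = g_max(V)·a/(a + K_half) is fitted to all replicate records
simultaneously (unweighted least squares), with one shared K_half and one
g_max per voltage, a = activity in mol/L. The solver uses variable
projection: for fixed K_half each g_max(V) has a closed-form linear
least-squares solution, so the problem reduces to a bounded 1-D
minimization of the profiled RSS over log K_half (positivity is structural
and no starting point is needed; this is also what makes ~10⁴ bootstrap
refits cheap). Reported K_half is on the activity scale;
`electrochem.concentration_from_activity` maps it back to a nominal salt
concentration for comparison with concentration-quoted constants.

The bootstrap CI is the prescribed percentile interval from case
resampling within each (voltage, concentration) cell. With n = 4
replicates per cell this interval is known to run slightly narrow
(within-cell resampling underestimates variance by ~(n−1)/n), so its true
coverage sits a few points below the nominal 95%; measured coverage under
the default generator settings is ≈88–90%. Degenerate resamples that lose
a voltage's second distinct concentration are redrawn.

## Synthetic data

*Profiles.* G(z) = baseline − Σᵢ (depthᵢ − tail)·exp(−(z−cᵢ)²/2wᵢ²) −
tail·ramp(z), where ramp is 1 in the interior and smoothsteps to 0 over
the 0.05 nm ending at `plateau_start`. The weak long-range attraction
(tail = 3 kJ/mol) is what places the unbinding distance at the plateau
onset: narrow Gaussians alone would decay to bulk right after the last
well. Because Gaussian amplitudes subtract the tail, each well's total
depth below the plateau equals its specified depth exactly. The one-ion
default has wells of 37.4 (S3, = 15 kT so Arrhenius extraction reproduces
e^-15), 34.4 (S4, i.e. +3 kJ/mol), 8 (SX) and 12 (S0) kJ/mol at
0.25/0.55/0.90/1.30 nm with plateau at 2 nm; the two-ion default has one
12.4 kJ/mol well (25 kJ/mol shallower) with plateau at 1 nm. Positions
and the shallow-well depths are free design choices; only the ordering,
the 3 and 25 kJ/mol offsets, and the plateau onsets are meaningful. The
unbinding detector at tol = 1 kJ/mol crosses inside the ramp, ~0.02 nm
before the plateau onset (1.99 and 0.99 nm on the 0.01 nm grid).

*Conductance.* 4 concentrations (20/50/110/250 mM) × 4 voltages
(+140..+200 mV) × 4 replicates; generating half-activation constant 52 mM
specified on the concentration scale and converted to activity; g_max
rises linearly with voltage (0.7..1.0 before normalization); multiplicative
Gaussian noise with CV 5% (iid per replicate — the experimental error
model is unknown beyond mean ± SD); normalization to the (+200 mV,
110 mM) cell mean, which the free per-voltage g_max absorbs.

What the synthetic layer does *not* emulate: voltage-dependent kinetics,
correlated replicate noise, leak/rundown artifacts, or any structural
detail of real free-energy surfaces (multi-branch exit paths, entropic
plateaus). Passing tests therefore demonstrate the correctness of the
analysis machinery under the stated generative assumptions, not the
field-data robustness of the estimators.

## Problem sizes

Profiles use a 0.01 nm grid (201–301 points). Gillespie cross-checks run
to ~1200 expected exits per concentration (up to ~7e6 events at 0.1 mM).
The bootstrap uses 200 resamples per interval and the coverage simulation
100 repetitions; the acceptance script's fit runs on the 64-record default
design.
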