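# Methods

This note documents the models, numerical choices and known limitations of
the `catchbond` package in one place. Units are fixed package-wide: nm, pN,
s, K; spring constants are N/m (1 N/m = 1000 pN/nm); thermal energy
defaults to T = 298.15 K with kB = 0.013807 pN·nm/K (kBT ≈ 4.1166 pN·nm),
configurable through `ThermalContext`.

## Polymer elasticity

Force–extension data are mapped into contour-length space with the freely
rotating chain (FRC), a rigid-bond model with bond length `b`, fixed bond
angle `γ` and correction constant `c`:

```
x/L = Fa/3kBT                  for Fb/kBT < b/p        (entropic)
x/L = 1 − (4Fp/kBT)^(−1/2)     for b/p < Fb/kBT < p/b  (intermediate)
x/L = 1 − (cFb/kBT)^(−1)       for p/b < Fb/kBT        (high force)
```

with Kuhn length `a = b(1+cos γ)/((1−cos γ)cos(γ/2))` and persistence
length `p = b cos(γ/2)/|ln cos γ|`. Defaults are the standard polypeptide
values `b = 0.4 nm`, `γ = 41°`, `c = 2`; they are a documented choice, not
a fitted quantity, and are configurable per analysis.

The piecewise law is not continuous everywhere. With the defaults the
mid/high junction is exactly continuous (a property of `c = 2`), but the
low/mid junction jumps down by ≈ 0.26 in `x/L` at ≈ 3.1 pN.
`frc_branch_discontinuities` reports both junctions; nothing is smoothed
or masked. The discontinuity lies below the 10 pN contour-length noise
floor, so it never affects analysed samples, but synthetic curves rendered
with the FRC inverse do show a force jump across it, and ruptures landing
exactly on the seam (~14 pN with defaults) produce one-sample spikes that
peak detection legitimately misses. Boundary equality is assigned to the
middle branch; the inverse map returns the lowest admissible force, which
makes transform ∘ inverse an exact identity (used heavily in tests).

Below the noise floor (default 10 pN) the inversion `L = x/(x/L)(F)`
amplifies force noise without bound; those samples are returned as NaN —
excluded, never zeroed.

Simulations generate forces with the Marko–Siggia WLC interpolation
`F = (kBT/p)[1/(4(1−x/L)²) − 1/4 + x/L]`; its inverse is computed by
bisection (monotone, unique root).

## Synthetic data generator

The generator emulates a surface–ELP–fingerprint–complex–ELP–cantilever
construct:

* tether: 130 nm ELP contour (2 × 65 nm handles) plus a folded-protein
  offset of 28 nm, giving an initial contour of 158 nm and a
  post-fingerprint contour of 190 nm. Reported construct geometries give a
  bare-rupture contour of ~135 nm *and* a fingerprint-complete contour of
  ~190 nm, which a single +32 nm increment cannot connect; the generator
  therefore exposes the folded offset as one free parameter and its
  default reproduces the fingerprint-complete value. Pipeline defaults
  keep the 135/190 nm criteria; analyses of generator output set
  `criterion1_contour = 158`.
* fingerprint: 2 domains × 2 events × 8 nm, each event firing
  deterministically when the force crosses a per-curve threshold drawn
  uniformly in 50–80 pN (thresholds sorted ascending). Zero-noise curves
  are therefore exactly recoverable: event count, 0.1 nm increments and
  0.1 pN rupture forces round-trip through the pipeline.
* intermediates: on each state transition of the bond model, with
  probability 0.4, a contour increment ~N(15, 5²) nm (floored at 1 nm) is
  added, emulating pathway-linked partial unfolding (median ≈ 15 nm).
* rupture: the complex follows the same shuffled-event kinetic Monte Carlo
  rule as the dedicated simulator, marched along the curve's own
  extension/time grid.
* noise: Gaussian force noise (default 2 pN), optional linear baseline
  drift, and optional non-specific adhesion artifacts — a sharp triangular
  peak at 30–70 nm extension that the prefilter rejects as an early peak.
* force clamp: ramp at a configurable rate (default 400 pN/s,
  cantilever-limited), plateau at the target setpoint plus a per-trace
  Gaussian offset (default sd 2 pN, emulating ~5 pN instrument setpoint
  accuracy), lifetime drawn from the clamp simulator, then release and
  50 ms of zero-force tail. Lifetimes under 15 ms are generated but
  flagged below the detection floor.

Per-curve randomness comes from `default_rng([master_seed, curve_index])`,
so datasets are reproducible and order-independent.

What the generator does **not** emulate: thermal cantilever dynamics,
hydrodynamic drag, feedback ringing, surface contact/approach segments,
multiple simultaneous tethers, or instrument drift beyond a linear tilt.
Passing tests on this synthetic data therefore validates the *analysis
logic* (filters, transforms, fits), not robustness to every artifact of
real traces.

## Curve pipeline

* Baseline: a line fitted to the post-rupture tail (samples beyond the
  last median-smoothed force above 10 pN) is subtracted; tail median
  forced to zero; curves without a tail are flagged and passed through.
* Peaks: median smoothing (5 samples), `scipy.signal.find_peaks` with
  10 pN prominence, a required 10 pN drop after the peak, and apex
  re-location on the raw signal (smoothing shifts maxima by 1–2 samples).
* Prefilter rejection reasons are exclusive and checked in order:
  `early_peak` (first peak < 100 nm), `no_peaks`, `too_many_peaks` (> 9).
* Fingerprint criteria (tildes made explicit, all configurable):
  criterion 1 = bare rupture < 100 pN at 135 ± 10 nm with no other peaks;
  criterion 2 = four 50–80 pN peaks (hard window) whose increments sum to
  32 ± 4 nm and rupture at 190 ± 15 nm. When extra in-window peaks exist,
  the four whose increments sum closest to 32 nm are taken as the
  fingerprint; identified intermediate increments are credited to the
  expected final contour before the 190 nm comparison (a curve with one
  15 nm intermediate ruptures at ~205 nm).
* Loading rate: linear force-vs-time fit from the last local minimum
  before the terminal peak, restricted to forces above 30% of the rupture
  force; fewer than 5 samples flags the record with an undefined rate.
  Time is reconstructed from head height `H = x + F/k` at the pulling
  speed.
* Subtypes: `a` = criterion-1 rupture, `b` = criterion-2 without
  intermediates, `c` = with intermediates. This taxonomy is a documented
  convention of this package.
* Clamp filtering, in order: > 3 discrete head-height steps (> 5 nm jumps
  between feedback plateaus), retraction distance outside [40, 200] nm
  (measured up to bond rupture, excluding the post-rupture pull-away),
  lifetime < 15 ms. Setpoint = maximum mean force over a sliding ~5 ms
  window during clamping; lifetime = clamp start to resumption of
  retraction.

## Pathway classification

Pooled rupture forces are square-root transformed and z-standardised
(invertible; standardisation is the package's documented choice of
normalisation). 1-D Gaussian mixtures with 1–4
unequal-variance components are fitted with 10 restarts and a fixed seed;
the component count is selected by BIC, matching the behaviour of the
model-based-clustering software family commonly used for this step.
Pathways P0 < P1 < P2 are components ordered by mean; assignment is by maximum responsibility with ties toward the
lower-mean pathway. A selected fourth component is treated as minor
experimental variance: the smallest-weight component with Bhattacharyya
overlap > 0.1 against another is removed and its records reassigned by
maximum remaining responsibility (no overlapping parent → still removed,
but flagged). Proportions are computed per experiment and speed (summing
to 1) and averaged across experiments with SEM; a single experiment
reports SEM = NaN.

## Energy landscapes

The histogram transform uses 10 pN bins from zero force; per-bin force and
loading rate are in-bin medians. Occupied bins with fewer than 3 records
are merged into their upper neighbour (the transform generalises to
unequal widths via the count form
`k_off = C_k r_k / (w_k (C_k/2 + Σ_{i>k} C_i))`, which reduces to the
equal-width expression). The DHS model

`k_off(F) = k0 (1 − νFΔx/ΔG‡)^{1/ν−1} exp{βΔG‡[1 − (1 − νFΔx/ΔG‡)^{1/ν}]}`

is fitted to ln k_off by Levenberg–Marquardt from uniform random starts
within k0 ∈ [0.001, 20] s⁻¹, Δx ∈ [0.001, 2] nm, ΔG‡ ∈ [0.01, 20]; ΔG‡ is
carried in kBT units (the conventional bounds are quoted without units;
kBT is the documented choice). The package default is 10,000 starts in 3
independently seeded batches whose best SSRs must agree within 1%; tests
and the acceptance script use a few hundred starts, which saturates this
3-parameter, ≤ 15-point fit. At ν = 1 the model reduces algebraically to
the Bell rate, so ΔG‡ is reported as unidentifiable; the same flag fires
when ΔG‡ runs into its upper bound, which happens whenever ln k(F) is
effectively linear (Bell-like data).

The force–loading-rate relation is implemented as

`F(l) = ΔG‡/(νΔx) · {1 − [(1/βΔG‡) ln(k0 e^{βΔG‡} kBT/(Δx l))]^ν}`

(ΔG‡ here in energy units). This form satisfies the analytic zero
`F = ΔG‡/(νΔx)` at `l* = k0 e^{βΔG‡} kBT/Δx` and reduces *exactly* to the
Bell–Evans spectrum `F = (kBT/Δx) ln(Δx l/(k0 kBT))` at ν = 1, which is
the consistency check the tests enforce. Beyond `l*` the barrier has
vanished and the value is undefined (NaN). The Bell–Evans fit is
unweighted least squares of per-speed median force against the log median
loading rate; Δx comes from the slope and is the robust quantity; k0 is a
zero-force extrapolation and should be read as order-of-magnitude only.

## Kinetic Monte Carlo

States N, I1, I2 carry rupture edges P0, P1, P2, forward edges
N→I1, I1→I2 and, in the reversible variant, I1→N and I2→I1; each edge is a
Bell rate. Constant-speed pulling marches an evenly spaced molecular
extension grid (default 0.1 nm); the WLC gives `F(x)`, head height
`H = x + F/k` gives time via `dt = dH/V`, and each step each eligible
event fires with `P = 1 − e^{−k(F)dt}`. The literal stepping rule —
shuffle eligible events, execute the first success — is implemented in an
equivalent vectorised form: independent Bernoulli draws per event, then a
uniform choice among the successes (a uniform permutation restricted to
the success set is uniform on it). Rupture records the current force,
local loading rate (dF/dt from the WLC + cantilever series compliance) and
pathway; a tether stretched to its contour length marks the replicate
censored.

Force clamp holds F constant, so the per-step probabilities are constant
and the same stepped process is sampled exactly with geometric waiting
times per event (ties broken uniformly), capped at 10 s (censored). The
default interval is Δt = 10⁻⁴ s; a warning fires when Δt·max k exceeds
0.1, where faster-than-step dynamics collapse onto single intervals. The
per-interval probability `1 − e^{−kΔt}` is used throughout — multiplying
an off-rate by the total elapsed time does not define a probability and
is not used.

### Hidden-barrier search

Transition-edge parameters are not observable as curve events; they are
fitted by random search: draw candidate (k0, Δx) for each transition edge
— k0 log-uniform in [10⁻⁵, 100] s⁻¹ (the range spans seven decades, which
uniform sampling cannot cover usefully), Δx uniform in [0.01, 10] nm —
simulate 500 replicates per speed (rupture edges held at their
experimentally fitted values), and score with the SSR between simulated
and target probability-normalised 20 pN histograms summed over speeds.
The best 1% of starts get a coordinate-wise multiplicative polish (×2 /
×½ per parameter per sweep, fresh simulation seeds, improvements kept).
The package default is 10,000 starts; tests and acceptance use 100 starts
× 100 replicates, which suffices for the model-comparison property. Model
comparison runs both variants with equal budgets and prefers the lower
total SSR.

### The demonstration catch-bond model

`example_catch_bond_model()` encodes the qualitative multi-state
catch-bond landscape: rupture Δx decreasing (0.5 / 0.25 / 0.1 nm) and
zero-force stability increasing (k0 = 2 / 0.5 / 0.15 s⁻¹) from P0 to P2;
strongly force-promoted forward transitions (Δx = 1.2, 0.7 nm) that funnel
the complex into the intermediates above ~20 pN; and weak but also
force-promoted reverse transitions (k0 = 10⁻³ s⁻¹, Δx = 0.45 nm) that are
negligible in the catch regime yet dominant above ~80 pN, cascading
complexes back to N. This produces a mean clamp lifetime peaking near
30–40 pN with P0 ruptures dominating at both force extremes and P2 inside
the catch window — and it makes reversibility *identifiable* from
constant-speed histograms: the high-force native-pathway ruptures cannot
be produced by any irreversible parameter set with the same rupture edges.
Reverse edges with force-insensitive rates, by contrast, act as a
quasi-equilibrium prefactor on the forward flux and are nearly invisible
in rupture-force histograms. The parameter values are package defaults
chosen to illustrate the mechanism; they are not fitted experimental
constants, and quantitative positions (exact peak force, lifetime scale)
have no claim to match any specific complex.

## Statistics

Shapiro–Wilk screens each group at α = 0.05 (n ≥ 3). Kruskal–Wallis is
the omnibus test; all-identical data returns p = 1 by convention. Dunn's
tests use tie-corrected rank variance and Šidák adjustment
`p' = 1 − (1−p)^m` with m = all pairs in the panel; the compact letter
display uses insert-and-absorb, so two groups share a letter iff their
adjusted p ≥ α. The rank-sum variant uses two-sided Mann–Whitney tests.
The Hill fit `signal = baseline + bmax·cⁿ/(K_Dⁿ + cⁿ)` runs from a
log-spaced K_D grid with n bounded to [0.5, 4] (free but bounded is the
package's documented choice).
At 5% noise on the 7-point 5-fold design the mean K_D recovery error is
~10–13%; single noise realisations occasionally exceed 20% because n and
K_D trade off, which the tests acknowledge by asserting on the mean.

## Problem sizes

Default test and acceptance problem sizes are the package's own choices
for desk-scale runs: 500 replicates per pulling speed and 100–1000 per
clamp setpoint for the simulators; 90–120 DHS starts; 100 random-search
starts × 100 replicates for barrier fitting; 600-record GMM samples;
10–30 seeds for recovery sweeps. All scale up by configuration.

## I/O

Curves and clamp traces are TSV files with JSON metadata sidecars; record
tables are CSV with unit-suffixed columns; models and configurations are
JSON. Run provenance embeds the package version, master seed and a SHA-256
configuration hash. All formats are plain text by design (desk-scale data,
diffable fixtures); no binary container format is provided.
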