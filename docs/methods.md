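# Methods

## The model

`minwave` simulates the pole-to-pole oscillation of the *E. coli* Min
system with a one-dimensional reaction-diffusion model of five species
along the cell's long axis: cytosolic MinD-ADP (`c_DD`), cytosolic
MinD-ATP (`c_DT`), cytosolic MinE (`c_E`), membrane-bound MinD-ATP
(`c_d`), and the membrane-bound MinD-MinE complex (`c_de`).
Concentrations are linear densities in molecules/µm; the 1D reduction
removes any cytosol/membrane volume conversion. Five mass-action steps
couple the species:

| step | rate constant | units | reference value |
|---|---|---|---|
| spontaneous membrane attachment of MinD-ATP | `k_D` | 1/s | 1.66 |
| cooperative recruitment of MinD-ATP by membrane MinD | `k_dD` | µm/s | 0.22 |
| recruitment of MinE by membrane MinD | `k_dE` | µm/s | 0.82 |
| MinDE complex dissociation (ATP hydrolysis) | `k_de` | 1/s | 0.33 |
| nucleotide exchange MinD-ADP → MinD-ATP | `k_ADP_ATP` | 1/s | 1.09 |

Because densities are per-µm, the bimolecular constants carry µm/s so
every reaction term has units (molecules/µm)/s. Diffusion coefficients
are `D_D` = 16 µm²/s for both cytosolic MinD states, `D_E` = 10 µm²/s
for cytosolic MinE, and `D_d` = `D_de` = 0.2 µm²/s for the
membrane-bound species. Protein content is 2,205 MinD and 1,580 MinE
molecules at the reference length 2.84 µm; copy numbers scale
proportionally with length (fixed concentration). The reaction terms
conserve total MinD (`c_DD + c_DT + c_d + c_de`) and total MinE
(`c_E + c_de`) identically; the test suite asserts both as exact
algebraic identities and as <1e-8 relative drift over full simulations.

The reference rate-constant set above (screen id #2827) is the one
combination, found by random search, whose oscillation features match
the experimentally observed behavior of growing cells.

## Numerics

**Grid.** Node-centered: `L/dx + 1` points spanning `[0, L]` with
`dx = 0.2` µm. Reflecting boundaries are imposed through symmetric ghost
points (`c[-1] = c[1]`), under which the trapezoidal-rule mass of every
species is conserved exactly by the semi-discrete scheme. The
node-centered layout was chosen over a cell-centered one deliberately:
at the report lengths (2.6, 3.0, 3.8, 4.6 µm, all with odd `L/dx`) it
places no grid point exactly at midcell. A point exactly at midcell sees
the traveling concentration wave twice per cycle with equal amplitudes,
slips through the 5% peak-stability filter, and contaminates the period
estimate with half-periods; grid points merely *near* midcell alternate
by ~2.4–10% and are rejected by that filter.

**Time stepping.** Explicit forward Euler with `dt = 3.125e-5` s, far
inside the diffusive stability bound `dx²/(2 max D) = 1.25e-3` s. The
integrator refuses to run when the bound is violated, aborts with a
diagnostic when concentrations become non-finite, and warns when the
per-step concentration change exceeds 5% of the current global maximum
density (the per-step change of the reference runs peaks at ~1.8%).
Frames are stored every 0.15625 s = 5,000 steps, making the reported
periods exact multiples of the frame interval reachable. A
numba-compiled kernel is used when numba is importable; a vectorized
numpy stepper implements the identical arithmetic otherwise.

**Initial condition.** All MinD in the left half-cell, split equally
between the membrane pool `c_d` and cytosolic `c_DT`; MinE uniform.
Whether the cytosolic half starts ATP- or ADP-bound is immaterial for
anything measured after burn-in (nucleotide exchange equilibrates the
pools within ~1/k_ADP_ATP ≈ 1 s), and the left/right choice only fixes
the oscillation phase. The first 40 s are discarded as burn-in.

**Steady state.** The homogeneous steady state reduces, through the
stationarity identities, to a single mass-balance equation in `c_d`,
bracketed on `[0, ρ_D]` and solved with Brent's method; a dense-scan
oracle in the test suite confirms the physical root is unique for the
reference set and random parameter draws. Residuals are below 1e-9 in
all five components.

## Linear stability screening

Linearizing around the uniform steady state with a plane-wave
perturbation gives the 5×5 eigenvalue problem `A_q = A − D q²`. Under
no-flux boundaries the longest admissible wavelength is `2L`, i.e.
`q = π/L`. Two verdict modes are exposed:

- `strict`: the eigenvalue of largest real part at `q = π/L` has
  `Re > 0` **and** `Im ≠ 0` (|Im| > 1e-10·max(1, |Re|); floating-point
  eigenvalues are never exactly real). Ties between a real and a complex
  eigenvalue at equal real part break toward the complex pair.
- `hopf_turing` (used as screening filter F1): `Re > 0` at `q = π/L`
  (the domain mode grows — Turing-unstable in space) **and** the
  dispersion relation carries a growing oscillatory branch at some
  wavenumber (a complex leading eigenvalue with `Re > 0` — Hopf-unstable
  in time), scanned over `q` from 1e-3 to π/dx.

The two modes genuinely differ for the reference set: its instability at
`q = π/L` is a real growing mode (the full spectrum at L = 3.0 µm is
real), while its oscillatory unstable branch sits at small `q`
(≈0.07 ± 0.03i at q ≈ 0.2 µm⁻¹). Only the combined reading is
consistent with the reference set entering — and surviving — the
simulation funnel while the full nonlinear simulation plainly
oscillates. Steady states with negative components are classified stable
(unphysical).

## Oscillation metrics

**Period.** Per grid point, local temporal maxima of the normalized
membrane signal `I = (c_d + c_de)/max` within the 40–140-s window; a
point contributes only if consecutive peak amplitudes agree within 5%
(dampening filter). The package aggregates the per-point mean inter-peak
intervals by the **median** across points (the mean is available by
argument): points adjacent to midcell can pass the 5% filter while
seeing the wave twice per cycle, and the median is immune to these
half-period votes while at least half the points lie in the polar zones.

**λ_N.** The merged pole profile — the average of the left-pole peak
profile and the mirrored right-pole peak profile, each normalized to its
own maximum ("merged" is read as averaging; the halves differ by <0.02%
anyway, see below) — is fitted with `I(x) = a·exp(−λ_N·x) + c` on the
normalized length, restricted to the interval from the profile maximum
to the profile minimum. Profiles whose spatial peak-to-trough range is
below 1% of their mean are flat by convention: λ_N = 0 (short cells can
oscillate in time without a spatial gradient).

**I_Ratio.** `I(0.5)/I(0)` of the merged profile, linear interpolation
on the normalized grid; defined only when the spatial maximum alternates
between cell halves (otherwise NaN).

**Pattern classes.** From the run-length encoding of which half holds
the per-frame spatial maximum: `pole_to_pole` when ≥90% of complete
dwell intervals last 30–70% of the detected period; `late_onset` when
that criterion holds only on the trailing half of the window; `none`
when the signal is temporally flat (relative range <1e-3); `irregular`
otherwise. The 30–70% dwell band and the 90% tolerance were chosen
strict enough to reject one-sided and erratic oscillations while
accepting every clean simulated alternation in the suite.

**Pole-profile symmetry.** The profile at a left-pole temporal maximum
is compared with the mirrored profile at the subsequent right-pole
maximum. Peak times are refined to sub-frame precision by fitting a
parabola through the pole trace around the peak frame and evaluating all
grid points there by quadratic interpolation — at frame resolution alone
the ±0.078-s sampling offset contributes ~0.1% spurious asymmetry, an
order of magnitude above the genuine one (<0.004% for the reference set
at L = 3.0 µm).

**Biphasic λ_N(L).** Every admissible breakpoint is scanned; the left
segment is fitted by a least-squares line `aL + b`, the right by a
constant, and the split minimizing the total squared residual is
reported with the breakpoint at the segment intersection. A single
constant model is preferred when it fits as well as the best split.

## Screening funnel

Candidates draw `k_D, k_dD, k_dE, k_ADP_ATP = 10^N`, `N ~ Normal(0, 3)`
independently; `k_de` stays at 0.33 1/s and diffusion at the table
values. Filters: F1 linear instability (`hopf_turing`, at the 3.0-µm
reference length); F2 nonzero period at more than one simulated length;
F3 period ≥ 15 s and pole-to-pole pattern at both focus lengths (2.8 and
3.0 µm; AND across lengths); F4 1.2 ≤ λ_N ≤ 3 at both focus lengths
(AND). `count_semantics` chooses whether `n_sets` counts F1 survivors
(default, matching a funnel whose downstream fractions are relative to
the collected sets) or raw draws. Divergent simulations (explicit Euler
with extreme sampled rates) are caught and counted as failures.

At desk scale — 120 F1 survivors, four lengths (1.6/2.6/3.6/4.6 µm),
`dt = 6.25e-4` s (the detected reference period is identical at this
step to the full-resolution run), 100-s horizon — the F2|F1 fraction
measures 0.37–0.47 across five seeds. The full-scale reference point for
this fraction is ≈0.289; under a growth-only (Turing-only) F1 reading
the same proxy measures 0.14–0.17. The fraction is thus dominated by the
exact semantics of the linear filter, which the model description
underdetermines; the acceptance test asserts the deliberately broad band
[0.09, 0.60] and this note records the offset rather than hiding it.

## Profile analysis (measured-intensity side)

**Photobleach normalization.** Profiles are min-shifted to zero, then
per-frame totals are fitted to `a·exp(−bt)` and each profile is divided
by `exp(−b̂T_j)`, leaving corrected totals trend-free. The literal
transcription of the procedure multiplies by `exp(−b̂T_j)` — which
deepens a decay instead of removing it — and is kept behind
`printed_sign=True`; the default follows the stated purpose (decay
removal). This is recorded as a presumed sign typo in the source
procedure.

**Center fraction.** Intensities are interpolated at
`x = 0.5 ∓ 0.1 µm/L`, the midzone and total intensities are trapezoidal
integrals, and the fraction is the ratio of their means over the first
20 frames. Verified against a dense-grid quadrature oracle to <1e-4.

**Two-sided I_Ratio estimator.** Frame slopes at x = 0.2 and 0.8
(local linear regression over a ±0.05 window; width exposed as a
parameter) are 2-means-clustered into left/right-peaked groups with
deterministic extreme-point initialization; frames whose pooled slope
magnitude falls in the lowest quartile (transition frames) are dropped
(pooled rather than per-group; ties at the quartile boundary are kept so
clean synthetic series are not emptied). Each group is smoothed with
**Gaussian-kernel local linear regression** — locally linear rather than
locally constant because the pole maxima sit on the domain boundary,
where a locally constant smoother is biased low by ~1% and would corrupt
I_max; local linear is boundary-unbiased to first order. Bandwidth
defaults to twice the median position spacing (min 0.02), exposed as a
parameter. Each group is fitted with `d·exp(−λ|x − m|)` (m at the
smoothed argmax), the shared decay λ′ is the group-size-weighted mean,
amplitudes (only) are refitted with λ′ fixed, and I_min is the
intersection of the two refitted curves (closed form); no intersection
inside (0, 1) yields a flagged NaN. I_max is the maximum of the smoothed
curves. The estimator is exactly scale-invariant.

**Snapshot correction.** The normalized reference decay is fitted with
`a1·e^(−b1·k) + a2·e^(−b2·k)` (components ordered fast-first), totals
are divided by the fitted curve, and corrected totals are regressed
linearly on time within each cell's division bracket; population slopes
and intercepts are averaged. Intensity-to-molecule conversion pins the
fitted line to a calibration copy number at an anchor time and warns
when the anchor lies outside the fitted range.

## Synthetic data

The generators emulate the structure the analysis stages assume:
alternating-pole exponential gradients `a·e^(−λx) + c` (kymographs mix
the two poles sinusoidally; profile series switch discretely, mimicking
sampling well below the oscillation frequency), multiplicative
exponential photobleaching, linear per-cell growth under biexponential
snapshot bleaching, and additive Gaussian noise (matching the
least-squares assumptions of the fitting stages; Poisson/shot noise,
optics, and segmentation artifacts are *not* modeled, so recovery tests
certify the algorithms, not robustness to real microscopy pathologies).
Every generator returns a machine-readable truth record (period, λ_N,
closed-form I_Ratio `(a·e^(−λ/2) + c)/(a + c)`, bleach rate, growth
slope) consumed by the parameter-recovery tests. Seeds are mandatory and
runs are bit-reproducible.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the reference set at full
resolution (dt = 3.125e-5 s, 140 s, four lengths — 4.48 million steps
each) and the screening proxy at reduced resolution (120 survivors, four
lengths, dt = 6.25e-4 s, 100 s), sizes chosen so the whole suite
completes in minutes on one CPU while leaving every reported quantity at
the exact numerical conditions of the reference runs where it matters
(the period is unchanged between dt = 3.125e-5 and 6.25e-4 at the
reference set; the screen uses the coarser step, the headline period
regression the finer one).

## Known limitations

- One spatial dimension; no cell geometry, no membrane saturation, no
  MinC, no stochastic kinetics.
- The linear-screen semantics (strict vs combined Hopf+Turing) changes
  the funnel composition; both are exposed, the combined form is the
  default filter, and the funnel fraction is reported with that caveat.
- The period detector assumes peaks resolved on the frame grid (no
  sub-frame interpolation), so detected periods are near-multiples of
  the frame interval by construction.
- `fit_biphasic` models exactly one rising segment followed by one
  plateau; it does not test for other segment shapes.
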