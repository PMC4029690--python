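# Methods

## Model and assumptions

The skin at and around the three-electrode sensor is treated as a pure
resistance network; the low-amplitude, low-frequency excitation used for
such measurements (≈100 mV at 10 Hz) justifies neglecting capacitive and
reactive components, and electrode geometry is absorbed into the resistor
values rather than modelled. Seven elements describe one site: longitudinal
epidermal resistances `r_a, r_b, r_c` under electrodes A, B, C; subepidermal
links `r_1` (B–C) and `r_2` (A–B); lateral epidermal surface paths `r_3`
(B–C) and `r_4` (A–B). Units are kΩ throughout (kΩ⁻¹ for conductance):
human epidermal resistances sit naturally in this range, and no units are
imposed by the underlying algebra.

Each pairwise resistance is measured with the third electrode switched out
(SPDT switches in the instrument), so the unused electrode's longitudinal
branch carries no current. Under that condition the forward model

    R_AB = (r_a + r_2 + r_b) ∥ r_4
    R_BC = (r_b + r_1 + r_c) ∥ r_3
    R_AC = (r_a + r_2 + r_1 + r_c) ∥ (r_3 + r_4)

is the *exact* nodal analysis of the seven-resistor graph, which is what the
test suite verifies against an independently coded graph-Laplacian
effective-resistance solver (relative tolerance 1e-9). If the third
electrode were left connected, its branch would bridge the circuit and the
closed forms above would only be approximate; the switched-out reading is
both the physically correct model of the instrument and the mathematically
clean one.

The inversion `r_b ≈ (R_AB + R_BC − R_AC)/2` is exact in the series-sum
limit (lateral paths open) and biased low for finite lateral paths. The
bias for the reference network (100/50/80/20/30 kΩ) is −1.39 kΩ at
r_3 = r_4 = 10⁴ kΩ and shrinks monotonically with larger lateral
resistance; "lateral paths ≥ 100× the largest series sum" is used as the
package's testable proxy for "extremely large", at which point the bias is
under 5% of `r_b` for networks whose branch sums are of comparable
magnitude. For strongly asymmetric branch sums the residual bias is
dominated by a (branch-mismatch)²/lateral term instead, so the 5% bound is
not claimed there. Non-positive inversion results are *flagged*, never
raised: noisy field triples can violate the triangle-like constraint and
downstream reductions simply drop them (counted in `n_invalid`). "Infinite"
lateral resistance is an explicit `None` flag, not a large sentinel number.

## Extraction chemistry and calibration

The dilution mass balance `CB·x = k·CI·x = k·(V + x)·CS` assumes ideal
volume-additive mixing of ISF and buffer and a stable linear blood↔ISF
glucose relation (fasting or ≥2 h post-meal); `k` is a per-subject input
constant (default 1.0) — no estimation procedure for it is attempted.
The resistance→volume law `x = C1·G = C1/R` lumps pore geometry,
electrolyte properties and extraction time into `C1` (μL·kΩ), fixed by one
reference extraction via `C1 = x_cal·R_cal` with
`x_cal = k·V·CS/(CB − k·CS)`; calibration is infeasible (an error) when
`CB ≤ k·CS`. `C1` is scoped to one (subject, site, calibration event);
re-calibration is a user action. The prediction equation is the
mass-balance-consistent `CB = k·(1 + V·R/C1)·CS`. The high-dilution
approximation `CB ≈ k·V·CS/(P·t·A)` is provided with `k` included by
default and an `include_k=False` switch for formulations that absorb it;
its relative gap from the exact form is the algebraic identity `x/(V + x)`,
which the tests verify over a parameter grid.

Default extraction constants: `V = 50 μL`, `t = 10 min`,
`A = π·(10 mm/2)² = 0.785 cm²`, `k = 1`.

## Measurement protocols and the synthetic generator

Static mode takes one triple before and one after extraction and averages
the two inversions ("average" is read as the arithmetic mean); incomplete
skin recovery between the two readings is a multiplicative
`recovery_factor` on `r_b`. Dynamic mode samples at t = 2, 4, 6, 8, 10 min
(five samples at 2-min intervals within the 10-min extraction; the first
sample time is a package convention, recorded in the config) and averages
the valid inversions. Within-extraction drift — electrolyte under the disc
electrode infiltrating the epidermis — is modelled as single-exponential
relaxation `r_floor + (r_start − r_floor)·e^(−t/τ)`: the simplest monotone
form with an asymptote consistent with the qualitative "fast decrease" the
protocol exhibits. Electrode type (ECG disc vs Ag/AgCl in electrolyte)
is represented only through different drift presets, not circuit changes.
Measurement noise is multiplicative lognormal per pairwise value
(`exp(σ·z)`, median 1): resistances are positive and errors scale with
magnitude. A 3-MAD screen over replicate reduced values
(`flag_gross_errors`) is available for gross-error rejection; the criterion
is the package's own.

The cohort generator defines the study conditions: true blood glucose
uniform on 4–10 mmol/L (normal-to-hyperglycaemic fasting range), site
resistance lognormal with median 100 kΩ and log-sd 0.25, `C1 = 500 μL·kΩ`
(so the median extraction yields 5 μL into 50 μL of buffer — a realistic
~1:10 dilution), base network 100/100/100/20/20 kΩ with lateral paths open,
drift preset (200, 50, 3 min), and σ_rel = 0.05 for noisy cohorts. In
dynamic mode the drift curve is rescaled per session so its noiseless
five-sample mean equals the session's drawn resistance, keeping the ground
truth `x = C1/r_b` consistent across modes. Everything is deterministic
given the seed.

What the generator does *not* emulate: contact-resistance drift, humidity
and temperature effects on the skin state, day-to-day physiological skin
recovery, sweat or movement confounders, and capacitive skin behaviour.
Passing tests therefore demonstrate the correctness and noise behaviour of
the estimation chain under the stated measurement model, not clinical
accuracy on real skin.

## Validation statistics

Linearity is checked by OLS of the diluted-sample glucose `CS` on
conductance per unit area `G/A` with an intercept (the through-origin
prediction stays observable as "fitted intercept ≈ 0") and Pearson's r as
the correlation measure; no p-values are reported. On noiseless synthetic
cohorts at constant blood glucose r exceeds 0.999 — not exactly 1, because
`CS = CI·x/(V + x)` is slightly concave in `G` over the physiological
resistance range.

The error budget propagates three noise sources — resistance measurement,
diluted-sample assay, and the calibration meter reading — through a
(calibration, prediction)-pair Monte Carlo to the median relative glucose
error. One set of standard-normal draws is shared across the noise grid
(common random numbers), which makes the error surface monotone in each
axis per replicate and exactly reproducible per seed. At small noise the
Monte-Carlo error agrees with the first-order linearisation
(relative error ≈ f·σ·(z₁ − z₂), f = (V·R/C1)/(1 + V·R/C1)) within 25%,
which the suite checks against an independently coded delta-method sample.

## Problem sizes and numerical choices

The suite and the acceptance script use 1000 random networks for the
exactness and oracle checks, 100-session noiseless and 1000-session noisy
cohorts for end-to-end recovery, 200-session cohorts for linearity, and a
10-replicate brute-force oracle of the full noisy experiment; these sizes
give Monte-Carlo bands far narrower than the effects being measured while
keeping a full run in seconds. Tolerances: machine-precision identities are
asserted at 1e-10…1e-12 relative; the network-model/oracle agreement at
1e-9 relative (Laplacian pseudoinverse conditioning); stochastic
comparisons at the Monte-Carlo spread of the independent oracle. CSV floats
are written at 12 significant digits, which round-trips the pipeline's
quantities to well below every asserted tolerance.

## Known limitations

Single-frequency pure-resistance model only; no electrode-polarisation
electrochemistry; no blood↔ISF glucose lag dynamics; `k` supplied, not
estimated; dynamic-mode drift form is a modelling choice, not measured
physics; the generator's parameter ranges are plausible for permeabilised
forearm skin but are conventions, not fitted to data.
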