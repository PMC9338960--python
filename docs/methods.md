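# Methods

This note documents the models, conventions and numerical choices
behind `lumiplate`, and what its tests do and do not demonstrate.

## Geometry

The LED matrix is 32 rows × 64 columns at a 3 mm pitch (active area
192 × 96 mm), indexed 0-based and row-major from the top-left corner;
physical coordinates are millimetres from the same corner, so LED
(row, col) has its centre at (3·col + 1.5, 3·row + 1.5) mm. Wells are
addressed letter + 1-based number, with "A2" and "A02" equivalent.

**Default placement.** Plates are corner-aligned: the nominal centre of
well A1 is half a well diameter from the matrix corner, snapped to the
nearest point whose coordinates are both multiples of the 3 mm pitch
(the midpoint of a 2 × 2 LED cell). For the 96-well format this puts A1
at (3, 3) mm and, because the 9 mm well pitch is a multiple of the LED
pitch, centres a 2 × 2 LED block in every well. The 6.38 mm well then
overhangs the matrix edge by 0.19 mm, which is accepted since no
assigned LED is lost.

**Per-well snapping.** 6/12/24/48-well pitches are not multiples of
3 mm, so each well centre is independently snapped to the nearest
2 × 2-cell midpoint (displacement ≤ 1.5 mm per axis; ties broken by
round-half-to-even, though no registry entry produces a tie). Snapping
makes all wells of a format resolve to congruent LED patterns, which is
how the hardware is used in practice; a `rigid` mode keeps nominal
centres for physical-fidelity studies.

**Inclusion rule.** A well's LED set contains every LED whose centre
lies strictly within the well radius of the snapped centre, compared on
exact squared distances (the closest registry case is 292.5 vs
302.76 mm², far from needing an epsilon). With the 34.8 mm 6-well
diameter this yields exactly 112 LEDs per well (4 × 28 lattice points
by quadrant symmetry), and 4 LEDs per 96-well well. The 34.8 mm
diameter, like the other non-96-well registry entries, follows common
ANSI/SLAS catalogue dimensions and is overridable through a YAML
registry; only the 96-well entry (9 mm pitch, 6.38 mm diameter) is
anchored to the device characterization.

## Program dialect

Headers are fixed as `target,start,duration,red,green,blue,repeats,
interval,message,buzzer`; both `,` and `;` separate fields
(spreadsheet-locale tolerance), `#` starts comments and `#!` carries
metadata directives. Times are integer seconds or `HH:MM:SS`;
sub-second values are rejected rather than rounded, because silent
rounding would distort dose accounting, and durations under the 1 s
firmware minimum are a dedicated error. The `repeats` column is either
a pulse count or, when written as a time, the absolute end of the loop:
pulse k starts at `start + k·interval` for every k with
`start + k·interval < end` (equivalently ceil((end − start)/interval)
pulses). This end-exclusive convention makes "every 5 min until 1 h"
fire 12 pulses and the same loop started at 30 min fire 6, the natural
reading of the worked example the dialect is modelled on.

The rectangle (`Rec_A1_D4`), circle (`Cir_x_y_r`, mm) and explicit-LED
(`LED_row_col`, joined with `+`) spellings are this package's own
documented syntax; original-firmware csv headers are not published in
the source material, so portability to any particular firmware is not
claimed.

Self-overlapping repeats (interval < duration) are reported by
`validate_program` as a finding rather than raised at parse time, so a
whole program can be checked in one pass; the compiler handles them
safely regardless (see below).

## Scheduling

Timelines are sparse maps second → 32 × 64 × 3 uint8 grid, an absent
second meaning all-off, at a fixed 1 Hz resolution mirroring the 1 s
minimum pulse. Event intervals are half-open [t_on, t_off): a 3 s
pulse lights exactly 3 frames. Conflicting commands combine per LED
and channel by **maximum** — idempotent and order-independent, and
unlike additive blending it can neither exceed the 255 hardware ceiling
nor fabricate dose. Whether real firmwares overwrite, add or clamp is
undocumented, so this is a declared dialect choice.

Reverse schedules ("fix everything at once") place well k's pulse at
`fixation_horizon − time_point_k`; the fixation horizon is stored on
the program (and serialized as a `#!` directive) because it generally
lies after the last off-time.

Messages show on the control unit at their command's start, tick once
per second for the command's duration, and the buzzer (when flagged)
sounds at the deadline — the source material describes countdowns
without defining them, so these semantics are ours.

## Optics

A single-exponent generalized-Lambertian point emitter is the simplest
model consistent with the empirically characterized "cone of light":
E(r, h) = S·h^(m+1)/(r² + h²)^((m+3)/2), with S set so one
full-intensity blue LED gives 135 µW/cm² on axis at the 2 mm
calibration height (the measurement geometry of that power density is
not published; treating it as the 2 mm on-axis value is a documented,
configurable choice). The total flux through any plane is 2πS/(m+1),
independent of h, which the tests verify as an energy-conservation
property. Only the blue channel carries a default calibration; other
channels must be calibrated before physical units are reported.

Homogeneity is V = 1 − min(edge)/centre over a well footprint (the
alternative global max-vs-min reading of "maximum variation" is
ambiguous in the source; centre-vs-edge-minimum is implemented and
documented). Fields are integrated by grid summation at 0.25 mm
default resolution; per-well dose uses well-local grids (default
0.5 mm) so the sharply peaked near field at small h is resolved without
a plate-wide fine grid. Dose integrates *all* received light, so a
neighbouring well accrues spillover dose while `lit_seconds` counts
only seconds in which the well's own LEDs are driven.

**Calibration and the 25 % figure.** `calibrate_emission` fits m by
bisection so an isolated 2 × 2 block centred in a well reproduces a
target V (tolerance 1e-3, m ∈ [0, 200]; V is increasing in m). The
characteristic measured value for a 96-well well at 2 mm is V ≈ 0.25
and is kept as the default target, but it is **not reachable at 2 mm
under this emitter model**: even an isotropic point source (m = 0)
gives V ≈ 0.47 for an isolated 2 × 2 block at that height, and larger m
only concentrates the beam further. The physical emitters are
evidently broader than any cos^m point source (extended dies, package
optics, diffusion), which this model deliberately does not include.
The calibration therefore raises a clear error for unreachable targets
instead of clipping; the same 25 % target is reachable at h ≳ 5.5 mm,
and planted-exponent recovery (m* ∈ {0.5, 1, 2, 5} recovered within
0.1 % from their V values) shows the fit itself is sound. Downstream
quantities that depend on the absolute beam shape at 2 mm (V, spillover
percentages) should be read as model predictions, not device
measurements.

## Thermal

ΔT(t) = gain · duty · (1 − e^(−t/τ)) is the simplest form consistent
with the qualitative observation that heating grows with stimulation
frequency/length and plateaus after about an hour; τ defaults to
1200 s (≥95 % saturated at 3600 s). No plateau magnitude is published,
so `gain_K` has no hardware-anchored default and the module is an
order-of-magnitude schedule-screening estimate, not a heat-transfer
simulation.

## Synthetic programs and presets

`random_program` draws valid programs (well/row/column targets, 1–30 s
durations, starts ≤ 600 s, ≤ 4 repeats with non-overlapping intervals)
for property testing; it is deterministic per seed. The packaged
presets encode the main published stimulation schedules at their
printed parameters: the phase-shifted 3 s/5 min/1 h pulse-train pair,
the 12-point × 2-min staggered-fixation design (10 s pulse), the 2 s
single-pulse 1-min fixation ladder (12 points chosen as a
representative ladder length; the full multi-well layouts of the
original screens are not reproduced), and the 84-min high- (every
2 min, 42 pulses) and low-frequency (every 20 min, 5 pulses) 10 s
trains. The 84-min horizon is treated end-exclusively, so no pulse
fires at t = 84 min.

What passing tests show: the coordinate mapping, loop conventions,
compiler and dose bookkeeping are exact and internally consistent, and
the optics obeys superposition, symmetry, flux conservation and the
homogeneity/spillover trade-off. What they do not show: agreement of
absolute irradiance or uniformity with any physical device beyond the
single calibrated on-axis point, or any biological outcome.

## Problem sizes

The test suite compiles hundreds of randomized programs with horizons
of a few hundred seconds and verifies them against a brute-force
per-second simulator; optics property scans sample heights 1–20 mm at
0.5 mm grid resolution. These sizes keep the full suite around five
seconds while exercising every code path; all quantities scale
linearly with horizon and grid density.
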