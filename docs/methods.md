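# Methods

`msicd` models the death of adherent breast-cancer cells (BT-474,
MDA-MB-231) under oscillating mechanical compression: a platen cyclically
compresses a gel-overlaid monolayer, the dissipated viscoelastic energy
damages cells, and the damage is read out as caspase-3/7 (apoptosis) and
propidium-iodide (PI, necrosis) positivity. The package chains five stages —
loading mechanics, stress/strain geometry, viscoelastic energy dissipation, a
generative damage model, and a seeded synthetic-experiment simulator — and
closes the loop with rate/trend analysis and maximum-likelihood parameter
recovery.

## Loading waveform

The commanded platen displacement is

    u(t) = (1 − e^(−t/τ1)) · (α/2)(1 − cos 2πft) + β(1 − e^(−t/τ2)),

with α the peak-to-peak oscillation amplitude (µm), f the frequency (Hz), τ1
the ramp-up constant (s), and β an extra compressive offset (time constant
τ2) that keeps the contact force strictly positive. This expression is a
**reconstruction**: the published account gives the parameter list and the
contract (ramp-up without overshoot, steady peak-to-peak α, u ≥ 0, F > 0) but
not the closed form, and this is the simplest form satisfying all of it. The
steady state is defined as t > 5·max(τ1, τ2); amplitudes are measured on that
window. Default sampling is 100 samples per cycle, capped at 10 kHz, which
resolves the extrema to well under 1 % amplitude error; anything below 20
samples per cycle is rejected.

Force follows from a linear contact model F = preload + k·u with
preload = 0.2 N. The stiffness k is the through-origin least-squares slope of
the four measured (α, ΔF) pairs (40, 4.7), (70, 8.6), (100, 11.8),
(130, 17.2) (µm, N), giving k = 0.1259 N/µm. The pairs are mildly nonlinear
(pointwise slopes 0.1175–0.1323 N/µm), so a single k cannot reproduce all
four ΔF at once; the residual is surfaced in the tests rather than hidden
behind a higher-order fit, since nothing distinguishes gel nonlinearity from
measurement scatter in four points.

## Stress, strain and dish geometry

Nominal stress is force amplitude over the full platen face,
σ = ΔF / (π(d/2)²) with d = 34.2 mm. This reproduces the published
conversions 4.7 N → 5.1 kPa, 17.2 N → 18.7 kPa and the range
3.6–19.5 N → 3.9–21.2 kPa at one-decimal rounding; 8.6 N and 11.8 N convert
to 9.4 and 12.8 kPa where 9.3 and 12.9 were reported — a last-digit
disagreement the package flags but does not force.

Strain amplitude is referenced to the only printed compliant-layer thickness,
the 2 mm agarose overlay: ε0 = α / h with h = 2 mm (configurable). The strain
datum is otherwise undefined in the source; this choice makes ε0
dimensionless and reproducible.

The dish (radius 17.1 mm) splits at r = 10 mm into a center and a peripheral
region; the boundary radius itself is peripheral (closed outer interval,
following the body-text convention). Peripheral cells are hypothesized to see
shear on top of compression; the package carries that as a single linear
amplification factor A(r) = 1 + κ·(r − 10)/(17.1 − 10) for r > 10 mm, A = 1
in the center. No contact-pressure distribution or finite-element model is
attempted. An optional frequency derating of applied stress (linear in log f
between 0.1 Hz and 30 Hz, matching the observed 0.8 → 0.5 kPa actuator lag)
is provided but off by default.

## Viscoelastic energy dissipation

Cells are idealized as a generalized Maxwell (Prony-series) solid,
G(t) = G∞ + Σ wᵢ e^(−t/τᵢ), whose dynamic modulus is G*(ω) = (iω)·Ḡ(iω):
G1 = G∞ + Σ wᵢ(ωτᵢ)²/(1+(ωτᵢ)²), G2 = Σ wᵢωτᵢ/(1+(ωτᵢ)²). Under sinusoidal
strain the energy dissipated per cycle and unit volume is the hysteresis-loop
area Δw = π·ε0²·|G*|·sin δ = π·ε0²·G2, and the run total is W = Δw·f·t —
linear in duration, quadratic in strain amplitude. The published account
attaches sin δ to the per-cycle loss but tan δ to the frequency term of W;
both readings live behind a `variant` flag (`loss-modulus`, the physically
exact default, and `paper-tan-delta` for compatibility with that frequency
analysis). A brute-force oracle integrates σ(t)·ε̇(t) over steady-state
cycles with `scipy.integrate.quad` and agrees with the closed form to better
than 1e−6 relative error; the tests keep the two routes independent.

The default model (G0 = 2 kPa, G∞ = 1 kPa, τ = 1 s, single branch) is a
calibration placeholder in the soft-cell rheology range, not a measured
rheogram. For any single-branch model the frequency term f·G2 rises
monotonically to the plateau w/(2πτ); the supplementary analysis the study
cites places an interior maximum at f = 0.21 Hz, but the model and parameters
behind that figure are not available in the provided text, and no
single-branch Prony model can produce an interior maximum of f·G2. The
package therefore documents the plateau behaviour it can verify analytically
and leaves the 0.21 Hz feature untargeted; multi-branch models are supported
should a calibrated spectrum become available.

## Damage model

The effective energy a cell at radius r experienced is
w_eff = min(W·A(r), detach), where `detach` is a per-line ceiling encoding
that loosely attached cells detach before damage accumulates to a lethal
level (MDA-MB-231 detaches far more easily than BT-474). Outcome
probabilities are then

* necrosis: p_nec = bg_nec + (1 − bg_nec)(1 − exp(−(w_eff/w_nec)^h)) — a
  Hill-saturating, strictly increasing dose response (hence force- and
  time-dependent, since W is increasing in both);
* total apoptosis: p_apo = bg_apo + a_max(1 − p_nec)·x·e^(1−x) with
  x = w_eff/w_apo — a unimodal bump whose intrinsic mode sits at w_apo
  (the (1 − p_nec) competition factor shifts the realized mode below w_apo
  when the two scales are comparable, which the defaults accept);
* the apoptotic fraction splits into early (caspase-only) and late
  (double-positive) by a logistic in log w_eff, non-decreasing in energy;
* survivors: p_none = 1 − p_nec − p_apo. Necrosis is assigned first and
  apoptosis drawn from the survivors, so the four probabilities sum to 1 by
  construction.

"Late apoptosis" is operationalized as caspase⁺/PI⁺ double positivity — the
natural reading of the two-probe scheme, though never defined explicitly in
the source.

### Default calibration

The defaults were calibrated once against the printed qualitative anchors and
frozen; they are calibration values, never measurements:

| parameter | default | anchor |
|---|---|---|
| w_nec | 45 J/m³ | with h_nec, puts necrosis at ~91 % for α = 40 µm, t = 300 s (center), matching ">90 % by 300 s" |
| h_nec | 3 | leaves α = 40 µm, t = 210 s at ~56 %, so the dose response is visible rather than saturated |
| w_apo | 40 J/m³ | places the apoptosis peak at the mildest loaded condition |
| a_max | 0.25 | peak observed apoptosis ≈ 11 % after necrosis competition, near the reported 12.7 % maximum |
| late_w_half, late_slope | 50 J/m³, 1.5 | late apoptosis common at harsh energies, rare at mild ones |
| κ | 2 | peripheral necrosis visibly above center at sub-saturating doses |
| bg_apo, bg_nec | 0.001, 0.004 | mid the printed control bands 0–0.2 % and 0–0.9 % |
| detach BT-474 / MDA-MB-231 | 3000 / 120 J/m³ | BT-474 accumulates lethal damage at long duration; MDA-MB-231 plateaus |

At the default energies (Experiment 1 spans W ≈ 42–634 J/m³, Experiment 2
W ≈ 0.1–1.1 J/m³), Experiment 2 sits far below w_nec, so its necrosis is
essentially background — the frequency-flat regime — while its apoptosis is
an order of magnitude above control, echoing the reported mild-condition
behaviour. One reported contrast is *not* representable under these forms:
"more late apoptosis in MDA-MB-231 than BT-474" at mild conditions would
need a line-dependent late fraction, but the detachment ceilings only bite at
harsh-condition energies; this is a known limitation, not a target.

## Synthetic experiments

`experiment_design` enumerates the two study designs: Experiment 1 (2 lines ×
α ∈ {40, 70, 100, 130} µm × t ∈ {210, 300} s at f = 30 Hz × 3 replicates =
48 loaded dishes) and Experiment 2 (2 × f ∈ {0.1, 1, 5, 10, 30} Hz ×
t ∈ {30, 60, 90} s at α = 10 µm × 3 = 90), each plus 3 DMEM and 3 gel-overlay
(w/o MS) control dishes per line. `simulate_dish` scatters cells uniformly in
area (the simplest null for the radial analysis; ~66 % of cells land in the
peripheral annulus), computes W through the mechanics/viscoelastic chain, and
draws one categorical outcome per cell. The default census is 4000 cells per
dish — order of a confocal-field count at the printed seeding density of
2.0×10⁴ cells/cm², roughly 2000 per region readout; the study never reports
counted cells per dish, so this is a declared convention. Each dish owns an
RNG stream derived from (master seed, CRC-32 of the condition key), so any
subset of dishes reruns bit-for-bit identically.

What the generator deliberately omits: spatial correlation between
neighbouring cells, dish-to-dish biological variability beyond sampling
noise, imaging/segmentation error, actuator dynamics, and any immunological
sequelae of necrosis. Passing tests therefore demonstrate internal
consistency of the model chain and the analysis code, not fidelity to any
particular wet-lab dataset.

## Analysis

Rates follow the assay arithmetic (per-row percentages of caspase⁺, PI⁺ and
double-positive cells); summaries are mean ± sample s.d. (n−1) over
replicates, with a single replicate reported as value ± missing. The radial
profile bins per-cell records (default 1 mm bins), drops empty bins, and
correlates bin PI⁺ rate with mid-radius — Pearson by default (the source says
only "correlation test"), Spearman behind a flag; zero-variance or
single-bin profiles are reported as not computable rather than NaN.

Trend verdicts are taken at the whole-design level: necrosis means are
averaged over every other design dimension within each level of the factor
under test, and the slack is the pooled replicate s.d. across loaded
conditions. Force/time monotonicity allows one pooled s.d. of slack per
step; frequency flatness requires the level means to span at most two pooled
s.d. Pooling is deliberate — per-slice triplicate s.d. estimates are far too
noisy to gate a boolean on, and the headlines being checked are
design-level claims.

Parameter recovery maximizes the multinomial likelihood of the four
mutually exclusive stain categories (none / caspase-only / double / PI-only —
the only partition consistent with the stored counts) over any subset of
(w_nec, h_nec, w_apo, a_max, κ), the rest held at their initialization.
Region rows average the model over a 16-node Gauss–Legendre quadrature
uniform in r², making the likelihood exactly consistent with the simulator.
Positive parameters are optimized in log space, a_max in logit space, with
L-BFGS-B; non-convergence is reported in the diagnostics, never silently. At
the default scale (3 replicates, ~2000 cells per region) each free parameter
is typically recovered within a few percent; w_apo is the weakest-identified
(apoptosis counts are small once necrosis competes) and occasionally
approaches 15 % relative error. A two-way ANOVA via statsmodels is offered
as labelled convenience output only.

## Problem sizes

Default runs are desk-scale by design: 4000 cells per dish (60 dishes for
Experiment 1, 102 for Experiment 2), 10 000 cells for control-calibration
dishes, 20 seeds for Monte-Carlo checks of the radial correlation and
control bands. The complete pipeline, including the maximum-likelihood
refit, runs in a few seconds.
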