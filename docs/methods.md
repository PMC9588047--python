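# Methods

## Model overview

`dfvwm` simulates delayed color estimation with dynamic neural fields
(DNFs): continuous populations of feature-tuned units whose activation
u(x, t) over a circular feature dimension x evolves as

    tau * du/dt = -u + h + s(x,t) + \int k(x - x') g(u(x')) dx' + q xi(x,t)

with resting level h < 0, external input s, logistic output
g(u) = 1/(1 + exp(-beta u)), an interaction kernel k given by a
difference of Gaussians (local self-excitation, broader surround
inhibition, optionally a constant global-inhibition offset), and
Gaussian white noise of amplitude q. Peaks of supra-threshold activation
are the unit of representation; with sufficiently strong self-excitation
a peak survives removal of its input and acts as a working-memory trace.

Two architectures are provided.

**Model 1 (parallel encoding).** A 2D color-space sensory field (CS)
drives a feature pathway over hue: feature attention (FA), feature
contrast (FC), a shared inhibitory field (Inhib) and feature working
memory (FWM). FC and FWM are reciprocally coupled to Inhib; this
three-layer core stores multiple self-sustained hue peaks. Inhibitory
feedback from Inhib into FC suppresses already-stored hues, making FC a
novelty detector. All display items are encoded in parallel.

**Model 2 (scene-level, sequential).** Adds a spatial attention field
(SA) and an inhibition-of-return field (IOR) over polar angle, a
scene-level attention field (SLA) over hue, and two scalar dynamic
nodes: a peak detector (PD) driven by total supra-threshold SLA output,
and a condition-of-satisfaction node (CoS) driven by the PD. FA and SA
run in a winner-takes-all regime (strong global inhibition); SLA
requires the conjunction of working-memory and attention input. When
the attended item's memory peak forms, SLA crosses threshold, PD then
CoS activate, CoS charges IOR at the attended location and transiently
suppresses all three attention fields, and the next novel item is
selected. This cycle yields autonomous sequential consolidation.

## Why the behavioral signatures emerge

* **Repulsion of similar colors.** Two memory peaks 20 deg apart share
  surround inhibition; the inhibition is deeper between the peaks than
  on their outer flanks, so each peak climbs its local activation
  gradient away from the other during the delay. Peaks ~170 deg apart
  share no surround and do not move.
* **Delay dependence.** While the stimulus is on, its localized input
  pins each peak near the true hue; repulsion accrues only after input
  offset. The control condition (wheel overlapping the final 300 ms of
  the display) therefore shows only a small residual bias.
* **Lower precision for close colors.** The same inhibition gradient
  that produces the mean shift also amplifies trial-to-trial variance
  in peak position.
* **Guessing.** A trial is scored as a guess when no stable
  supra-threshold response peak forms on the wheel before the deadline
  (the model must "click" somewhere, so a uniform random report is
  recorded); this happens when the cued item's memory peak failed to
  consolidate or died during the delay.
* **Unique item consolidated last (Model 2).** The close pair's sensory
  inputs to FA overlap in hue, pushing that region of color space
  closer to threshold, so attention tends to select the close colors
  first.

## Trial flow and readout

Fixation (500 ms), sample (800 ms, one or three 2D Gaussian inputs into
CS), delay (1000 ms; absent in the control condition where the wheel
appears 500 ms into the sample and overlaps it for 300 ms with the
uncued inputs attenuated by 0.5), then test. At test the color wheel
enters CS as a sub-threshold diagonal ridge (hue = wheel(angle), with
per-trial rotation and mirroring), the cued item is boosted — Model 1:
a flat 40-deg window (amplitude 2.5) on FWM plus the same window
(amplitude 1.5) on FA, flat so that it selects the cued item without
shifting the reported position; Model 2: a flat window (amplitude 3.0)
on SLA — and FA's resting level is raised. The FA winner projects a hue
ridge into CS; a response peak forms at the intersection of that ridge
with the wheel. The readout takes the strongest CS peak lying on the
wheel (within 12 deg of the diagonal), requires it to hold position
within 6 deg for 50 ms, refines its polar angle by a circular centroid,
and maps angle to hue through the wheel. No stable peak within 2000 ms
of test onset scores as a uniform guess.

Model 1's cue pathway includes an FWM -> FA projection (gated to the
test phase) carrying the cued item's hue into attention; Model 2 routes
the same information through SLA. During Model 2's sample phase the
memory field's resting level is held 2.5 units lower (a resting-level
gate), so consolidation requires the attended item's combined
feature-contrast and attention drive; this is what makes encoding
sequential rather than parallel. The PD -> CoS link is gated off during
the test phase so attention stays engaged while the response forms.

## Parameters

All amplitudes are per-degree weights (convolutions multiply by the
grid spacing), so tuned values are resolution-invariant. Key defaults
(full set in `dfvwm/params.py`, YAML-dumpable for provenance):

| quantity | value | role |
|---|---|---|
| beta (all sigmoids) | 4 | soft threshold at u = 0 |
| tau (fields) | 20 ms (Inhib 10 ms, IOR 50 ms) | relaxation time |
| dt | 2 ms | Euler-Maruyama step |
| FWM kernel | c_exc 1.35, sigma 4 deg | self-sustaining peaks |
| FWM <- Inhib | gain -28, smoothing sigma 12 deg | surround inhibition |
| Inhib <- FWM | gain 8, sigma 10 deg | drives shared inhibition |
| FWM noise q | 0.45 | delay-period diffusion (recall s.d.) |
| stimulus | amplitude 8, sigma 5 x 4 deg | supra-threshold input |
| wheel ridge | amplitude 3 (sub-threshold), sigma 5 deg | response substrate |
| cue window | 40 deg flat | partial overlap of a close neighbor |

The grid presets are `default` (2 deg/site, matching the task's
2-deg color lattice) and `fast` (3 deg/site) used for batch
simulations; the grid-refinement tests bound the discretization error
of a noise-free equilibrium peak position at < 0.5 deg.

Noise enters as i.i.d. Gaussian increments per site scaled by sqrt(dt)
(Euler-Maruyama); a spatially smoothed noise variant was considered and
not adopted — the white-noise reading of the field equation is the
simplest and suffices for the targeted behavior.

## Statistical analysis

Recall errors are fit by maximum likelihood with the standard circular
mixture model (with bias): (1-P_u) VM(e; mu, kappa) + P_u/360, where VM
is the von Mises density per degree and kappa maps to circular s.d. via
sd = sqrt(-2 ln(I1/I0)). Fitting uses a multi-start grid
(mu in {-20,0,20}, sd in {10,25,50}, P_u in {0.05,0.3}) with bounded
L-BFGS-B, deterministic for a given sample. The s.d. is bounded at
100 deg (a broader von Mises is operationally indistinguishable from
the uniform component), and a fit whose s.d. lands on that bound is
kept only if its likelihood gain over the pure-uniform model justifies
the three extra parameters (AIC); otherwise the sample is reported as
pure guessing. This guards the P_m estimate against the
boundary-degenerate solution on (near-)uniform data. The three-component swap
variant adds a von Mises on each non-probed item's offset (shared s.d.
and bias) and nests the standard model at p_nontarget = 0.

Simulation experiments run the full trial design (delay: 160 SS1 + 640
SS3; control: 640 SS3) across 12 independent seeded runs ("simulated
participants"), fit each run per condition, and average. Model
comparison uses per-parameter RMSE against reference values and
AIC = N ln(MSE) + 2k with N = 12 (4 conditions x 3 measures) and
k = 49 (Model 1) / 56 (Model 2) free parameters, natural logarithm
(the base-10 variant does not reproduce the published totals).

## Problem sizes used by the test suite and acceptance script

The statistical checks run at reduced scale: one run of 20–30 trials
per probed condition on the `fast` grid, enough for stable sign and
ordering statistics (a mean bias of ~6 deg with trial s.d. ~8 deg has a
standard error under 1.5 deg at n = 30). Mixture-model recovery runs
the full 100 replicates of n = 320. The full design (12 x 800 trials)
is available through `dfvwm reproduce` / `run_simulated_participants`.

## What the generator does and does not emulate

Simulated observers differ from human participants in known ways: the
model's recall s.d. is lower than human s.d. (as in the reported
simulations), peak failures are rarer (P_m nearer 1.0 than the reported
0.92 for close colors in the parallel variant), and no perceptual or
categorical color-space anisotropies exist (hue is metrically uniform).
Passing tests therefore certify the mechanism — delay-dependent,
similarity-driven repulsion with set-size- and similarity-dependent
precision — not a quantitative account of any individual human data
set.

## Numerical choices and degenerate inputs

Fixed-step Euler(-Maruyama) with dt = 2 ms (dt >= tau raises); FFT
circular convolution for the 2D field and dense circulant matrices for
the small 1D fields (equal to the brute-force double loop to < 1e-8);
peak locations by three-point parabolic interpolation, ties broken by
lowest site index; degenerate mixture samples (all-identical errors)
return a boundary fit with a warning and `converged=False`; mixture
fits require n >= 20 responses, and conditions below that are excluded
with a warning.

## Known limitations

* Parameters were hand-tuned to the reported behavioral pattern; no
  automated fitting is provided.
* Recall dispersion is lower than in the reported simulations (mean
  circular s.d. ~7 deg vs ~12-16 deg): the noise level that would close
  the gap makes the resting memory field ignite spontaneous (phantom)
  peaks, so the quieter regime is kept.
* The winner-takes-all ties in Model 2 are broken by noise; noise-free
  symmetric displays can deadlock (a measure-zero configuration).
* The control condition's close-pair biases show a small attraction
  (~1-3 deg toward the neighbor) from overlapping sensory inputs,
  slightly larger than the reported near-zero control biases.
* Model 2's unique-item storage probability exceeds the reported 0.84
  at the default (robust-encoding) operating point.
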