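# Methods

## The model

`israpop` implements a multi-scale kinetic model of how the integrated
stress response (ISR) couples to the intrinsic apoptosis pathway in
venetoclax-resistant AML cells, and of how that coupling shapes the
response to venetoclax (a BH3-mimetic Bcl-2 inhibitor), tedizolid (an
oxazolidinone that inhibits mitochondrial translation and triggers the
ISR), and their combination.

The dynamical state has 28 components (concentrations in nM, time in
hours, cell counts dimensionless):

* **Drug pools.** Each drug has an extracellular pool with first-order
  decay and a first-order uptake flux into an intracellular pool, which
  decays first order.  The subsystem is linear and autonomous, so the
  intracellular concentration after a dose D at time t_k has the closed
  form D·k_up/(a−b)·(e^(−b·s) − e^(−a·s)), s = t − t_k, with
  a = k_up + k_dec,ext and b = k_dec,int.
* **Transcription factors.** c-Myc and Chop have basal production and
  first-order degradation; intracellular drug modulates production through
  Hill terms evaluated at a delayed time t − τ (per-edge delays of order
  hours represent transport and transcription lags).  Both signs occur
  across the drug→TF edge set.  Chop carries an additional superadditive
  product term (amplitude `chop_syn_amp`) so that either monotherapy
  produces a transient Chop rise that decays with the intracellular drug,
  while the combination produces a heightened and more sustained rise.
* **Bcl-2 family network.** Synthesis of Bcl-2, Mcl-1, Bim, Bax and Bak is
  regulated by c-Myc and Chop through per-edge Hill functions with a
  unique (K, n) pair per edge.  Activating edges multiply the basal rate
  by (1 + amp·h(x)), inhibiting edges by (1 − amp·h(x)) with amp < 1, so
  rates stay positive and the factor is exactly 1 with both factors at
  zero.  The c-Myc edge ordering is hormetic by construction: the
  pro-survival edges (c-Myc→Bcl-2 up, c-Myc→Mcl-1 up) half-saturate at
  lower c-Myc than the pro-apoptotic edges (c-Myc→Bim/Bax/Bak up,
  c-Myc→Bcl-2 down), so the normalized net pro-survival balance rises
  through a "cancer zone" of intermediate c-Myc and falls in an
  "apoptosis zone" at high c-Myc, changing slope sign exactly once.  The
  ordering is kept as a soft-bound calibration prior, not a hard-coded
  cutoff.  Chop up-regulates Bim and Bak and represses Mcl-1 strongly;
  its Bax-up and Bcl-2-down edges exist but are weak at the nominal set.
* **Mass action.** Free species bind reversibly: {Bcl-2, Mcl-1} ×
  {Bim, active Bax, active Bak}, Bim × {inactive Bax, inactive Bak}, and
  Bcl-2 × venetoclax.  The venetoclax–Bcl-2 dissociation constant
  (1 nM) is strictly smaller than every Bcl-2–pro-apoptotic K_D
  (10–60 nM), which is what lets the drug strip Bcl-2 from the network.
  The drug pair is *reservoir-buffered*: complex formation sequesters
  Bcl-2 without depleting the intracellular free-drug concentration,
  because the extracellular medium holds far more drug moles than the
  cellular protein pool can bind.  A consequence worth noting: the
  drug/TF block is exactly self-contained, which makes the stage-1
  calibration (below) consistent with the full model.
* **Complex turnover.** All complexes degrade first order (shared rate
  `cx_deg`).  Without this sink the sequestered pools would grow without
  bound under constant synthesis and no untreated steady state would
  exist.
* **Activation and commitment.** The Bim·Bax complex converts
  catalytically at rate k_act into free Bim plus active Bax (likewise for
  Bak): direct activation with release of the activator.  Active
  effectors drive Caspase-3 activation through a steep Hill term in
  (BaxA + BakA) — a continuous surrogate for the MOMP commitment point;
  the Hill coefficient is kept in [2, 8] and every Hill coefficient in
  the registry is capped at 10 to avoid needlessly sharp, stiff response
  functions.  Active Caspase-3 deactivates first order (returning to the
  inactive pool, so total caspase is conserved) and cleaves free Bcl-2
  and Mcl-1 into inert pools — the positive feedback that makes the
  combination's apoptotic avalanche self-sustaining.
* **Population.** Live cells proliferate at rate
  g = g0 · h_up(Bcl-2_free) · h_down(tedizolid_int) · (1 + a·h_up(c-Myc)):
  venetoclax's metabolic effect enters through free Bcl-2, tedizolid's
  through the drug concentration itself.  Death is
  d = d0 + d_max · h_up(active-caspase fraction).  dN_live/dt =
  (g − d)·N_live and dN_dead/dt = d·N_live; viability is
  N_live/(N_live + N_dead), matching an Annexin-V live-fraction readout.

Conservation: with synthesis, degradation, activation and cleavage
switched off, each protein total (free + complexes + drug complex +
cleaved) is a linear invariant of the remaining binding/caspase dynamics;
the test suite verifies drift below 1e-6 relative over 100 h.

## Initialization (quasi-steady state)

Transcription factors start at their basal production/degradation
balance.  With binding conceptually off, each protein's maximal synthesis
rate is fixed so that regulated production at basal TF levels balances
degradation of the configured initial free abundance (p = δ·x0 up to the
basal regulation factor).  Free species then start at those abundances
with every complex, active effector and cleaved pool at zero, and the
system relaxes with binding on until the max-norm of the derivative over
the protein states falls below 1e-8 nM/h (cell counts are excluded from
the criterion — the untreated population grows exponentially by design
and cannot be part of a fixed point).  This steady state seeds every
treatment simulation as the constant pre-treatment history.

## Numerics

Stiff integration uses LSODA through `scipy.integrate.solve_ivp` with
rtol 1e-6 / atol 1e-9 by default, piecewise between administration events
(a dose adds to the extracellular pool and restarts the integrator at the
discontinuity).  Delays are handled by the method of steps: the
integrator advances in chunks, storing dense output, and delayed lookups
interpolate completed segments or the constant pre-treatment history.
Because the buffered drug subsystem is linear, the delayed drug
concentrations also have exact closed forms; the solver uses these by
default (`analytic_drug_delays=True`), which removes the chunk-length
constraint, and the generic interpolated history remains available and is
tested to agree.  The system is integrated in non-dimensional form: each
state is scaled by a power of two near its typical magnitude, so the
round trip to physical units is exact in binary floating point.
Trajectories are reported on a fixed grid of 25,000 points per 120 h
window by default, extended proportionally for pre-treatment windows;
analysis and calibration runs use coarser grids (400–2,000 points) since
only scheduled time points are consumed.

## Calibration

The objective is a banded loss per measurement: zero when the simulated
value lies inside [mean − k·sd, mean + k·sd], the relative exceedance
outside.  A half-width floor of 2% of the mean represents measurement
resolution and keeps bands non-degenerate for noise-free synthetic data.
Protein (f_p), viability (f_v) and count (f_c) sums combine as
w_p·f_p + w_v·f_v + w_c·f_c with weights 1 : 0.1 : 0.1 (default) or
1 : 0.2 : 0.05, roughly inverse to each modality's coefficient of
variation.  The band multiplier starts at k = 2 and tightens to k = 1
during the fit.

Fitting is two-stage, mirroring the separation between the drug/TF block
and the downstream network: stage 1 estimates drug-kinetic and
transcription-factor parameters against the c-Myc (24/48/72 h) and Chop
(24/48/72/96 h) relative-expression data using the self-contained 6-state
drug/TF subsystem (no equilibration needed); stage 2 freezes those and
fits the remaining free parameters against total protein on day 3 and
viability/counts on days 1–5 with full-model simulations.

The optimizer is a real-coded, block-structured genetic algorithm:
tournament selection with one elite, blend crossover, Gaussian mutation
scaled to the soft range.  Within each block the crossover fraction is
0.5 for the first iterations (mutation-heavy exploration) and 0.9
thereafter; between blocks, soft search boundaries shift toward any edge
the incumbent presses against — by up to 10% of the range early and 1%
late — clipped to hard biological bounds and logged.  A simulation
failure returns a 1e6 penalty plus a term rewarding later failure, so the
search steers around stiff blow-up regions without crashing.  Runs are
bit-reproducible for a fixed seed.  An optional bounded Powell polish of
the incumbent refines desk-scale runs, and the recovery harness finishes
with a joint trust-region least-squares pass on the per-point violation
vector (finite-difference Jacobian, confined to the soft box): banded
objectives have full-dimensional zero sets, and the feasibility view
converges into the all-in-band region where direct descent on the summed
hinge loss stalls on the kinks.

Identifiability caveat: the banded objective is flat inside the bands, so
several parameter sets fit equally well, and fitted values can drift
substantially from a generating truth in sloppy directions while
preserving every qualitative behaviour.  The summary table therefore
reports search intervals, not confidence intervals.

### The shipped nominal set

`israpop/data/nominal_params.csv` was produced by exactly this pipeline:
a synthetic study dataset was generated from the hand-designed template
registry (`default_params()`), and the two-stage GA (stage 1: 27 drug/TF
parameters, population 32, 4 blocks × 10 iterations; stage 2: 45 network
parameters, population 24, 4 blocks × 8 iterations) was run at desk scale
(~2,400 evaluations).  The result was then verified to retain the
qualitative treatment phenotypes before being versioned.  Figure-level
magnitudes from any published study are treated as qualitative targets
only, never as fit targets.

## Synthetic data

The generator simulates the four study conditions — untreated, 400 nM
venetoclax, 5,000 nM tedizolid, simultaneous combination; single dose, no
washout, no replenishment — and emits 3 replicates per measurement cell
on the experimental schedule (c-Myc 24/48/72 h; Chop 24/48/72/96 h; six
protein/caspase readouts at 72 h; viability and live counts at
24/48/72/96/120 h; 92 cells in total).  Protein readouts are totals
(free + complexed + cleaved) relative to the untreated steady state;
active Caspase-3 is the active fraction relative to untreated.  Noise is
multiplicative lognormal, mean-centred (the empirical mean converges to
the noise-free value), with default CVs 0.15 / 0.05 / 0.10 for
protein / viability / counts — repository choices standing in for
unpublished raw spreads; expression and count data are positive and
heteroskedastic, which an additive model would not respect.

What the generator does *not* emulate: blot saturation and background,
batch effects, replicate correlation, deviations from exponential growth.
Passing calibration and recovery tests on these data therefore
demonstrates the machinery works and the model is recoverable under its
own assumptions, not that the model is correct for real cells.

## Sensitivity analysis

Local: one-at-a-time ±1% perturbations of every free parameter and
protein initial condition; S = (Δv/v0)/(Δp/p0) with v the viability
120 h after the last administration.  Both signs are emitted; rankings
use |S|.  Perturbing an initial condition changes the untreated steady
state, so every perturbed run re-equilibrates before treatment.  The
qualitative signature at the nominal set: untreated and monotherapy
max |S| stay below 1 while the combination exceeds 1 by a wide margin,
with Chop-production parameters among the top-ranked — the stress
response is the fulcrum of the combination's efficacy.

Global: a Morris elementary-effects screen over ±25% ranges (clipped to
hard bounds), reported as μ* with the Spearman correlation against the
local ranking.  Morris was chosen as the cheapest defensible screen; the
trajectory count is configurable and seeded.

## Scheduling

The response statistic for a pre-treatment window τ is
R(τ) = (N0(t_n)/Nτ(t_n)) · (max N0 / max Nτ) over the dense grid, with
time measured from the completion of the combination; R(0) = 1 exactly
and the peak term penalizes transient live-cell spikes (the clinical
tumor-lysis consideration).  Scans evaluate τ ∈ [0, 96] h; τ* is reported
at grid resolution.  At the nominal set, tedizolid pre-treatment has an
interior optimum near τ* ≈ 42 h with R(τ*) ≈ 1.9: pre-treatment lets the
Chop rise, Mcl-1 dip and Bak accumulation happen *before* venetoclax
arrives, so caspase ignition is immediate rather than delayed by the
~1.5-day stress-response build-up, while windows beyond ~2 days forfeit
drug exposure and let the population grow during the wait.  Venetoclax
pre-treatment shows no benefit at the nominal set (R declines
monotonically): sequestering Bcl-2 early only spends the drug's finite
residence time before the ISR arm is active.

The virtual Mcl-1-inhibitor counterfactual replays the combination's
recorded Chop time course into the Chop→Mcl-1 edge only, during a
venetoclax monotherapy simulation (every other Chop and tedizolid effect
follows the monotherapy state).  Its viability tracks the combination
early and diverges upward after ~2 days, landing strictly between
monotherapy and combination on day 5: transient Mcl-1 relief alone
ignites apoptosis but cannot sustain it without the Chop-driven Bim/Bak
supply.

## Problem sizes

Default analysis runs use: 900-point output grids for protocol
simulations and the counterfactual; a 12-point τ grid for the headline
scan and 6 parameters × 2 signs × 9-point grids for τ* robustness;
the full free-parameter set (one sign) for the sensitivity sweep;
population 14–16, 2 blocks, 5–6 iterations per block plus polish for the
desk-scale refit and recovery demonstrations.  These sizes were chosen so
a complete end-to-end reproduction runs on a laptop-class single core in
well under half an hour; all are configurable upward.

## Known limitations

* No Bcl-XL, Bid, Puma, Noxa, Bad or Bok species; no apoptosome /
  Caspase-9 intermediates; MOMP is continuous, not an event.
* Exponential growth only; the model cannot capture saturating growth.
* Single-dose protocols; no washout, replenishment or PK plasma model.
* Local sensitivities at a flat banded optimum inherit the
  identifiability caveat: rankings are robust, magnitudes less so.
* The 28-state composition and the drug→TF submodel are reconstructions
  consistent with the printed state count and the described behaviours;
  they should not be read as a verbatim transcription of any published
  equation list.
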