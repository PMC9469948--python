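# israpop

Kinetic modelling of the integrated stress response (ISR) coupled to the
intrinsic apoptosis pathway in venetoclax-resistant AML cells — for
systems biologists studying how a BH3-mimetic (venetoclax, 400 nM) and an
ISR-triggering mitochondrial-translation inhibitor (tedizolid, 5,000 nM)
combine, and when to give which drug first.

Resistant cells survive venetoclax because up-regulated Mcl-1 buffers the
pro-apoptotic proteins that the drug displaces from Bcl-2.  Tedizolid
activates the ISR effector Chop, which represses Mcl-1 and induces Bim
and Bak.  The package models this coupling as a 28-state delay-ODE
system — drug uptake, c-Myc/Chop regulation, Bcl-2-family mass action,
Caspase-3 activation with cleavage feedback, and live/dead cell
populations — and layers on top of it everything needed to use the model
as an instrument:

* quasi-steady-state initialization of the untreated system;
* two-stage genetic-algorithm calibration against banded multi-modal
  objectives (protein expression, viability, live counts);
* a synthetic-data generator emulating the study's measurement design
  (3 replicates, scheduled time points, multiplicative lognormal noise),
  so calibration and recovery are testable without external data;
* local (one-at-a-time ±1%) and global (Morris) sensitivity analysis of
  day-5 viability;
* pre-treatment scheduling scans with the response statistic
  R(τ) = (N₀(t_n)/N_τ(t_n)) · (max N₀ / max N_τ), and the virtual
  Mcl-1-inhibitor counterfactual.

## Model sketch

Free species bind by mass action, `A + B ⇌ C` with net flux
`kon·[A][B] − koff·[C]`, for {Bcl-2, Mcl-1} × {Bim, BaxA, BakA},
Bim × {BaxI, BakI}, and Bcl-2 × venetoclax (K_D = 1 nM, below every
protein–protein K_D).  Synthesis of protein `i` is
`p_i · Π_e (1 ± amp_e · x_e^n_e/(K_e^n_e + x_e^n_e))` over its c-Myc and
Chop edges (unique K, n per edge); the pro-survival c-Myc edges
half-saturate before the pro-apoptotic ones, producing the hormetic
cancer-zone/apoptosis-zone profile.  Active effectors drive Caspase-3
through a steep Hill term (the continuous MOMP surrogate); active
Caspase-3 cleaves Bcl-2 and Mcl-1.  Cells obey
`dN_live/dt = (g − d)·N_live`, `dN_dead/dt = d·N_live` with g gated by
free Bcl-2, intracellular tedizolid and c-Myc, and d driven by the
active-caspase fraction.  Drug→transcription-factor production terms act
on delayed intracellular drug concentrations (method of steps; the
linear drug subsystem also admits exact closed-form delays, used by
default).  Details and design rationale: `docs/methods.md`.

## Worked example

```python
import numpy as np
from israpop import nominal_params, equilibrate
from israpop.protocols import run_protocol, scan_pretreatment

params = nominal_params()              # shipped calibrated set
steady = equilibrate(params).state     # untreated steady state

for name in ("untreated", "ven_mono", "ted_mono", "combo"):
    traj = run_protocol(params, name, steady_state=steady, output_points=900)
    v = traj.value_at(traj.viability, 120.0)
    c3 = traj.value_at(traj.state("casp3_active"), 72.0)
    print(f"{name:10s}  day-5 viability {v:6.3f}   active caspase-3 at 72 h {c3:8.2f} nM")

curve = scan_pretreatment(params, "tedizolid", np.arange(0.0, 97.0, 6.0),
                          steady_state=steady, output_points=600)
print(f"optimal tedizolid pre-treatment window: {curve.tau_star:.0f} h "
      f"(response R = {curve.R_star:.2f})")
```

prints

```
untreated   day-5 viability  0.951   active caspase-3 at 72 h     0.00 nM
ven_mono    day-5 viability  0.909   active caspase-3 at 72 h     0.27 nM
ted_mono    day-5 viability  0.825   active caspase-3 at 72 h     0.43 nM
combo       day-5 viability  0.002   active caspase-3 at 72 h    62.95 nM
optimal tedizolid pre-treatment window: 42 h (response R = 1.94)
```

Untreated cells and both monotherapies keep high viability — the
resistant phenotype — while the combination collapses it, driven by the
~10⁴-fold caspase activation.  The scan says pre-treating with tedizolid
~42 h before venetoclax roughly doubles the response: priming (Chop up,
Mcl-1 down, Bak up) lets apoptosis ignite the moment venetoclax arrives
instead of after the 1.5-day stress-response build-up.

Calibration runs through a statsmodels-style interface:

```python
from israpop import TreatmentResponseModel
model = TreatmentResponseModel.from_synthetic(seed=0)   # or .from_csv(...)
result = model.fit()        # two-stage GA; result.summary(), result.params
```

A `israpop` console script exposes `simulate`, `equilibrate`, `fit`,
`sense`, `scan`, `counterfactual` and `synth` subcommands; every run
writes a manifest (config, parameter hash, seed) for reproducibility.

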