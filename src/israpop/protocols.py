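"""Named treatment protocols, pre-treatment scheduling scans, the virtual
Mcl-1-inhibitor counterfactual, and dose-response curve evaluation.

The four experimental conditions are single-dose, no-washout,
no-replenishment protocols: untreated, 400 nM venetoclax, 5,000 nM
tedizolid, and the simultaneous combination.  Pre-treatment protocols give
one drug at t = -tau and complete the combination at t = 0; the response
statistic R(tau) compares endpoint and peak live-cell counts against the
simultaneous combination, both measured from the time the combination is
complete, so R(0) = 1 identically and R > 1 means the pre-treatment both
lowered the endpoint burden and avoided a larger transient spike in live
cells (the clinical tumor-lysis consideration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .equilibration import equilibrate
from .params import ParamSet
from .ratelaws import RhsSwitches, basal_tf_levels
from .solver import SolverConfig, simulate
from .states import TOTALS, total
from .trajectory import DEFAULT_OUTPUT_POINTS, Protocol, Trajectory

VENETOCLAX_DOSE_NM = 400.0
TEDIZOLID_DOSE_NM = 5_000.0
HORIZON_H = 120.0

PROTOCOL_NAMES = ("untreated", "ven_mono", "ted_mono", "combo",
                  "pretreat_ven", "pretreat_ted", "ven_plus_mcl1i")


def named_protocol(name: str, tau: float = 0.0,
                   output_points: int = DEFAULT_OUTPUT_POINTS) -> Protocol:
    """Build the Protocol object for a named experimental condition."""
    common = dict(horizon_h=HORIZON_H, output_points=output_points, name=name)
    if name == "untreated":
        return Protocol(**common)
    if name == "ven_mono":
        return Protocol(venetoclax_nM=VENETOCLAX_DOSE_NM, **common)
    if name == "ted_mono":
        return Protocol(tedizolid_nM=TEDIZOLID_DOSE_NM, **common)
    if name == "combo":
        return Protocol(venetoclax_nM=VENETOCLAX_DOSE_NM,
                        tedizolid_nM=TEDIZOLID_DOSE_NM, **common)
    if name == "pretreat_ven":
        if tau < 0:
            raise ValueError("pre-treatment window must be >= 0")
        return Protocol(venetoclax_nM=VENETOCLAX_DOSE_NM,
                        tedizolid_nM=TEDIZOLID_DOSE_NM,
                        venetoclax_time_h=-tau, tedizolid_time_h=0.0, **common)
    if name == "pretreat_ted":
        if tau < 0:
            raise ValueError("pre-treatment window must be >= 0")
        return Protocol(venetoclax_nM=VENETOCLAX_DOSE_NM,
                        tedizolid_nM=TEDIZOLID_DOSE_NM,
                        venetoclax_time_h=0.0, tedizolid_time_h=-tau, **common)
    if name == "ven_plus_mcl1i":
        return Protocol(venetoclax_nM=VENETOCLAX_DOSE_NM,
                        mcl1_inhibitor_mode=True, **common)
    raise KeyError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")


def run_protocol(params: ParamSet, name: str, tau: float = 0.0,
                 solver_cfg: SolverConfig | None = None,
                 steady_state: np.ndarray | None = None,
                 output_points: int = DEFAULT_OUTPUT_POINTS) -> Trajectory:
    """Simulate a named protocol from the untreated steady state."""
    if steady_state is None:
        steady_state = equilibrate(params).state
    if name == "ven_plus_mcl1i":
        return mcl1_inhibitor_counterfactual(
            params, solver_cfg=solver_cfg, steady_state=steady_state,
            output_points=output_points)
    proto = named_protocol(name, tau=tau, output_points=output_points)
    return simulate(params, proto, solver_cfg, steady_state=steady_state)


def normalized_protein_totals(traj: Trajectory, steady_state: np.ndarray,
                              times_h) -> pd.DataFrame:
    """Total-protein readouts at given times, relative to the untreated
    steady state (the experimental normalization), plus active Caspase-3
    relative to its untreated level (floored at one grid unit to avoid a
    zero reference)."""
    rows = []
    for t in times_h:
        y = traj.at(t)
        for prot in ("bcl2", "mcl1", "bim", "bax", "bak"):
            ref = total(steady_state, prot)
            rows.append({"time_h": t, "species": prot,
                         "rel_expression": total(y, prot) / ref})
        ref_c3 = max(float(steady_state[22] + 0.0), 1e-12)
        # active Caspase-3 is reported as fraction of the total caspase pool
        frac = y[23] / (y[22] + y[23])
        frac_ref = steady_state[23] / (steady_state[22] + steady_state[23])
        rows.append({"time_h": t, "species": "casp3_active",
                     "rel_expression": frac / max(frac_ref, 1e-9)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Response statistic and pre-treatment scans
# ---------------------------------------------------------------------------

def response(traj_ref: Trajectory, traj_tau: Trajectory,
             t_origin: float = 0.0) -> float:
    """R = (N0(t_n)/N_tau(t_n)) * (max N0 / max N_tau), live-cell counts
    measured from the time the combination therapy is complete."""
    w_ref = traj_ref.window(t_origin, traj_ref.t[-1])
    w_tau = traj_tau.window(t_origin, traj_tau.t[-1])
    n_ref, n_tau = w_ref.n_live, w_tau.n_live
    if n_tau[-1] <= 0 or n_tau.max() <= 0:
        raise ZeroDivisionError("live-cell count vanished in pre-treated run")
    return float((n_ref[-1] / n_tau[-1]) * (n_ref.max() / n_tau.max()))


@dataclass
class ResponseCurve:
    drug: str
    tau_h: np.ndarray
    R: np.ndarray
    peak_count: np.ndarray
    end_count: np.ndarray

    @property
    def tau_star(self) -> float:
        return float(self.tau_h[int(np.argmax(self.R))])

    @property
    def R_star(self) -> float:
        return float(self.R.max())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"tau_h": self.tau_h, "response": self.R,
                             "peak_count": self.peak_count,
                             "end_count": self.end_count})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def scan_pretreatment(params: ParamSet, drug: str, tau_grid,
                      solver_cfg: SolverConfig | None = None,
                      steady_state: np.ndarray | None = None,
                      output_points: int = DEFAULT_OUTPUT_POINTS) -> ResponseCurve:
    """Evaluate R(tau) for pre-treatment with one drug before combination.

    The simulation horizon is 5 days after the combination is complete;
    the output grid is extended proportionally to tau by the Protocol
    machinery.  tau = 0 reproduces the simultaneous combination (R = 1).
    """
    if drug not in ("venetoclax", "tedizolid"):
        raise KeyError(f"unknown pre-treatment drug {drug!r}")
    name = "pretreat_ven" if drug == "venetoclax" else "pretreat_ted"
    tau_grid = np.asarray(sorted(tau_grid), dtype=float)
    if tau_grid.min() < 0 or tau_grid.max() > 96.0:
        raise ValueError("pre-treatment windows must lie in [0, 96] h")
    if steady_state is None:
        steady_state = equilibrate(params).state

    ref = run_protocol(params, "combo", solver_cfg=solver_cfg,
                       steady_state=steady_state, output_points=output_points)
    Rs, peaks, ends = [], [], []
    for tau in tau_grid:
        if tau == 0.0:
            traj = ref
        else:
            traj = run_protocol(params, name, tau=tau, solver_cfg=solver_cfg,
                                steady_state=steady_state,
                                output_points=output_points)
        w = traj.window(0.0, HORIZON_H)
        Rs.append(response(ref, traj))
        peaks.append(float(w.n_live.max()))
        ends.append(float(w.n_live[-1]))
    return ResponseCurve(drug=drug, tau_h=tau_grid, R=np.array(Rs),
                         peak_count=np.array(peaks), end_count=np.array(ends))


# ---------------------------------------------------------------------------
# Virtual Mcl-1 inhibitor counterfactual
# ---------------------------------------------------------------------------

def mcl1_inhibitor_counterfactual(params: ParamSet,
                                  combo_traj: Trajectory | None = None,
                                  solver_cfg: SolverConfig | None = None,
                                  steady_state: np.ndarray | None = None,
                                  output_points: int = DEFAULT_OUTPUT_POINTS) -> Trajectory:
    """Venetoclax monotherapy plus a virtual Mcl-1 inhibitor.

    The inhibitor reproduces the kinetic pattern of the Chop->Mcl-1
    inhibitory regulation seen in the recorded combination treatment: the
    Chop->Mcl-1 edge is driven by the combination's Chop time course while
    every other Chop and tedizolid effect is absent (Chop itself follows
    its venetoclax-monotherapy dynamics).
    """
    if steady_state is None:
        steady_state = equilibrate(params).state
    if combo_traj is None:
        combo_traj = run_protocol(params, "combo", solver_cfg=solver_cfg,
                                  steady_state=steady_state,
                                  output_points=output_points)
    chop_rec = interp1d(combo_traj.t, combo_traj.state("chop"),
                        bounds_error=False,
                        fill_value=(combo_traj.state("chop")[0],
                                    combo_traj.state("chop")[-1]))

    def drive(t: float) -> float:
        return float(chop_rec(t))

    proto = named_protocol("ven_plus_mcl1i", output_points=output_points)
    switches = RhsSwitches(mcl1_chop_drive=drive)
    traj = simulate(params, proto, solver_cfg, steady_state=steady_state,
                    switches=switches)
    traj.metadata["mcl1_inhibitor_mode"] = True
    return traj


# ---------------------------------------------------------------------------
# Dose-response curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter sigmoid y = a + (b-a) x^n / (x^n + K^n); with n < 0
    the curve runs from b at low dose to a at high dose."""
    a: float
    b: float
    K: float
    n: float

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("K must be positive")


def eval_dose_response(fit: DoseResponseFit, x) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("dose-response curve is evaluated on x > 0 only")
    xn = x ** fit.n
    y = fit.a + (fit.b - fit.a) * xn / (xn + fit.K ** fit.n)
    return float(y) if y.ndim == 0 else y


def fit_dose_response(x, y, p0: DoseResponseFit | None = None) -> DoseResponseFit:
    """Least-squares fit of the sigmoid to (dose, normalized viability)
    points; a validation utility, not a core method."""
    from scipy.optimize import curve_fit
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def f(x, a, b, K, n):
        xn = np.power(x, n)
        return a + (b - a) * xn / (xn + np.power(K, n))

    start = (p0.a, p0.b, p0.K, p0.n) if p0 else (y.min(), y.max(), np.median(x), -1.0)
    popt, _ = curve_fit(f, x, y, p0=start, maxfev=20000)
    return DoseResponseFit(*[float(v) for v in popt])
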