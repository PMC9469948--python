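"""Model/Results interface tying the pipeline together.

`TreatmentResponseModel` wraps a multi-modal treatment dataset (the shared
CSV schema: condition, modality, species, time_h, mean, sd) together with
a parameter registry; `fit()` runs the two-stage genetic-algorithm
calibration and returns a `TreatmentResponseResults` carrying the
calibrated parameters, the objective decomposition, the fit diagnostics,
and simulation/sensitivity/scheduling methods evaluated at the estimates.

Because the banded objective is deliberately flat near the data (any
parameter set inside every band is equivalent), no curvature-based
standard errors are reported; the summary shows each estimate with its
final search interval, and the identifiability caveat applies: several
parameter sets may fit equally well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (DATASET_COLUMNS, FitReport, GAConfig,
                          ObjectiveConfig, fit_stage1_tf, fit_stage2_full,
                          objective)
from .equilibration import equilibrate
from .params import ParamSet, default_params
from .protocols import (ResponseCurve, mcl1_inhibitor_counterfactual,
                        run_protocol, scan_pretreatment)
from .sensitivity import condition_sensitivity_report
from .solver import SolverConfig
from .trajectory import Trajectory


class TreatmentResponseModel:
    """Kinetic treatment-response model bound to a measurement dataset."""

    def __init__(self, dataset: pd.DataFrame, params: ParamSet | None = None,
                 objective_config: ObjectiveConfig | None = None):
        missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
        if missing:
            raise ValueError(f"dataset lacks required columns {missing}")
        self.dataset = dataset.reset_index(drop=True)
        self.params = (params or default_params()).copy()
        self.objective_config = objective_config or ObjectiveConfig()

    @classmethod
    def from_csv(cls, path, **kw) -> "TreatmentResponseModel":
        return cls(pd.read_csv(path), **kw)

    @classmethod
    def from_synthetic(cls, true_params: ParamSet | None = None, seed: int = 0,
                       noise_cv: dict | None = None, **kw) -> "TreatmentResponseModel":
        """Convenience constructor: simulate the study conditions from a
        ground-truth parameter set and bind the generated dataset."""
        from .synthetic import generate
        truth = true_params or default_params()
        ds = generate(truth, noise_cv=noise_cv, seed=seed)
        model = cls(ds.data, **kw)
        model._synthetic_truth = truth
        return model

    def objective_at(self, params: ParamSet | None = None) -> dict:
        return objective(params or self.params, self.dataset, self.objective_config)

    def fit(self, ga_config: GAConfig | None = None,
            stages: tuple[str, ...] = ("tf", "full"),
            stage1_free: list[str] | None = None,
            stage2_free: list[str] | None = None) -> "TreatmentResponseResults":
        """Two-stage calibration: drug/TF parameters first (frozen
        thereafter), then the downstream network parameters."""
        ga = ga_config or GAConfig()
        params = self.params.copy()
        reports: list[FitReport] = []
        if "tf" in stages:
            params, rep = fit_stage1_tf(params, self.dataset, ga,
                                        self.objective_config,
                                        free_names=stage1_free)
            reports.append(rep)
        if "full" in stages:
            params, rep = fit_stage2_full(params, self.dataset, ga,
                                          self.objective_config,
                                          free_names=stage2_free)
            reports.append(rep)
        parts = objective(params, self.dataset, self.objective_config)
        return TreatmentResponseResults(model=self, params=params,
                                        fit_reports=reports,
                                        objective_parts=parts)


@dataclass
class TreatmentResponseResults:
    """Calibrated-model results: estimates, diagnostics and downstream
    analyses (simulation, sensitivity, scheduling) at the estimates."""

    model: TreatmentResponseModel
    params: ParamSet
    fit_reports: list[FitReport]
    objective_parts: dict
    _steady_state: np.ndarray | None = field(default=None, repr=False)

    # -- diagnostics -------------------------------------------------------
    @property
    def objective(self) -> float:
        return float(self.objective_parts["total"])

    @property
    def fitted_names(self) -> list[str]:
        names: list[str] = []
        for rep in self.fit_reports:
            names += [n for n in rep.free_names if n not in names]
        return names

    def steady_state(self) -> np.ndarray:
        if self._steady_state is None:
            self._steady_state = equilibrate(self.params).state
        return self._steady_state

    # -- downstream analyses ----------------------------------------------
    def simulate(self, protocol: str = "combo", tau: float = 0.0,
                 solver_cfg: SolverConfig | None = None,
                 output_points: int = 2000) -> Trajectory:
        return run_protocol(self.params, protocol, tau=tau,
                            solver_cfg=solver_cfg,
                            steady_state=self.steady_state(),
                            output_points=output_points)

    def sensitivity(self, **kw) -> dict[str, pd.DataFrame]:
        return condition_sensitivity_report(self.params, **kw)

    def scan_pretreatment(self, drug: str = "tedizolid",
                          tau_grid=None, output_points: int = 2000,
                          **kw) -> ResponseCurve:
        tau_grid = tau_grid if tau_grid is not None else np.arange(0.0, 97.0, 4.0)
        return scan_pretreatment(self.params, drug, tau_grid,
                                 steady_state=self.steady_state(),
                                 output_points=output_points, **kw)

    def counterfactual(self, output_points: int = 2000) -> Trajectory:
        return mcl1_inhibitor_counterfactual(self.params,
                                             steady_state=self.steady_state(),
                                             output_points=output_points)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = []
        w = 78
        lines.append("Treatment-response kinetic model".center(w))
        lines.append("=" * w)
        parts = self.objective_parts
        lines.append(f"objective total {parts['total']:.6g}   "
                     f"f_p {parts['f_p']:.6g}   f_v {parts['f_v']:.6g}   "
                     f"f_c {parts['f_c']:.6g}")
        n_pts = len(self.model.dataset)
        lines.append(f"measurement points: {n_pts}   "
                     f"fitted parameters: {len(self.fitted_names)}")
        for rep in self.fit_reports:
            lines.append(f"  {rep.stage}: best {rep.best_objective:.6g} "
                         f"({rep.n_evaluations} evaluations, seed {rep.seed})")
        lines.append("-" * w)
        lines.append(f"{'parameter':<26}{'estimate':>12}{'units':>10}"
                     f"{'search lo':>14}{'search hi':>14}")
        lines.append("-" * w)
        for name in self.fitted_names:
            e = self.params.entry(name)
            lines.append(f"{name:<26}{e.value:>12.5g}{e.units:>10}"
                         f"{e.soft_lo:>14.5g}{e.soft_hi:>14.5g}")
        lines.append("-" * w)
        lines.append("note: banded objectives are flat inside the data bands;")
        lines.append("the search interval is not a confidence interval, and")
        lines.append("several parameter sets may fit the data equally well.")
        return "\n".join(lines)

    def plot_viability(self, conditions=("untreated", "ven_mono", "ted_mono",
                                         "combo"), ax=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for cond in conditions:
            traj = self.simulate(cond)
            ax.plot(traj.t, traj.viability, label=cond)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("viability")
        ax.set_ylim(0, 1.05)
        ax.legend(frameon=False)
        return ax
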