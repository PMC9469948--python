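"""Local and global sensitivity of day-5 viability.

The local measure is the one-at-a-time relative sensitivity
S = (dv/v0) / (dp/p0) of the day-5 (120 h after the last administration)
cell viability to a +/-1% perturbation of a single kinetic parameter or
initial condition.  |S| < 1 means the response absorbs the perturbation;
|S| > 1 flags an interaction that dominates the treatment outcome.  The
global screen is a Morris elementary-effects design over +/-25% ranges,
reported as mu* (mean absolute elementary effect) with the rank
correlation against the local |S| ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .equilibration import equilibrate, EquilibrationError
from .params import ParamSet
from .solver import SimulationError, SolverConfig
from .protocols import run_protocol

DEFAULT_DELTA = 0.01
_INITIAL_CONDITIONS = ("bcl2_0", "mcl1_0", "bim_0", "bax_0", "bak_0", "casp3_0")

_SENS_SOLVER = SolverConfig(rtol=1e-7, atol=1e-10)
_SENS_POINTS = 600


@dataclass(frozen=True)
class SensitivityRecord:
    target: str
    condition: str
    sign: str            # "+" | "-"
    delta: float         # |dp| / p0
    v0: float
    v_pert: float
    S: float

    def recompute(self) -> float:
        dp = self.delta if self.sign == "+" else -self.delta
        return ((self.v_pert - self.v0) / self.v0) / dp


def day5_viability(params: ParamSet, condition: str,
                   solver_cfg: SolverConfig | None = None,
                   output_points: int = _SENS_POINTS) -> float:
    """Viability 120 h after the (final) drug administration."""
    traj = run_protocol(params, condition, solver_cfg=solver_cfg or _SENS_SOLVER,
                        output_points=output_points)
    w = traj.window(0.0, 120.0)
    return float(w.viability[-1])


def local_oat(params: ParamSet, condition: str,
              targets: list[str] | None = None,
              delta: float = DEFAULT_DELTA,
              signs: tuple[str, ...] = ("+", "-"),
              solver_cfg: SolverConfig | None = None,
              output_points: int = _SENS_POINTS) -> list[SensitivityRecord]:
    """One-at-a-time local sensitivities of day-5 viability, ranked by |S|.

    Targets default to every free parameter plus the protein initial
    conditions; entries with a zero nominal value are skipped (the relative
    perturbation is undefined there).
    """
    solver_cfg = solver_cfg or _SENS_SOLVER
    if targets is None:
        targets = list(dict.fromkeys(list(params.free_names) + list(_INITIAL_CONDITIONS)))
    v0 = day5_viability(params, condition, solver_cfg, output_points)
    records = []
    for name in targets:
        p0 = params[name]
        if p0 == 0.0:
            continue
        for sign in signs:
            dp = delta if sign == "+" else -delta
            pert = params.copy()
            pert[name] = p0 * (1.0 + dp)
            try:
                v = day5_viability(pert, condition, solver_cfg, output_points)
            except (SimulationError, EquilibrationError, FloatingPointError):
                continue
            S = ((v - v0) / v0) / dp
            records.append(SensitivityRecord(target=name, condition=condition,
                                             sign=sign, delta=delta,
                                             v0=v0, v_pert=v, S=S))
    records.sort(key=lambda r: abs(r.S), reverse=True)
    return records


def records_to_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def condition_sensitivity_report(params: ParamSet,
                                 conditions=("untreated", "ven_mono",
                                             "ted_mono", "combo"),
                                 targets: list[str] | None = None,
                                 top_k: int = 20,
                                 delta: float = DEFAULT_DELTA,
                                 signs: tuple[str, ...] = ("+",),
                                 solver_cfg: SolverConfig | None = None,
                                 output_points: int = _SENS_POINTS) -> dict[str, pd.DataFrame]:
    """Ranked |S| tables per condition (deterministic: same inputs give
    byte-identical CSV)."""
    out = {}
    for cond in conditions:
        recs = local_oat(params, cond, targets=targets, delta=delta,
                         signs=signs, solver_cfg=solver_cfg,
                         output_points=output_points)
        df = records_to_frame(recs)
        df["abs_S"] = df["S"].abs()
        df = df.sort_values(["abs_S", "target", "sign"],
                            ascending=[False, True, True]).head(top_k)
        out[cond] = df.reset_index(drop=True)
    return out


def chop_production_targets(params: ParamSet) -> list[str]:
    """Parameters governing the drug-induced production of Chop."""
    return [n for n in params.names
            if n.startswith(("chop_ven", "chop_ted", "chop_syn", "chop_prod"))]


# ---------------------------------------------------------------------------
# Morris elementary-effects screen
# ---------------------------------------------------------------------------

@dataclass
class MorrisResult:
    targets: list[str]
    mu_star: np.ndarray
    sigma: np.ndarray
    n_trajectories: int
    n_failures: int
    seed: int

    def ranking(self) -> pd.DataFrame:
        df = pd.DataFrame({"target": self.targets, "mu_star": self.mu_star,
                           "sigma": self.sigma})
        return df.sort_values("mu_star", ascending=False).reset_index(drop=True)


def global_screen(params: ParamSet, targets: list[str] | None = None,
                  condition: str = "combo",
                  rel_range: float = 0.25,
                  n_trajectories: int = 8,
                  n_levels: int = 4,
                  seed: int = 0,
                  solver_cfg: SolverConfig | None = None,
                  output_points: int = _SENS_POINTS,
                  max_failures: int = 20,
                  response=None) -> MorrisResult:
    """Morris elementary-effects screen of day-5 viability (or a custom
    scalar `response(params) -> float`) over +/-`rel_range` parameter
    ranges, clipped to hard bounds.  Degenerate (zero-width) ranges yield
    zero effects by construction."""
    solver_cfg = solver_cfg or _SENS_SOLVER
    if targets is None:
        targets = list(params.free_names)
    if response is None:
        def response(ps):
            return day5_viability(ps, condition, solver_cfg, output_points)

    rng = np.random.default_rng(seed)
    ndim = len(targets)
    lo = np.empty(ndim)
    hi = np.empty(ndim)
    for i, name in enumerate(targets):
        e = params.entry(name)
        lo[i] = max(e.value * (1.0 - rel_range), e.hard_lo)
        hi[i] = min(e.value * (1.0 + rel_range), e.hard_hi)

    delta = n_levels / (2.0 * (n_levels - 1))
    grid = np.arange(0, n_levels // 2) / (n_levels - 1)

    effects: list[list[float]] = [[] for _ in range(ndim)]
    n_failures = 0

    def evaluate(u: np.ndarray) -> float | None:
        nonlocal n_failures
        x = lo + u * (hi - lo)
        trial = params.copy()
        for name, v in zip(targets, x):
            trial[name] = v
        try:
            return response(trial)
        except (SimulationError, EquilibrationError, FloatingPointError):
            n_failures += 1
            if n_failures > max_failures:
                raise RuntimeError("too many failed Morris samples")
            return None

    for _ in range(n_trajectories):
        u = rng.choice(grid, ndim)
        order = rng.permutation(ndim)
        direction = rng.choice([-1.0, 1.0], ndim)
        y_prev = evaluate(u)
        for d in order:
            step = delta * direction[d]
            if not (0.0 <= u[d] + step <= 1.0):
                step = -step
            u = u.copy()
            u[d] += step
            y = evaluate(u)
            if y_prev is not None and y is not None and hi[d] > lo[d]:
                effects[d].append((y - y_prev) / step)
            y_prev = y

    mu_star = np.array([np.mean(np.abs(e)) if e else 0.0 for e in effects])
    sigma = np.array([np.std(e) if len(e) > 1 else 0.0 for e in effects])
    return MorrisResult(targets=list(targets), mu_star=mu_star, sigma=sigma,
                        n_trajectories=n_trajectories, n_failures=n_failures,
                        seed=seed)


def rank_correlation(local_records: list[SensitivityRecord],
                     morris: MorrisResult) -> float:
    """Spearman rank correlation between local |S| and Morris mu*."""
    from scipy.stats import spearmanr
    local_by_target: dict[str, float] = {}
    for r in local_records:
        local_by_target[r.target] = max(local_by_target.get(r.target, 0.0), abs(r.S))
    common = [t for t in morris.targets if t in local_by_target]
    if len(common) < 3:
        raise ValueError("need at least 3 shared targets for a rank correlation")
    ls = [local_by_target[t] for t in common]
    ms = [morris.mu_star[morris.targets.index(t)] for t in common]
    rho, _ = spearmanr(ls, ms)
    return float(rho)
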