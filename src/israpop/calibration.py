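"""Banded-loss objective and two-stage genetic-algorithm calibration.

The loss for a single measurement is zero when the simulated value lies
inside the data band [x_bar - k*sd, x_bar + k*sd] and equals the relative
exceedance outside it; this prevents over-fitting sparse, noisy data.  A
band-tightening schedule starts the fit at k = 2 for the low-CV
viability/count modalities and narrows to k = 1.  The total objective is a
weighted sum of the protein (f_p), viability (f_v) and count (f_c) sums,
with weights roughly inverse to each modality's coefficient of variation
(1 : 0.1 : 0.1 or 1 : 0.2 : 0.05).

Calibration is two-stage: stage 1 determines the drug-kinetic and
transcription-factor parameters against the c-Myc/Chop time courses using
the self-contained drug/TF subsystem; stage 2 freezes those and fits the
remaining free parameters against the protein, viability and count data
with full-model simulations.  The genetic algorithm is real-coded and
block-structured: within each block the crossover fraction switches from
0.5 (mutation-heavy exploration) to 0.9, and between blocks the soft
search boundaries are shifted toward any edge the incumbent is pressing
against — by up to 10% early and 1% late — without ever crossing the hard
biological bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibration import equilibrate, EquilibrationError
from .params import ParamSet, stage1_names
from .ratelaws import basal_tf_levels
from .solver import SimulationError, SolverConfig, simulate
from .states import IDX, total
from .trajectory import Protocol
from .protocols import named_protocol

DATASET_COLUMNS = ["condition", "modality", "species", "time_h", "mean", "sd"]

FAILURE_PENALTY = 1.0e6


# ---------------------------------------------------------------------------
# Banded loss (relative-exceedance loss with a data band)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementPoint:
    condition: str
    modality: str                 # protein_rel | viability | live_count
    species: str | None
    time_h: float
    mean: float
    sd: float
    band_multiplier: float = 1.0


def banded_loss(x_s: float, point: MeasurementPoint,
                k: float | None = None, min_band_rel: float = 0.0) -> float:
    """Zero inside [mean - k*sd, mean + k*sd]; relative exceedance outside.

    `min_band_rel` is a half-width floor (fraction of the mean) representing
    measurement resolution; it keeps the band non-degenerate for noise-free
    synthetic data.
    """
    k = point.band_multiplier if k is None else k
    half = max(k * point.sd, min_band_rel * abs(point.mean))
    x_minus = point.mean - half
    x_plus = point.mean + half
    if x_minus <= 0:
        raise ValueError(
            f"lower band edge must be positive (mean={point.mean}, half-width={half}); "
            "widen the band policy or rescale the measurement")
    if x_s > x_plus:
        return (x_s - x_plus) / x_plus
    if x_s < x_minus:
        return (x_minus - x_s) / x_minus
    return 0.0


@dataclass
class ObjectiveConfig:
    weights: tuple[float, float, float] = (1.0, 0.1, 0.1)   # (w_p, w_v, w_c)
    band_k_start: float = 2.0
    band_k_end: float = 1.0
    min_band_rel: float = 0.02
    output_points: int = 400
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(rtol=1e-5, atol=1e-8))

    @classmethod
    def scheme(cls, name: str, **kw) -> "ObjectiveConfig":
        table = {"1:0.1:0.1": (1.0, 0.1, 0.1), "1:0.2:0.05": (1.0, 0.2, 0.05)}
        if name not in table:
            raise KeyError(f"unknown weighting scheme {name!r}")
        return cls(weights=table[name], **kw)


def dataset_points(df: pd.DataFrame) -> list[MeasurementPoint]:
    pts = []
    for _, r in df.iterrows():
        sp = r["species"]
        sp = None if (pd.isna(sp) or sp in ("", "na")) else str(sp)
        pts.append(MeasurementPoint(str(r["condition"]), str(r["modality"]), sp,
                                    float(r["time_h"]), float(r["mean"]),
                                    float(r["sd"])))
    return pts


def _simulated_value(traj, steady_state, basal_tf, point: MeasurementPoint) -> float:
    t = point.time_h
    if point.modality == "viability":
        return traj.value_at(traj.viability, t)
    if point.modality == "live_count":
        return traj.value_at(traj.n_live, t)
    if point.modality == "protein_rel":
        sp = point.species
        if sp in ("myc", "chop"):
            ref = basal_tf[sp]
            return traj.value_at(traj.state(sp), t) / ref
        if sp == "casp3_active":
            y = traj.at(t)
            frac = y[IDX["casp3_active"]] / (y[IDX["casp3_inactive"]] + y[IDX["casp3_active"]])
            frac_ref = steady_state[IDX["casp3_active"]] / (
                steady_state[IDX["casp3_inactive"]] + steady_state[IDX["casp3_active"]])
            return frac / max(frac_ref, 1e-9)
        return total(traj.at(t), sp) / total(steady_state, sp)
    raise KeyError(f"unknown modality {point.modality!r}")


def objective_residuals(params: ParamSet, dataset: pd.DataFrame,
                        cfg: ObjectiveConfig | None = None,
                        band_k: float | None = None) -> np.ndarray:
    """Per-point banded-loss vector (unweighted); zero iff every simulated
    value lies inside its band.  The feasibility view of the objective."""
    cfg = cfg or ObjectiveConfig()
    k = cfg.band_k_end if band_k is None else band_k
    points = dataset_points(dataset)
    conditions = sorted({p.condition for p in points})
    try:
        myc0, chop0 = basal_tf_levels(params)
        basal_tf = {"myc": myc0, "chop": chop0}
        steady = equilibrate(params).state
        trajs = {cond: simulate(params,
                                named_protocol(cond, output_points=cfg.output_points),
                                cfg.solver, steady_state=steady)
                 for cond in conditions}
    except (SimulationError, EquilibrationError, FloatingPointError,
            ZeroDivisionError):
        return np.full(len(points), FAILURE_PENALTY)
    return np.array([banded_loss(
        _simulated_value(trajs[p.condition], steady, basal_tf, p), p,
        k=k, min_band_rel=cfg.min_band_rel) for p in points])


def objective(params: ParamSet, dataset: pd.DataFrame,
              cfg: ObjectiveConfig | None = None,
              band_k: float | None = None,
              tf_only: bool = False,
              squared: bool = False) -> dict[str, float]:
    """Weighted banded-loss objective over all measurement points.

    Returns {"total", "f_p", "f_v", "f_c"}.  Simulation failures yield a
    documented penalty (1e6 plus a term rewarding later failure) rather
    than an exception, so the optimizer can steer away from pathological
    parameter regions.  With ``squared`` the per-point losses are squared:
    a C1-smooth surrogate with the same zero set, useful for local polish.
    """
    cfg = cfg or ObjectiveConfig()
    k = cfg.band_k_end if band_k is None else band_k
    points = dataset_points(dataset)
    conditions = sorted({p.condition for p in points})

    trajs = {}
    try:
        myc0, chop0 = basal_tf_levels(params)
        basal_tf = {"myc": myc0, "chop": chop0}
        if tf_only:
            for cond in conditions:
                trajs[cond] = simulate_tf_subsystem(
                    params, named_protocol(cond, output_points=cfg.output_points),
                    solver=cfg.solver)
            steady = None
        else:
            steady = equilibrate(params).state
            for cond in conditions:
                trajs[cond] = simulate(
                    params, named_protocol(cond, output_points=cfg.output_points),
                    cfg.solver, steady_state=steady)
    except (SimulationError, EquilibrationError, FloatingPointError,
            ZeroDivisionError) as err:
        t_fail = getattr(err, "last_valid_time", 0.0) or 0.0
        bad = FAILURE_PENALTY + max(0.0, 120.0 - t_fail)
        return {"total": bad, "f_p": bad, "f_v": bad, "f_c": bad,
                "failure": str(err)}

    sums = {"protein_rel": 0.0, "viability": 0.0, "live_count": 0.0}
    for p in points:
        x_s = _simulated_value(trajs[p.condition], steady, basal_tf, p)
        loss = banded_loss(x_s, p, k=k, min_band_rel=cfg.min_band_rel)
        sums[p.modality] += loss * loss if squared else loss
    w_p, w_v, w_c = cfg.weights
    f_p, f_v, f_c = sums["protein_rel"], sums["viability"], sums["live_count"]
    return {"total": w_p * f_p + w_v * f_v + w_c * f_c,
            "f_p": f_p, "f_v": f_v, "f_c": f_c}


# ---------------------------------------------------------------------------
# Fast drug/TF subsystem (stage 1 operates on this self-contained block)
# ---------------------------------------------------------------------------

class _TfTrajectory:
    """Minimal trajectory facade over the 6-state drug/TF subsystem."""

    def __init__(self, t, ve, vi, te, ti, myc, chop):
        self.t = t
        self._series = {"venetoclax_ext": ve, "venetoclax_int": vi,
                        "tedizolid_ext": te, "tedizolid_int": ti,
                        "myc": myc, "chop": chop}

    def state(self, name):
        return self._series[name]

    def value_at(self, series, t_query):
        i = int(np.argmin(np.abs(self.t - t_query)))
        return float(series[i])

    def at(self, t_query):  # pragma: no cover - protein points invalid here
        raise KeyError("drug/TF subsystem carries no protein states")


def simulate_tf_subsystem(params: ParamSet, protocol: Protocol,
                          solver: SolverConfig | None = None) -> _TfTrajectory:
    """Integrate only the drug pools and transcription factors.

    The drug/TF block receives no feedback from the protein network (drug
    sequestration by Bcl-2 is neglected here, as in a mean-field
    treatment), so stage-1 calibration can run without equilibrating the
    full model.
    """
    from .ratelaws import drug_and_tf_rhs_fast
    solver = solver or SolverConfig(rtol=1e-6, atol=1e-9)
    p = params.values_dict()
    myc0, chop0 = basal_tf_levels(params)

    taus = {k: p[f"{k}_tau"] for k in ("myc_ven", "myc_ted", "chop_ven", "chop_ted")}
    state_of = {"myc_ven": 1, "myc_ted": 3, "chop_ven": 1, "chop_ted": 3}
    pos = [v for v in taus.values() if v > 0]
    chunk = min(pos) if pos else 24.0

    def _hill(x, K, n):
        if x <= 0:
            return 0.0
        return 1.0 / (1.0 + (K / x) ** n)

    segments: list = []
    seg_starts: list[float] = []
    t_start = protocol.t_start
    y = np.array([0.0, 0.0, 0.0, 0.0, myc0, chop0])

    def hist_val(idx, tq):
        if tq <= t_start or not segments:
            return 0.0 if idx in (1, 3) else (myc0 if idx == 4 else chop0)
        import bisect
        kk = max(bisect.bisect_right(seg_starts, tq) - 1, 0)
        sol = segments[kk]
        tt = min(max(tq, sol.t_min), sol.t_max)
        return float(sol(tt)[idx])

    def fun(t, yv):
        delayed = {key: (yv[state_of[key]] if taus[key] == 0.0
                         else hist_val(state_of[key], t - taus[key]))
                   for key in taus}
        return np.array(drug_and_tf_rhs_fast(t, yv, delayed, p, _hill))

    ev_map: dict[float, list[tuple[int, float]]] = {}
    for t_ev, pool, dose in protocol.events():
        ev_map.setdefault(t_ev, []).append((0 if pool == "venetoclax_ext" else 2, dose))
    for i, dose in ev_map.get(t_start, []):
        y[i] += dose
    boundaries = sorted({t for t in ev_map if t > t_start} | {protocol.horizon_h})

    t_cur = t_start
    for t_b in boundaries:
        while t_cur < t_b - 1e-12:
            t_next = min(t_cur + chunk, t_b)
            sol = solve_ivp(fun, (t_cur, t_next), y, method="LSODA",
                            rtol=solver.rtol, atol=solver.atol, dense_output=True)
            if not sol.success:
                raise SimulationError(f"TF subsystem failed: {sol.message}",
                                      last_valid_time=float(sol.t[-1]))
            seg_starts.append(sol.sol.t_min)
            segments.append(sol.sol)
            y = sol.y[:, -1]
            t_cur = t_next
        for i, dose in ev_map.get(t_b, []):
            y[i] += dose

    grid = np.linspace(t_start, protocol.horizon_h, protocol.n_grid())
    Y = np.empty((grid.size, 6))
    import bisect
    for i, t in enumerate(grid):
        kk = max(bisect.bisect_right(seg_starts, t) - 1, 0)
        sol = segments[kk]
        Y[i] = sol(min(max(t, sol.t_min), sol.t_max))
    return _TfTrajectory(grid, *(Y[:, j] for j in range(6)))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    population_size: int = 100
    n_blocks: int = 40
    iterations_per_block: int = 30        # within the 25-100 convention
    crossover_switch_iteration: int = 20  # 0.5 before, 0.9 after (within block)
    crossover_fraction_early: float = 0.5
    crossover_fraction_late: float = 0.9
    soft_adjust_early: float = 0.10       # max relative soft-bound shift, early blocks
    soft_adjust_late: float = 0.01        # ... in the final third of blocks
    mutation_sigma: float = 0.15          # fraction of the soft range
    elite: int = 1
    tournament: int = 3
    seed: int = 0
    stall_blocks: int = 8                 # stop early after this many flat blocks
    polish: bool = False                  # Nelder-Mead refinement of the incumbent
    polish_maxfev: int | None = None      # default 60 * ndim

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitReport:
    stage: str
    free_names: list[str]
    best_objective: float
    objective_parts: dict
    block_trace: list[float]
    boundary_log: list[dict]
    ga_config: dict
    seed: int
    n_evaluations: int
    dataset_hash: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _ga_minimize(fun, soft: np.ndarray, hard: np.ndarray, cfg: GAConfig,
                 x0: np.ndarray | None = None):
    """Block-structured real-coded GA.  Returns (x_best, f_best, trace,
    boundary_log, n_evals).  Deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    ndim = soft.shape[0]
    soft = soft.astype(float).copy()
    lo, hi = soft[:, 0], soft[:, 1]
    hlo, hhi = hard[:, 0], hard[:, 1]

    pop = lo + (hi - lo) * rng.random((cfg.population_size, ndim))
    if x0 is not None:
        pop[0] = np.clip(x0, lo, hi)
    fit = np.array([fun(x) for x in pop])
    n_evals = len(pop)
    trace, blog = [], []
    best_prev = np.inf
    stall = 0

    for block in range(cfg.n_blocks):
        late = block >= (2 * cfg.n_blocks) // 3
        for it in range(cfg.iterations_per_block):
            cx_frac = (cfg.crossover_fraction_early
                       if it < cfg.crossover_switch_iteration
                       else cfg.crossover_fraction_late)
            order = np.argsort(fit)
            elite_idx = order[:cfg.elite]
            children = np.empty_like(pop)
            children[:cfg.elite] = pop[elite_idx]
            for j in range(cfg.elite, cfg.population_size):
                cand = rng.integers(0, cfg.population_size, cfg.tournament)
                p1 = pop[cand[np.argmin(fit[cand])]]
                if rng.random() < cx_frac:
                    cand = rng.integers(0, cfg.population_size, cfg.tournament)
                    p2 = pop[cand[np.argmin(fit[cand])]]
                    w = rng.random(ndim) * 1.5 - 0.25   # blend-alpha crossover
                    child = p1 + w * (p2 - p1)
                else:
                    child = p1 + rng.normal(0.0, cfg.mutation_sigma, ndim) * (hi - lo)
                children[j] = np.clip(child, lo, hi)
            new_fit = np.empty(cfg.population_size)
            new_fit[:cfg.elite] = fit[elite_idx]
            for j in range(cfg.elite, cfg.population_size):
                new_fit[j] = fun(children[j])
            n_evals += cfg.population_size - cfg.elite
            pop, fit = children, new_fit

        ibest = int(np.argmin(fit))
        f_best = float(fit[ibest])
        trace.append(f_best)
        if f_best <= 0.0:
            break
        if f_best >= best_prev - 1e-12:
            stall += 1
            if stall >= cfg.stall_blocks:
                break
        else:
            stall = 0
        best_prev = min(best_prev, f_best)

        # soft-boundary adaptation toward the incumbent's pressed edges
        max_adj = cfg.soft_adjust_late if late else cfg.soft_adjust_early
        xb = pop[ibest]
        span = hi - lo
        for d in range(ndim):
            if span[d] <= 0:
                continue
            shift = 0.0
            if xb[d] >= hi[d] - 0.05 * span[d]:
                shift = max_adj * span[d]
            elif xb[d] <= lo[d] + 0.05 * span[d]:
                shift = -max_adj * span[d]
            if shift:
                new_lo = np.clip(lo[d] + shift, hlo[d], hhi[d])
                new_hi = np.clip(hi[d] + shift, hlo[d], hhi[d])
                clipped = (new_lo != lo[d] + shift) or (new_hi != hi[d] + shift)
                blog.append({"block": block, "dim": d, "shift": float(shift),
                             "max_fraction": max_adj, "clipped_at_hard": bool(clipped)})
                lo[d], hi[d] = new_lo, new_hi

    ibest = int(np.argmin(fit))
    x_best, f_best = pop[ibest].copy(), float(fit[ibest])

    if cfg.polish and f_best > 0.0:
        from scipy.optimize import minimize
        budget = cfg.polish_maxfev if cfg.polish_maxfev else 60 * ndim
        # Powell handles the hinge geometry of banded losses well; restart
        # while it stalls above zero with budget left (the all-in-band zero
        # set is full-dimensional, so descent usually lands inside it).
        # Confined to the adapted soft box: line searches out to the hard
        # limits wander into extreme, numerically brutal parameter regions.
        for _ in range(3):
            if budget <= 0 or f_best <= 0.0:
                break
            res = minimize(fun, x_best, method="Powell",
                           bounds=list(zip(lo, hi)),
                           options={"maxfev": budget, "xtol": 1e-8,
                                    "ftol": 1e-12})
            n_evals += res.nfev
            budget -= res.nfev
            if res.fun < f_best - 1e-15:
                x_best, f_best = np.clip(res.x, lo, hi), float(res.fun)
            else:
                break

    return x_best, f_best, trace, blog, n_evals


# ---------------------------------------------------------------------------
# Two-stage fitting protocol
# ---------------------------------------------------------------------------

def _dataset_hash(df: pd.DataFrame) -> str:
    import hashlib
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _run_stage(params: ParamSet, dataset: pd.DataFrame, free: list[str],
               ga_cfg: GAConfig, obj_cfg: ObjectiveConfig, stage: str,
               tf_only: bool) -> tuple[ParamSet, FitReport]:
    if not free:
        raise ValueError("no free parameters for this stage")
    soft = params.soft_bounds(free)
    hard = params.hard_bounds(free)
    x0 = params.vector(free)

    def make_fun(k):
        def fun(x):
            trial = params.with_vector(x, free)
            return objective(trial, dataset, obj_cfg, band_k=k,
                             tf_only=tf_only)["total"]
        return fun

    # band-tightening schedule: a wide-band phase followed by the
    # single-standard-deviation phase seeded with the wide-band incumbent
    trace: list[float] = []
    blog: list[dict] = []
    n_evals = 0
    if obj_cfg.band_k_start != obj_cfg.band_k_end and ga_cfg.n_blocks > 1:
        import dataclasses
        wide = dataclasses.replace(ga_cfg, n_blocks=max(1, ga_cfg.n_blocks // 3),
                                   polish=False)
        x0, _, tr0, bl0, ev0 = _ga_minimize(
            make_fun(obj_cfg.band_k_start), soft, hard, wide, x0=x0)
        trace += tr0
        blog += bl0
        n_evals += ev0
    x_best, f_best, tr1, bl1, ev1 = _ga_minimize(
        make_fun(obj_cfg.band_k_end), soft, hard, ga_cfg, x0=x0)
    trace += tr1
    blog += bl1
    n_evals += ev1
    fitted = params.with_vector(x_best, free)
    parts = objective(fitted, dataset, obj_cfg, band_k=obj_cfg.band_k_end,
                      tf_only=tf_only)
    report = FitReport(stage=stage, free_names=free, best_objective=f_best,
                       objective_parts=parts, block_trace=trace,
                       boundary_log=blog, ga_config=ga_cfg.to_dict(),
                       seed=ga_cfg.seed, n_evaluations=n_evals,
                       dataset_hash=_dataset_hash(dataset))
    return fitted, report


def fit_stage1_tf(params: ParamSet, dataset: pd.DataFrame,
                  ga_cfg: GAConfig | None = None,
                  obj_cfg: ObjectiveConfig | None = None,
                  free_names: list[str] | None = None) -> tuple[ParamSet, FitReport]:
    """Stage 1: drug-kinetic and transcription-factor parameters against the
    c-Myc and Chop relative-expression time courses (days 1-3 for c-Myc,
    1-4 for Chop, all conditions)."""
    ga_cfg = ga_cfg or GAConfig()
    obj_cfg = obj_cfg or ObjectiveConfig()
    tf_rows = dataset[(dataset["modality"] == "protein_rel")
                      & dataset["species"].isin(["myc", "chop"])]
    if tf_rows.empty:
        raise ValueError("dataset has no transcription-factor rows")
    s1 = set(stage1_names(params))
    free = free_names if free_names is not None else [
        n for n in params.free_names if n in s1]
    bad = [n for n in free if n not in s1]
    if bad:
        raise ValueError(f"stage-1 free parameters must be drug/TF entries, got {bad}")
    return _run_stage(params, tf_rows, free, ga_cfg, obj_cfg, "stage1_tf",
                      tf_only=True)


def fit_stage2_full(params: ParamSet, dataset: pd.DataFrame,
                    ga_cfg: GAConfig | None = None,
                    obj_cfg: ObjectiveConfig | None = None,
                    free_names: list[str] | None = None) -> tuple[ParamSet, FitReport]:
    """Stage 2: remaining free parameters against total protein on day 3 and
    viability/counts on days 1-5, with stage-1 parameters held fixed."""
    ga_cfg = ga_cfg or GAConfig()
    obj_cfg = obj_cfg or ObjectiveConfig()
    s1 = set(stage1_names(params))
    free = free_names if free_names is not None else [
        n for n in params.free_names if n not in s1]
    rows = dataset[~((dataset["modality"] == "protein_rel")
                     & dataset["species"].isin(["myc", "chop"]))]
    return _run_stage(params, rows, free, ga_cfg, obj_cfg, "stage2_full",
                      tf_only=False)
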