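"""Quasi-steady-state initialization of the untreated system.

Construction, in order:

1. Transcription factors start at their basal production/degradation
   balance (they set the regulated synthesis rates).
2. With binding conceptually disabled, each Bcl-2-family synthesis rate is
   fixed so production balances degradation at the configured initial free
   abundance (:func:`basal_production_rates`); this is how the maximal
   production rates in the parameter registry are anchored.
3. Free species start at those abundances; every complex, active effector,
   active Caspase-3 and cleaved pool starts at zero.  The system is then
   integrated with binding on until the protein subsystem reaches a fixed
   point.

Cell counts are excluded from the steady-state criterion: the untreated
population grows exponentially by design, so it cannot be part of a fixed
point.  The returned state seeds every treatment simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ParamSet
from .ratelaws import RhsSwitches, basal_tf_levels, make_rhs
from .states import IDX, N_STATES, PROTEIN_STATES, state_template

_PROTEIN_IDX = [IDX[n] for n in PROTEIN_STATES]


class EquilibrationError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class SteadyState:
    state: np.ndarray
    residual_maxnorm: float     # nM/h over protein states
    time_to_converge_h: float


def basal_production_rates(free_levels: dict[str, float],
                           degradation_rates: dict[str, float]) -> dict[str, float]:
    """Net production rate balancing degradation at the initial abundance,
    with binding disabled: p_i = delta_i * x_i0."""
    out = {}
    for name, x0 in free_levels.items():
        delta = degradation_rates[name]
        if delta <= 0:
            raise ValueError(f"degradation rate for {name} must be positive")
        out[name] = delta * x0
    return out


def initial_state(params: ParamSet) -> np.ndarray:
    """Pre-relaxation state: free levels at configured abundances, TFs at
    basal balance, everything downstream at zero."""
    myc0, chop0 = basal_tf_levels(params)
    return state_template(
        myc=myc0, chop=chop0,
        bcl2_free=params["bcl2_0"], mcl1_free=params["mcl1_0"],
        bim_free=params["bim_0"], bax_inactive=params["bax_0"],
        bak_inactive=params["bak_0"], casp3_inactive=params["casp3_0"],
        n_live=params["n_live_0"], n_dead=params["n_dead_0"],
    )


def protein_residual(params: ParamSet, state: np.ndarray,
                     switches: RhsSwitches | None = None) -> float:
    """Max-norm of the derivative over the protein states (nM/h)."""
    sw = switches or RhsSwitches(population=False)
    rhs = make_rhs(params, sw)
    delayed = {prefix: 0.0 for prefix in
               ("myc_ven", "myc_ted", "chop_ven", "chop_ted")}
    dy = rhs(0.0, state, delayed)
    return float(np.max(np.abs(dy[_PROTEIN_IDX])))


def equilibrate(params: ParamSet, tol: float = 1e-8, t_max: float = 10_000.0,
                switches: RhsSwitches | None = None,
                rtol: float = 1e-9, atol: float = 1e-12) -> SteadyState:
    """Relax the untreated protein network to its steady state.

    Raises :class:`EquilibrationError` if the residual has not dropped
    below `tol` (nM/h, max-norm over protein states) by `t_max` hours.
    """
    sw = switches or RhsSwitches(population=False)
    rhs = make_rhs(params, sw)
    delayed = {prefix: 0.0 for prefix in
               ("myc_ven", "myc_ted", "chop_ven", "chop_ted")}

    def fun(t, y):
        return rhs(t, y, delayed)

    y = initial_state(params)
    t = 0.0
    chunk = 250.0
    residual = float(np.max(np.abs(fun(0.0, y)[_PROTEIN_IDX])))
    while t < t_max:
        t_next = min(t + chunk, t_max)
        sol = solve_ivp(fun, (t, t_next), y, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise EquilibrationError(f"relaxation failed: {sol.message}", residual)
        y = sol.y[:, -1]
        t = t_next
        residual = float(np.max(np.abs(fun(t, y)[_PROTEIN_IDX])))
        if residual < tol:
            break
        chunk = min(chunk * 2.0, 2000.0)
    if residual >= tol:
        raise EquilibrationError(
            f"no steady state by t={t_max} h (residual {residual:.3e} nM/h)",
            residual)
    y = np.where((y < 0) & (y > -10 * atol), 0.0, y)
    return SteadyState(state=y, residual_maxnorm=residual, time_to_converge_h=t)
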