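"""Rate laws of the coupled drug / ISR / apoptosis / population model.

The model couples four layers:

1. *Drug kinetics* — extracellular venetoclax and tedizolid decay first
   order and enter the cell by first-order uptake.
2. *Transcription factors* — c-Myc and Chop have basal production and
   first-order degradation; intracellular drug modulates their production
   through delayed Hill terms (both signs occur), with a superadditive
   product term on Chop so that the drug combination produces a heightened,
   sustained stress response while either monotherapy gives only a
   transient rise.
3. *Bcl-2-family network* — synthesis of Bcl-2, Mcl-1, Bim, Bax and Bak is
   regulated by c-Myc and Chop through per-edge Hill functions
   (unique (K, n) per edge); the free species interact by mass action
   (anti-apoptotic x {activator, active effector} complexes, activator x
   inactive-effector complexes, and the Bcl-2-venetoclax drug complex);
   the activator-effector complex converts catalytically, releasing Bim
   and producing active Bax/Bak; active effectors drive Caspase-3
   activation through a steep Hill term (continuous stand-in for the MOMP
   commitment point), and active Caspase-3 cleaves the anti-apoptotic
   proteins into inert pools — a positive feedback.
4. *Population* — live cells proliferate at a rate gated by free Bcl-2
   (venetoclax's metabolic effect), inhibited by intracellular tedizolid,
   and mildly boosted by c-Myc; they die at a rate driven by the active
   Caspase-3 fraction.  Dead cells accumulate from the live pool.

All concentrations are nM, time is hours.  Individual flux groups can be
switched off (see :class:`RhsSwitches`) to expose conservation laws and the
pure-binding subsystem for testing and equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .params import ParamSet
from .states import IDX, N_STATES

__all__ = [
    "hill_up", "hill_down", "regulation_factor", "max_production_rates",
    "tf_regulated_production", "binding_fluxes", "effector_activation_flux",
    "caspase_fluxes", "drug_and_tf_rhs", "proliferation_death_rates",
    "RhsSwitches", "make_rhs", "DELAY_EDGES",
    "myc_regulatory_profile", "net_survival_balance",
]

REGULATED_PROTEINS = ("bcl2", "mcl1", "bim", "bax", "bak")
_PROTEIN_ALIASES = {
    "bcl-2": "bcl2", "mcl-1": "mcl1",
    "bcl2": "bcl2", "mcl1": "mcl1", "bim": "bim", "bax": "bax", "bak": "bak",
}

# (param prefix, delayed state) pairs used by the TF layer.
DELAY_EDGES = (
    ("myc_ven", "venetoclax_int"),
    ("myc_ted", "tedizolid_int"),
    ("chop_ven", "venetoclax_int"),
    ("chop_ted", "tedizolid_int"),
)


def hill_up(x: float, K: float, n: float) -> float:
    """Activating Hill function x^n / (K^n + x^n), in [0, 1)."""
    if K <= 0 or n <= 0:
        raise ValueError(f"hill_up requires K > 0 and n > 0 (got K={K}, n={n})")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill_up requires x >= 0")
    with np.errstate(over="ignore"):
        r = np.where(x > 0, 1.0 / (1.0 + (K / np.maximum(x, 1e-300)) ** n), 0.0)
    return float(r) if r.ndim == 0 else r


def hill_down(x: float, K: float, n: float) -> float:
    """Inhibitory Hill function K^n / (K^n + x^n); hill_up + hill_down = 1."""
    h = hill_up(x, K, n)
    return 1.0 - h


# ---------------------------------------------------------------------------
# Transcription-factor regulation of Bcl-2-family synthesis
# ---------------------------------------------------------------------------

# edge table: protein -> list of (tf, direction, param prefix)
_REG_EDGES: dict[str, list[tuple[str, int, str]]] = {
    "bcl2": [("myc", +1, "reg_myc_bcl2_up"), ("myc", -1, "reg_myc_bcl2_down"),
             ("chop", -1, "reg_chop_bcl2_down")],
    "mcl1": [("myc", +1, "reg_myc_mcl1_up"), ("chop", -1, "reg_chop_mcl1_down")],
    "bim": [("myc", +1, "reg_myc_bim_up"), ("chop", +1, "reg_chop_bim_up")],
    "bax": [("myc", +1, "reg_myc_bax_up"), ("chop", +1, "reg_chop_bax_up")],
    "bak": [("myc", +1, "reg_myc_bak_up"), ("chop", +1, "reg_chop_bak_up")],
}


def regulation_factor(protein_id: str, myc: float, chop: float,
                      params: ParamSet) -> float:
    """Dimensionless multiplier on the basal synthesis rate of `protein_id`.

    Activating edges contribute (1 + amp*hill_up), inhibiting edges
    (1 - amp*hill_up) with amp < 1; edges combine multiplicatively, so the
    factor is 1 at (myc, chop) = (0, 0) and stays positive.
    """
    key = _PROTEIN_ALIASES.get(protein_id.lower())
    if key is None:
        raise KeyError(f"unknown protein {protein_id!r}")
    tf = {"myc": myc, "chop": chop}
    f = 1.0
    for tf_name, sign, prefix in _REG_EDGES[key]:
        h = hill_up(tf[tf_name], params[f"{prefix}_K"], params[f"{prefix}_n"])
        f *= 1.0 + sign * params[f"{prefix}_amp"] * h
    return f


def basal_tf_levels(params: ParamSet) -> tuple[float, float]:
    """Untreated c-Myc and Chop levels (production/degradation balance)."""
    return (params["myc_prod_basal"] / params["myc_deg"],
            params["chop_prod_basal"] / params["chop_deg"])


def max_production_rates(params: ParamSet) -> dict[str, float]:
    """Maximal synthesis rate per protein, fixed by the quasi-steady-state
    construction: at basal transcription-factor levels the regulated
    production balances degradation of the configured initial abundance."""
    myc0, chop0 = basal_tf_levels(params)
    out = {}
    for p in REGULATED_PROTEINS:
        net = params[f"{p}_deg"] * params[f"{p}_0"]
        out[p] = net / regulation_factor(p, myc0, chop0, params)
    return out


def tf_regulated_production(protein_id: str, myc: float, chop: float,
                            params: ParamSet,
                            basal_rate: float | None = None) -> float:
    """Synthesis rate (nM/h) of a Bcl-2-family protein at the given
    transcription-factor levels.  `basal_rate` defaults to the
    quasi-steady-state maximal production rate."""
    key = _PROTEIN_ALIASES.get(protein_id.lower())
    if key is None:
        raise KeyError(f"unknown protein {protein_id!r}")
    if basal_rate is None:
        basal_rate = max_production_rates(params)[key]
    return basal_rate * regulation_factor(key, myc, chop, params)


def myc_regulatory_profile(params: ParamSet, myc_grid: np.ndarray,
                           chop: float = 0.0) -> dict[str, np.ndarray]:
    """Normalized (max 1) c-Myc-dependent regulatory function per protein,
    evaluated on `myc_grid` with Chop clamped (default 0)."""
    out = {}
    for p in REGULATED_PROTEINS:
        vals = np.array([regulation_factor(p, m, chop, params) for m in myc_grid])
        out[p] = vals / vals.max()
    return out


def net_survival_balance(params: ParamSet, myc_grid: np.ndarray) -> np.ndarray:
    """Normalized pro-survival minus pro-apoptotic regulation vs c-Myc.

    The hormetic signature is a single slope-sign change on (0, myc_max):
    the balance rises through the "cancer zone" (pro-survival edges, which
    half-saturate at lower c-Myc, dominate) and falls in the "apoptosis
    zone" (pro-apoptotic edges overtake at high c-Myc).
    """
    prof = myc_regulatory_profile(params, myc_grid, chop=0.0)
    survival = (prof["bcl2"] + prof["mcl1"]) / 2.0
    apoptosis = (prof["bim"] + prof["bax"] + prof["bak"]) / 3.0
    return survival - apoptosis


# ---------------------------------------------------------------------------
# Mass-action binding network
# ---------------------------------------------------------------------------

# (pair key, species A, species B, complex) — all mass action A + B <-> C.
# The drug pair is reservoir-buffered: the extracellular medium holds far
# more drug moles than the cellular protein pool can bind, so complex
# formation sequesters Bcl-2 without depleting the free intracellular drug
# concentration (which follows its own uptake/decay kinetics).
BUFFERED_PAIRS = ("bcl2_ven",)
BINDING_PAIRS = (
    ("bcl2_bim", "bcl2_free", "bim_free", "cx_bcl2_bim"),
    ("bcl2_baxA", "bcl2_free", "bax_active", "cx_bcl2_baxA"),
    ("bcl2_bakA", "bcl2_free", "bak_active", "cx_bcl2_bakA"),
    ("mcl1_bim", "mcl1_free", "bim_free", "cx_mcl1_bim"),
    ("mcl1_baxA", "mcl1_free", "bax_active", "cx_mcl1_baxA"),
    ("mcl1_bakA", "mcl1_free", "bak_active", "cx_mcl1_bakA"),
    ("bim_bax", "bim_free", "bax_inactive", "cx_bim_bax"),
    ("bim_bak", "bim_free", "bak_inactive", "cx_bim_bak"),
    ("bcl2_ven", "bcl2_free", "venetoclax_int", "cx_bcl2_drug"),
)


def binding_fluxes(state: np.ndarray, params: ParamSet) -> dict[str, float]:
    """Net complex-formation rate (nM/h) per pair: kon*[A]*[B] - koff*[C]."""
    out = {}
    for key, a, b, c in BINDING_PAIRS:
        out[key] = (params[f"kon_{key}"] * state[IDX[a]] * state[IDX[b]]
                    - params[f"koff_{key}"] * state[IDX[c]])
    return out


def effector_activation_flux(state: np.ndarray, params: ParamSet) -> dict[str, float]:
    """Catalytic conversion of activator-effector complexes (nM/h):
    cx_bim_bax -> bim_free + bax_active, and analogously for Bak."""
    return {
        "bax": params["k_act_bax"] * state[IDX["cx_bim_bax"]],
        "bak": params["k_act_bak"] * state[IDX["cx_bim_bak"]],
    }


def caspase_fluxes(state: np.ndarray, params: ParamSet) -> dict[str, float]:
    """Caspase-3 activation/deactivation and anti-apoptotic cleavage (nM/h)."""
    eff = state[IDX["bax_active"]] + state[IDX["bak_active"]]
    act = (params["k_casp_act"] * state[IDX["casp3_inactive"]]
           * hill_up(eff, params["K_momp"], params["momp_n"]))
    c3a = state[IDX["casp3_active"]]
    return {
        "activation": act,
        "deactivation": params["k_casp_deact"] * c3a,
        "cleave_bcl2": params["k_cleave_bcl2"] * c3a * state[IDX["bcl2_free"]],
        "cleave_mcl1": params["k_cleave_mcl1"] * c3a * state[IDX["mcl1_free"]],
    }


# ---------------------------------------------------------------------------
# Drug and transcription-factor layer
# ---------------------------------------------------------------------------

def drug_and_tf_rhs(t: float, state: np.ndarray,
                    delayed: dict[str, float], params: ParamSet) -> dict[str, float]:
    """Derivative contributions of the drug-uptake and TF layer.

    `delayed` maps each edge prefix in :data:`DELAY_EDGES` to the relevant
    intracellular drug concentration at t - tau for that edge.
    """
    for prefix, _ in DELAY_EDGES:
        if prefix not in delayed:
            raise KeyError(f"missing delayed value for edge {prefix}")
    ve, vi = state[IDX["venetoclax_ext"]], state[IDX["venetoclax_int"]]
    te, ti = state[IDX["tedizolid_ext"]], state[IDX["tedizolid_int"]]

    d_ve = -(params["ven_k_uptake"] + params["ven_k_decay_ext"]) * ve
    d_vi = params["ven_k_uptake"] * ve - params["ven_k_decay_int"] * vi
    d_te = -(params["ted_k_uptake"] + params["ted_k_decay_ext"]) * te
    d_ti = params["ted_k_uptake"] * te - params["ted_k_decay_int"] * ti

    h = {p: hill_up(delayed[p], params[f"{p}_K"], params[f"{p}_n"])
         for p, _ in DELAY_EDGES}
    myc_prod = (params["myc_prod_basal"]
                * (1.0 + params["myc_ven_amp"] * h["myc_ven"])
                * (1.0 + params["myc_ted_amp"] * h["myc_ted"]))
    chop_prod = params["chop_prod_basal"] * (
        1.0 + params["chop_ven_amp"] * h["chop_ven"]
        + params["chop_ted_amp"] * h["chop_ted"]
        + params["chop_syn_amp"] * h["chop_ven"] * h["chop_ted"])

    return {
        "venetoclax_ext": d_ve, "venetoclax_int": d_vi,
        "tedizolid_ext": d_te, "tedizolid_int": d_ti,
        "myc": myc_prod - params["myc_deg"] * state[IDX["myc"]],
        "chop": chop_prod - params["chop_deg"] * state[IDX["chop"]],
    }


def proliferation_death_rates(state: np.ndarray, params: ParamSet) -> dict[str, float]:
    """Per-capita proliferation g and death d (1/h)."""
    casp_total = state[IDX["casp3_inactive"]] + state[IDX["casp3_active"]]
    if casp_total <= 0:
        raise ValueError("total Caspase-3 must be positive")
    g = (params["g0"]
         * hill_up(state[IDX["bcl2_free"]], params["growth_bcl2_K"], params["growth_bcl2_n"])
         * hill_down(state[IDX["tedizolid_int"]], params["growth_ted_K"], params["growth_ted_n"])
         * (1.0 + params["growth_myc_amp"]
            * hill_up(state[IDX["myc"]], params["growth_myc_K"], params["growth_myc_n"])))
    frac = state[IDX["casp3_active"]] / casp_total
    d = params["d0"] + params["d_max"] * hill_up(frac, params["death_frac_K"], params["death_frac_n"])
    return {"g": g, "d": d}


# ---------------------------------------------------------------------------
# Full right-hand side
# ---------------------------------------------------------------------------

@dataclass
class RhsSwitches:
    """Flux-group toggles; defaults run the full model.

    `mcl1_chop_drive`: optional callable t -> Chop-equivalent concentration
    used *only* in the Chop->Mcl-1 inhibitory edge (the virtual Mcl-1
    inhibitor counterfactual); every other Chop effect uses the state.
    """
    synthesis: bool = True
    degradation: bool = True
    binding: bool = True
    activation: bool = True
    cleavage: bool = True
    caspase: bool = True
    drugs: bool = True
    population: bool = True
    mcl1_chop_drive: Callable[[float], float] | None = None


def make_rhs(params: ParamSet, switches: RhsSwitches | None = None):
    """Build the fast 28-component derivative function.

    Returns ``rhs(t, y, delayed)`` where `delayed` maps each delay-edge
    prefix to the delayed intracellular drug concentration.  All parameter
    values are captured as floats at build time, so a ParamSet edit after
    construction does not propagate (rebuild instead).
    """
    sw = switches or RhsSwitches()
    p = params.values_dict()
    I = IDX

    prod_max = max_production_rates(params)
    reg_params = {prot: [(tf, sign, p[f"{pre}_amp"], p[f"{pre}_K"], p[f"{pre}_n"])
                         for tf, sign, pre in _REG_EDGES[prot]]
                  for prot in REGULATED_PROTEINS}
    synth_table = [(I[target], prod_max[prot], reg_params[prot])
                   for prot, target in (("bcl2", "bcl2_free"), ("mcl1", "mcl1_free"),
                                        ("bim", "bim_free"), ("bax", "bax_inactive"),
                                        ("bak", "bak_inactive"))]
    bind = [(I[a], I[b], I[c], p[f"kon_{k}"], p[f"koff_{k}"],
             k in BUFFERED_PAIRS)
            for k, a, b, c in BINDING_PAIRS]
    drive = sw.mcl1_chop_drive

    # hoisted rate constants (local floats: the rhs is called ~1e4 times per
    # simulation and dict lookups dominate otherwise)
    kup_v = p["ven_k_uptake"]; kde_v = p["ven_k_decay_ext"]; kdi_v = p["ven_k_decay_int"]
    kup_t = p["ted_k_uptake"]; kde_t = p["ted_k_decay_ext"]; kdi_t = p["ted_k_decay_int"]
    myc_prod = p["myc_prod_basal"]; myc_deg = p["myc_deg"]
    chop_prod = p["chop_prod_basal"]; chop_deg = p["chop_deg"]
    amv = p["myc_ven_amp"]; Kmv = p["myc_ven_K"]; nmv = p["myc_ven_n"]
    amt = p["myc_ted_amp"]; Kmt = p["myc_ted_K"]; nmt = p["myc_ted_n"]
    acv = p["chop_ven_amp"]; Kcv = p["chop_ven_K"]; ncv = p["chop_ven_n"]
    act = p["chop_ted_amp"]; Kct = p["chop_ted_K"]; nct = p["chop_ted_n"]
    asyn = p["chop_syn_amp"]
    d_bcl2 = p["bcl2_deg"]; d_mcl1 = p["mcl1_deg"]; d_bim = p["bim_deg"]
    d_bax = p["bax_deg"]; d_bak = p["bak_deg"]
    d_baxA = p["baxA_deg"]; d_bakA = p["bakA_deg"]
    kcx = p["cx_deg"]; d_clv = p["cleaved_deg"]
    k_abx = p["k_act_bax"]; k_abk = p["k_act_bak"]
    k_c3 = p["k_casp_act"]; K_mp = p["K_momp"]; n_mp = p["momp_n"]
    k_dc3 = p["k_casp_deact"]
    k_clb = p["k_cleave_bcl2"]; k_clm = p["k_cleave_mcl1"]
    g0 = p["g0"]; Kgb = p["growth_bcl2_K"]; ngb = p["growth_bcl2_n"]
    Kgt = p["growth_ted_K"]; ngt = p["growth_ted_n"]
    agm = p["growth_myc_amp"]; Kgm = p["growth_myc_K"]; ngm = p["growth_myc_n"]
    d0 = p["d0"]; dmax = p["d_max"]; Kdf = p["death_frac_K"]; ndf = p["death_frac_n"]

    s_drugs = sw.drugs; s_synth = sw.synthesis; s_deg = sw.degradation
    s_bind = sw.binding; s_act = sw.activation; s_casp = sw.caspase
    s_clv = sw.cleavage; s_pop = sw.population

    def _hill(x, K, n):
        if x <= 0.0:
            return 0.0
        return 1.0 / (1.0 + (K / x) ** n)

    def rhs(t: float, y: np.ndarray, delayed: dict[str, float]) -> np.ndarray:
        if not np.isfinite(y.sum()):
            raise FloatingPointError(f"non-finite state at t={t}")
        dy = np.zeros(N_STATES)
        myc, chop = y[4], y[5]

        # drugs and transcription factors
        if s_drugs:
            dy[0] = -(kup_v + kde_v) * y[0]
            dy[1] = kup_v * y[0] - kdi_v * y[1]
            dy[2] = -(kup_t + kde_t) * y[2]
            dy[3] = kup_t * y[2] - kdi_t * y[3]
            hcv = _hill(delayed["chop_ven"], Kcv, ncv)
            hct = _hill(delayed["chop_ted"], Kct, nct)
            dy[4] = (myc_prod * (1.0 + amv * _hill(delayed["myc_ven"], Kmv, nmv))
                     * (1.0 + amt * _hill(delayed["myc_ted"], Kmt, nmt))
                     - myc_deg * myc)
            dy[5] = (chop_prod * (1.0 + acv * hcv + act * hct + asyn * hcv * hct)
                     - chop_deg * chop)
        else:
            dy[4] = myc_prod - myc_deg * myc
            dy[5] = chop_prod - chop_deg * chop

        # synthesis with transcription-factor regulation
        if s_synth:
            for target, pmax, edges in synth_table:
                f = 1.0
                for tf, sign, amp, K, n in edges:
                    x = myc if tf == "myc" else chop
                    if drive is not None and target == 7 and tf == "chop":
                        x = drive(t)
                    f *= 1.0 + sign * amp * _hill(x, K, n)
                dy[target] += pmax * f

        # degradation of free species, complexes and cleaved pools
        if s_deg:
            dy[6] -= d_bcl2 * y[6]
            dy[7] -= d_mcl1 * y[7]
            dy[8] -= d_bim * y[8]
            dy[9] -= d_bax * y[9]
            dy[10] -= d_bak * y[10]
            dy[11] -= d_baxA * y[11]
            dy[12] -= d_bakA * y[12]
            for ci in range(13, 22):
                dy[ci] -= kcx * y[ci]
            dy[24] -= d_clv * y[24]
            dy[25] -= d_clv * y[25]

        # mass-action binding (the drug pair is reservoir-buffered)
        if s_bind:
            for ia, ib, ic, kon, koff, buffered in bind:
                flux = kon * y[ia] * y[ib] - koff * y[ic]
                dy[ia] -= flux
                if not buffered:
                    dy[ib] -= flux
                dy[ic] += flux

        # catalytic effector activation (releases the activator)
        if s_act:
            fx = k_abx * y[19]
            dy[19] -= fx
            dy[8] += fx
            dy[11] += fx
            fk = k_abk * y[20]
            dy[20] -= fk
            dy[8] += fk
            dy[12] += fk

        # caspase module and anti-apoptotic cleavage feedback
        if s_casp:
            act_flux = k_c3 * y[22] * _hill(y[11] + y[12], K_mp, n_mp)
            deact = k_dc3 * y[23]
            dy[22] += deact - act_flux
            dy[23] += act_flux - deact
        if s_clv:
            clb = k_clb * y[23] * y[6]
            clm = k_clm * y[23] * y[7]
            dy[6] -= clb
            dy[24] += clb
            dy[7] -= clm
            dy[25] += clm

        # population
        if s_pop:
            ct = y[22] + y[23]
            g = (g0 * _hill(y[6], Kgb, ngb)
                 * (1.0 - _hill(y[3], Kgt, ngt))
                 * (1.0 + agm * _hill(myc, Kgm, ngm)))
            dd = d0 + dmax * _hill(y[23] / ct, Kdf, ndf)
            dy[26] = (g - dd) * y[26]
            dy[27] = dd * y[26]
        return dy

    return rhs


def drug_and_tf_rhs_fast(t, y, delayed, p, _hill):
    """Scalar-path version of :func:`drug_and_tf_rhs` used inside the solver
    loop (same formulas, no dict assembly)."""
    ve, vi, te, ti = y[0], y[1], y[2], y[3]
    d_ve = -(p["ven_k_uptake"] + p["ven_k_decay_ext"]) * ve
    d_vi = p["ven_k_uptake"] * ve - p["ven_k_decay_int"] * vi
    d_te = -(p["ted_k_uptake"] + p["ted_k_decay_ext"]) * te
    d_ti = p["ted_k_uptake"] * te - p["ted_k_decay_int"] * ti
    hmv = _hill(delayed["myc_ven"], p["myc_ven_K"], p["myc_ven_n"])
    hmt = _hill(delayed["myc_ted"], p["myc_ted_K"], p["myc_ted_n"])
    hcv = _hill(delayed["chop_ven"], p["chop_ven_K"], p["chop_ven_n"])
    hct = _hill(delayed["chop_ted"], p["chop_ted_K"], p["chop_ted_n"])
    d_myc = (p["myc_prod_basal"] * (1.0 + p["myc_ven_amp"] * hmv)
             * (1.0 + p["myc_ted_amp"] * hmt) - p["myc_deg"] * y[4])
    d_chop = (p["chop_prod_basal"]
              * (1.0 + p["chop_ven_amp"] * hcv + p["chop_ted_amp"] * hct
                 + p["chop_syn_amp"] * hcv * hct)
              - p["chop_deg"] * y[5])
    return d_ve, d_vi, d_te, d_ti, d_myc, d_chop
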