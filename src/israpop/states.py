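"""State-vector registry for the coupled drug/ISR/apoptosis/population model.

The dynamical state has 28 components: two drugs each with an extracellular
and intracellular pool, the transcription factors c-Myc and Chop, the free
Bcl-2-family species (anti-apoptotic Bcl-2 and Mcl-1, activator Bim,
effectors Bax and Bak in inactive and active forms), the mass-action
protein complexes among them, the Bcl-2-venetoclax drug complex, the
Caspase-3 pools, the caspase-cleaved (inert) anti-apoptotic pools, and the
live/dead cell counts.

Concentrations are in nM; cell counts are dimensionless; time is in hours.
"""

from __future__ import annotations

import numpy as np

STATE_NAMES: tuple[str, ...] = (
    # drug pools
    "venetoclax_ext",
    "venetoclax_int",
    "tedizolid_ext",
    "tedizolid_int",
    # transcription factors
    "myc",
    "chop",
    # free Bcl-2 family species
    "bcl2_free",
    "mcl1_free",
    "bim_free",
    "bax_inactive",
    "bak_inactive",
    "bax_active",
    "bak_active",
    # protein complexes
    "cx_bcl2_bim",
    "cx_bcl2_baxA",
    "cx_bcl2_bakA",
    "cx_mcl1_bim",
    "cx_mcl1_baxA",
    "cx_mcl1_bakA",
    "cx_bim_bax",
    "cx_bim_bak",
    # drug complex
    "cx_bcl2_drug",
    # caspase pools
    "casp3_inactive",
    "casp3_active",
    # cleaved anti-apoptotic pools
    "bcl2_cleaved",
    "mcl1_cleaved",
    # cell populations
    "n_live",
    "n_dead",
)

N_STATES = len(STATE_NAMES)
assert N_STATES == 28

IDX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

# Conservation groups: every pool a protein molecule can occupy.  With
# synthesis, degradation, activation and cleavage fluxes switched off, the
# sum over each group is a conserved quantity of the binding subsystem.
TOTALS: dict[str, tuple[str, ...]] = {
    "bcl2": ("bcl2_free", "cx_bcl2_bim", "cx_bcl2_baxA", "cx_bcl2_bakA",
             "cx_bcl2_drug", "bcl2_cleaved"),
    "mcl1": ("mcl1_free", "cx_mcl1_bim", "cx_mcl1_baxA", "cx_mcl1_bakA",
             "mcl1_cleaved"),
    "bim": ("bim_free", "cx_bcl2_bim", "cx_mcl1_bim", "cx_bim_bax",
            "cx_bim_bak"),
    "bax": ("bax_inactive", "bax_active", "cx_bim_bax", "cx_bcl2_baxA",
            "cx_mcl1_baxA"),
    "bak": ("bak_inactive", "bak_active", "cx_bim_bak", "cx_bcl2_bakA",
            "cx_mcl1_bakA"),
    "casp3": ("casp3_inactive", "casp3_active"),
}

# Total-protein readouts reported experimentally (free + complexed + cleaved),
# matching blot-style totals.
OBSERVABLE_TOTALS = TOTALS

PROTEIN_STATES: tuple[str, ...] = tuple(
    n for n in STATE_NAMES if n not in ("n_live", "n_dead")
)


def state_template(**values: float) -> np.ndarray:
    """Return a zero state vector with any named components filled in."""
    y = np.zeros(N_STATES)
    for name, v in values.items():
        y[IDX[name]] = float(v)
    return y


def total(y: np.ndarray, protein: str) -> float | np.ndarray:
    """Total abundance of `protein` across all pools (works on a state vector
    or a (n_times, 28) trajectory matrix)."""
    members = TOTALS[protein]
    cols = [IDX[m] for m in members]
    arr = np.asarray(y)
    if arr.ndim == 1:
        return float(arr[cols].sum())
    return arr[:, cols].sum(axis=1)
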