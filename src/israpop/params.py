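"""Named kinetic parameters with bounds and fixed/free status.

Every rate constant, half-saturation constant, Hill coefficient, delay and
initial abundance of the model lives in a :class:`ParamSet`.  Each entry
carries soft bounds (the genetic algorithm's current search range, adapted
between blocks) inside hard bounds (biological plausibility limits that are
never crossed).  Hill coefficients are capped at ``HILL_N_MAX`` everywhere:
sharper response functions than that buy nothing biologically and degrade
the conditioning of the stiff integration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

HILL_N_MAX = 10.0

_CSV_COLUMNS = ["name", "value", "units", "status",
                "soft_lo", "soft_hi", "hard_lo", "hard_hi"]


@dataclass
class Param:
    name: str
    value: float
    units: str = ""
    status: str = "free"          # "fixed" | "free"
    soft_lo: float = np.nan
    soft_hi: float = np.nan
    hard_lo: float = np.nan
    hard_hi: float = np.nan

    def __post_init__(self) -> None:
        if self.status not in ("fixed", "free"):
            raise ValueError(f"{self.name}: status must be fixed|free")
        if np.isnan(self.soft_lo):
            self.soft_lo = self.value * 0.5
        if np.isnan(self.soft_hi):
            self.soft_hi = self.value * 2.0
        if np.isnan(self.hard_lo):
            self.hard_lo = self.soft_lo * 0.1
        if np.isnan(self.hard_hi):
            self.hard_hi = self.soft_hi * 10.0
        if not (self.hard_lo <= self.soft_lo <= self.soft_hi <= self.hard_hi):
            raise ValueError(
                f"{self.name}: bounds must nest hard_lo<=soft_lo<=soft_hi<=hard_hi, "
                f"got {self.hard_lo}, {self.soft_lo}, {self.soft_hi}, {self.hard_hi}"
            )


class ParamSet:
    """Ordered mapping of named :class:`Param` entries.

    ``ps["k"]`` returns the value; ``ps.entry("k")`` the full record.
    """

    def __init__(self, entries: list[Param]):
        self._entries: dict[str, Param] = {}
        for e in entries:
            if e.name in self._entries:
                raise ValueError(f"duplicate parameter {e.name}")
            self._entries[e.name] = e

    # -- mapping surface ---------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._entries[name].value

    def __setitem__(self, name: str, value: float) -> None:
        self._entries[name].value = float(value)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def entry(self, name: str) -> Param:
        return self._entries[name]

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def free_names(self) -> list[str]:
        return [n for n, e in self._entries.items() if e.status == "free"]

    @property
    def fixed_names(self) -> list[str]:
        return [n for n, e in self._entries.items() if e.status == "fixed"]

    def copy(self) -> "ParamSet":
        return ParamSet([replace(e) for e in self._entries.values()])

    def set_status(self, names, status: str) -> None:
        for n in names:
            self._entries[n].status = status

    def values_dict(self) -> dict[str, float]:
        return {n: e.value for n, e in self._entries.items()}

    # -- vector view (for optimizers / sensitivity) ------------------------
    def vector(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.free_names
        return np.array([self._entries[n].value for n in names])

    def with_vector(self, values: np.ndarray, names: list[str] | None = None) -> "ParamSet":
        names = names if names is not None else self.free_names
        out = self.copy()
        for n, v in zip(names, values, strict=True):
            out[n] = v
        return out

    def soft_bounds(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.free_names
        return np.array([[self._entries[n].soft_lo, self._entries[n].soft_hi]
                         for n in names])

    def hard_bounds(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.free_names
        return np.array([[self._entries[n].hard_lo, self._entries[n].hard_hi]
                         for n in names])

    def hash(self) -> str:
        import hashlib
        payload = json.dumps(self.values_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # -- serialization -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = [[e.name, e.value, e.units, e.status,
                 e.soft_lo, e.soft_hi, e.hard_lo, e.hard_hi]
                for e in self._entries.values()]
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        # %.17g keeps every float bit-exact through the round trip
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ParamSet":
        entries = [Param(r["name"], float(r["value"]), str(r["units"]) if pd.notna(r["units"]) else "",
                         str(r["status"]), float(r["soft_lo"]), float(r["soft_hi"]),
                         float(r["hard_lo"]), float(r["hard_hi"]))
                   for _, r in df.iterrows()]
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "ParamSet":
        # round_trip parsing: the default float reader loses the last ulp
        return cls.from_dataframe(pd.read_csv(path, keep_default_na=True,
                                              float_precision="round_trip"))

    def to_json(self, path) -> None:
        payload = [vars(e) for e in self._entries.values()]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ParamSet":
        payload = json.loads(Path(path).read_text())
        return cls([Param(**d) for d in payload])

    def validate(self) -> None:
        """Check the structural invariants of the registry."""
        for e in self._entries.values():
            if e.name.endswith("_n") or "_n_" in e.name:
                pass
            if not (e.hard_lo <= e.value <= e.hard_hi):
                raise ValueError(f"{e.name}={e.value} outside hard bounds "
                                 f"[{e.hard_lo}, {e.hard_hi}]")
        for n in self.names:
            if _is_hill_coeff(n) and self[n] > HILL_N_MAX:
                raise ValueError(f"{n}={self[n]} exceeds Hill cutoff {HILL_N_MAX}")
            if _is_rate(n) and self[n] < 0:
                raise ValueError(f"rate {n} must be positive")


def _is_hill_coeff(name: str) -> bool:
    return name.endswith("_n")


def _is_rate(name: str) -> bool:
    return name.startswith(("k_", "kon_", "koff_")) or name.endswith(("_deg", "_uptake"))


# ---------------------------------------------------------------------------
# Registry construction
# ---------------------------------------------------------------------------

def _p(name, value, units, status="free", soft=None, hard=None) -> Param:
    s = soft if soft is not None else (value * 0.5, value * 2.0)
    h = hard if hard is not None else (s[0] * 0.1, s[1] * 10.0)
    return Param(name, value, units, status, s[0], s[1], h[0], h[1])


def _hill(name_prefix, amp, K, n, status="free", amp_soft=None) -> list[Param]:
    """One transcription-factor regulatory edge: amplitude, half-saturation, Hill n."""
    out = []
    a_soft = amp_soft if amp_soft is not None else (amp * 0.5, min(amp * 2.0, 0.99) if amp < 1 else amp * 2.0)
    # inhibitory-edge amplitudes stay in (-1, 1] so factors remain positive
    a_hard = (-0.99, max(a_soft[1], 0.0)) if a_soft[0] < 0 else (
        (0.0, 1.0) if a_soft[1] <= 1.0 else (0.0, a_soft[1] * 10))
    out.append(_p(f"{name_prefix}_amp", amp, "-", status, soft=a_soft, hard=a_hard))
    out.append(_p(f"{name_prefix}_K", K, "nM", status))
    out.append(Param(f"{name_prefix}_n", n, "-", status,
                     max(0.5, n * 0.5), min(HILL_N_MAX, n * 2.0), 0.5, HILL_N_MAX))
    return out


def default_params() -> ParamSet:
    """The template registry: every model parameter with nominal value, units,
    status and bounds.  The shipped calibrated set refines the free entries."""
    P: list[Param] = []

    # ---- drug kinetics (first-order uptake and decay), per drug ----------
    for drug, kup, kde, kdi in [("ven", 0.10, 0.030, 0.020),
                                ("ted", 0.03, 0.010, 0.010)]:
        P += [
            _p(f"{drug}_k_uptake", kup, "1/h"),
            _p(f"{drug}_k_decay_ext", kde, "1/h"),
            _p(f"{drug}_k_decay_int", kdi, "1/h"),
        ]

    # ---- transcription factors -------------------------------------------
    P += [
        _p("myc_prod_basal", 20.0, "nM/h"),
        _p("myc_deg", 0.20, "1/h"),
        _p("chop_prod_basal", 5.0, "nM/h"),
        _p("chop_deg", 0.25, "1/h"),
    ]
    # drug -> TF edges: signed amplitude, half-saturation in intracellular
    # drug concentration, Hill n, transport/transcription delay tau (h).
    P += _hill("myc_ven", 0.30, 200.0, 2.0, amp_soft=(0.0, 1.0))
    P += _hill("myc_ted", -0.40, 1200.0, 2.0, amp_soft=(-0.9, 0.0))
    P += _hill("chop_ven", 1.0, 200.0, 2.0, amp_soft=(0.0, 4.0))
    P += _hill("chop_ted", 2.5, 1500.0, 2.0, amp_soft=(0.5, 8.0))
    P += [_p("chop_syn_amp", 9.0, "-", soft=(1.0, 20.0))]
    P += [
        _p("myc_ven_tau", 6.0, "h", soft=(0.0, 24.0), hard=(0.0, 48.0)),
        _p("myc_ted_tau", 6.0, "h", soft=(0.0, 24.0), hard=(0.0, 48.0)),
        _p("chop_ven_tau", 8.0, "h", soft=(0.0, 24.0), hard=(0.0, 48.0)),
        _p("chop_ted_tau", 12.0, "h", soft=(0.0, 24.0), hard=(0.0, 48.0)),
    ]

    # ---- Bcl-2 family initial abundances (untreated free levels, nM) ------
    P += [
        _p("bcl2_0", 120.0, "nM"),
        _p("mcl1_0", 150.0, "nM"),
        _p("bim_0", 80.0, "nM"),
        _p("bax_0", 100.0, "nM"),
        _p("bak_0", 100.0, "nM"),
        _p("casp3_0", 100.0, "nM", status="fixed"),
    ]

    # ---- degradation rates (1/h); Mcl-1 is the short-lived one ------------
    P += [
        _p("bcl2_deg", 0.08, "1/h"),
        _p("mcl1_deg", 0.35, "1/h"),
        _p("bim_deg", 0.12, "1/h"),
        _p("bax_deg", 0.05, "1/h"),
        _p("bak_deg", 0.05, "1/h"),
        _p("baxA_deg", 0.10, "1/h"),
        _p("bakA_deg", 0.10, "1/h"),
        _p("cx_deg", 0.10, "1/h"),
        _p("cleaved_deg", 0.10, "1/h"),
    ]

    # ---- transcription-factor -> Bcl-2-family regulatory edges ------------
    # Unique (K, n) per edge.  Pro-survival c-Myc edges saturate at lower
    # c-Myc (smaller K) than the pro-apoptotic ones: this ordering produces
    # the hormetic cancer-zone / apoptosis-zone profile.
    P += _hill("reg_myc_bcl2_up", 1.5, 80.0, 2.0, amp_soft=(0.2, 4.0))
    P += _hill("reg_myc_bcl2_down", 0.70, 400.0, 4.0, amp_soft=(0.1, 0.95))
    P += _hill("reg_myc_mcl1_up", 1.2, 100.0, 2.0, amp_soft=(0.2, 4.0))
    P += _hill("reg_myc_bim_up", 1.5, 300.0, 4.0, amp_soft=(0.2, 4.0))
    P += _hill("reg_myc_bax_up", 1.2, 350.0, 4.0, amp_soft=(0.2, 4.0))
    P += _hill("reg_myc_bak_up", 1.2, 320.0, 4.0, amp_soft=(0.2, 4.0))
    P += _hill("reg_chop_bim_up", 1.0, 100.0, 2.0, amp_soft=(0.2, 4.0))
    P += _hill("reg_chop_bak_up", 1.5, 100.0, 2.0, amp_soft=(0.2, 6.0))
    P += _hill("reg_chop_bax_up", 0.20, 150.0, 2.0, amp_soft=(0.0, 1.0))
    P += _hill("reg_chop_mcl1_down", 0.95, 60.0, 2.0, amp_soft=(0.1, 0.98))
    P += _hill("reg_chop_bcl2_down", 0.10, 150.0, 2.0, amp_soft=(0.0, 0.5))

    # ---- binding on/off rates (mass action); K_D = koff/kon ---------------
    # Literature-range dissociation constants; venetoclax-Bcl-2 K_D is the
    # smallest by construction (high-affinity BH3 mimetic).
    binding = [
        ("bcl2_bim", 1.0, 10.0),
        ("bcl2_baxA", 1.0, 15.0),
        ("bcl2_bakA", 1.0, 15.0),
        ("mcl1_bim", 1.0, 10.0),
        ("mcl1_baxA", 1.0, 25.0),
        ("mcl1_bakA", 1.0, 20.0),
        ("bim_bax", 0.5, 100.0),
        ("bim_bak", 0.5, 100.0),
        ("bcl2_ven", 2.0, 1.0),
    ]
    for pair, kon, kd in binding:
        P += [
            _p(f"kon_{pair}", kon, "1/(nM h)", status="fixed"),
            _p(f"koff_{pair}", kon * kd, "1/h", status="fixed"),
        ]

    # ---- effector activation and caspase module ----------------------------
    P += [
        _p("k_act_bax", 0.5, "1/h"),
        _p("k_act_bak", 0.5, "1/h"),
        _p("k_casp_act", 0.7, "1/h"),
        _p("K_momp", 50.0, "nM"),
        Param("momp_n", 4.0, "-", "free", 2.0, 8.0, 2.0, HILL_N_MAX),
        _p("k_casp_deact", 0.08, "1/h"),
        _p("k_cleave_bcl2", 0.010, "1/(nM h)"),
        _p("k_cleave_mcl1", 0.010, "1/(nM h)"),
    ]

    # ---- proliferation / death ---------------------------------------------
    P += [
        _p("g0", 0.032, "1/h"),
        _p("growth_bcl2_K", 3.0, "nM"),
        Param("growth_bcl2_n", 1.0, "-", "free", 0.5, 2.0, 0.5, HILL_N_MAX),
        _p("growth_ted_K", 600.0, "nM"),
        Param("growth_ted_n", 1.5, "-", "free", 0.5, 4.0, 0.5, HILL_N_MAX),
        _p("growth_myc_amp", 0.20, "-", soft=(0.0, 1.0), hard=(0.0, 5.0)),
        _p("growth_myc_K", 150.0, "nM"),
        Param("growth_myc_n", 2.0, "-", "free", 1.0, 4.0, 0.5, HILL_N_MAX),
        _p("d0", 0.001, "1/h"),
        _p("d_max", 0.04, "1/h"),
        _p("death_frac_K", 0.02, "-"),
        Param("death_frac_n", 3.0, "-", "free", 1.0, 6.0, 0.5, HILL_N_MAX),
        _p("n_live_0", 1.0, "-", status="fixed"),
        _p("n_dead_0", 0.02, "-", status="fixed"),
    ]

    ps = ParamSet(P)
    ps.validate()
    return ps


# The drug/TF parameters estimated in calibration stage 1 (all drug-kinetic
# and transcription-factor entries); everything downstream is stage 2.
def stage1_names(ps: ParamSet) -> list[str]:
    pref = ("ven_k_", "ted_k_", "myc_", "chop_")
    return [n for n in ps.names if n.startswith(pref)]


def nominal_params() -> ParamSet:
    """The calibrated nominal set shipped with the package (falls back to the
    template registry if the data file is absent)."""
    from importlib.resources import files
    path = files("israpop").joinpath("data/nominal_params.csv")
    try:
        with path.open() as fh:  # type: ignore[attr-defined]
            return ParamSet.from_csv(fh)
    except FileNotFoundError:
        return default_params()
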