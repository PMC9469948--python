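"""Protocol and Trajectory containers.

Time is measured in hours with t = 0 at the *main* administration (for
pre-treatment protocols the pre-treated drug is given at t = -tau and the
combination completed at t = 0); the horizon is the absolute end time on
that axis.  The output grid density is specified as points per 120 h
window and extended proportionally for longer spans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .states import IDX, N_STATES, STATE_NAMES, TOTALS, total

DEFAULT_OUTPUT_POINTS = 25_000   # per 120 h window


@dataclass(frozen=True)
class Protocol:
    """Dosing protocol: single un-replenished dose per drug, no washout."""
    venetoclax_nM: float = 0.0
    tedizolid_nM: float = 0.0
    venetoclax_time_h: float = 0.0
    tedizolid_time_h: float = 0.0
    horizon_h: float = 120.0
    output_points: int = DEFAULT_OUTPUT_POINTS
    mcl1_inhibitor_mode: bool = False
    name: str = ""

    def __post_init__(self):
        if self.venetoclax_nM < 0 or self.tedizolid_nM < 0:
            raise ValueError("doses must be non-negative")
        if self.output_points < 2:
            raise ValueError("output_points must be >= 2")
        if self.horizon_h < max(self.active_times(), default=0.0):
            raise ValueError("horizon must cover every administration time")

    def active_times(self) -> list[float]:
        out = []
        if self.venetoclax_nM > 0:
            out.append(self.venetoclax_time_h)
        if self.tedizolid_nM > 0:
            out.append(self.tedizolid_time_h)
        return out

    @property
    def t_start(self) -> float:
        return min(self.active_times(), default=0.0)

    @property
    def pretreatment_window_h(self) -> float:
        times = self.active_times()
        return max(times) - min(times) if len(times) == 2 else 0.0

    def events(self) -> list[tuple[float, str, float]]:
        """(time, external pool state name, dose) administration events."""
        ev = []
        if self.venetoclax_nM > 0:
            ev.append((self.venetoclax_time_h, "venetoclax_ext", self.venetoclax_nM))
        if self.tedizolid_nM > 0:
            ev.append((self.tedizolid_time_h, "tedizolid_ext", self.tedizolid_nM))
        return sorted(ev)

    def n_grid(self) -> int:
        span = self.horizon_h - self.t_start
        return max(2, int(round(self.output_points * span / 120.0)))

    def to_dict(self) -> dict:
        return asdict(self)


class Trajectory:
    """Solver output on a fixed time grid with derived observables."""

    def __init__(self, t: np.ndarray, y: np.ndarray, protocol: Protocol,
                 metadata: dict | None = None):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.shape != (t.size, N_STATES):
            raise ValueError(f"state matrix shape {y.shape} != ({t.size}, {N_STATES})")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        self.t = t
        self.y = y
        self.protocol = protocol
        self.metadata = metadata or {}

    def state(self, name: str) -> np.ndarray:
        return self.y[:, IDX[name]]

    def protein_total(self, protein: str) -> np.ndarray:
        return total(self.y, protein)

    @property
    def n_live(self) -> np.ndarray:
        return self.state("n_live")

    @property
    def n_dead(self) -> np.ndarray:
        return self.state("n_dead")

    @property
    def viability(self) -> np.ndarray:
        tot = self.n_live + self.n_dead
        return self.n_live / tot

    def at(self, t_query: float) -> np.ndarray:
        """State row at the grid point closest to t_query."""
        i = int(np.argmin(np.abs(self.t - t_query)))
        return self.y[i]

    def value_at(self, series: np.ndarray, t_query: float) -> float:
        i = int(np.argmin(np.abs(self.t - t_query)))
        return float(series[i])

    def window(self, t_lo: float, t_hi: float) -> "Trajectory":
        m = (self.t >= t_lo - 1e-12) & (self.t <= t_hi + 1e-12)
        return Trajectory(self.t[m], self.y[m], self.protocol, dict(self.metadata))

    # -- observables table -------------------------------------------------
    def observables(self) -> pd.DataFrame:
        cols = {"time_h": self.t}
        for prot in ("bcl2", "mcl1", "bim", "bax", "bak"):
            cols[f"{prot}_total"] = self.protein_total(prot)
        cols["casp3_active"] = self.state("casp3_active")
        cols["myc"] = self.state("myc")
        cols["chop"] = self.state("chop")
        cols["n_live"] = self.n_live
        cols["n_dead"] = self.n_dead
        cols["viability"] = self.viability
        return pd.DataFrame(cols)

    # -- serialization -----------------------------------------------------
    def to_tidy_csv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.t)
        tidy = df.melt(id_vars="time_h", var_name="variable", value_name="value")
        tidy.to_csv(path, index=False)
        if sidecar:
            meta = {"protocol": self.protocol.to_dict(), **self.metadata}
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tidy_csv(cls, path) -> "Trajectory":
        tidy = pd.read_csv(path)
        wide = tidy.pivot(index="time_h", columns="variable", values="value")
        t = wide.index.to_numpy()
        y = wide[list(STATE_NAMES)].to_numpy()
        meta_path = Path(str(path) + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        proto = Protocol(**meta.pop("protocol")) if "protocol" in meta else Protocol()
        return cls(t, y, proto, meta)
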