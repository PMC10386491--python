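"""Self-contained auxiliary computations.

* Neutralizing ion counts for solvated-system setup: the number of anions
  follows the water-molarity convention (one ion pair per 55.5 waters per
  mol/L), and the protein's net charge is compensated by extra counter-ions.
* Ramp-subtraction ΔI/V: two ramp current sweeps recorded after different
  prepulses are each normalised to their current at −130 mV, interpolated
  to a common voltage grid, and subtracted to isolate the voltage-activated
  channel component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WATER_MOLARITY",
    "RampRecording",
    "neutralizing_ion_counts",
    "ramp_delta_iv",
    "aggregate_delta_iv",
]

WATER_MOLARITY = 55.5  # mol/L


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def neutralizing_ion_counts(
    n_water: int, concentration: float, net_charge: int
) -> tuple[int, int]:
    """Cation/anion counts for a target salt concentration plus neutrality.

    ``concentration`` is in mol/L. The base salt count is
    round(n_water · c / 55.5) with half-away-from-zero rounding; a negative
    protein net charge adds the deficit to the cations, a positive one
    symmetrically to the anions. Electroneutrality
    n_cation − n_anion + net_charge = 0 holds exactly.
    """
    if n_water < 0 or concentration < 0:
        raise ValueError("water count and concentration must be non-negative")
    base = _round_half_away(n_water * concentration / WATER_MOLARITY)
    n_cation = base + max(0, -net_charge)
    n_anion = base + max(0, net_charge)
    return n_cation, n_anion


@dataclass(frozen=True)
class RampRecording:
    """One fast voltage-ramp sweep: monotone voltage (mV), current (pA)."""

    voltage: np.ndarray
    current: np.ndarray
    prepulse: str = ""  # e.g. 'pc-40' or 'pc-130'
    cell_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=np.float64)
        i = np.asarray(self.current, dtype=np.float64)
        if v.shape != i.shape or v.ndim != 1:
            raise ValueError("voltage and current must be matching 1-D arrays")
        dv = np.diff(v)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("voltage must be monotone over the ramp")
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "current", i)


def _normalised(
    rec: RampRecording, norm_voltage: float, floor: float, window: float = 0.0
) -> tuple:
    if window > 0:
        mask = np.abs(rec.voltage - norm_voltage) <= window
        if not mask.any():
            raise ValueError("no samples inside the normalization window")
        i_norm = rec.current[mask].mean()
    else:
        k = int(np.argmin(np.abs(rec.voltage - norm_voltage)))
        i_norm = rec.current[k]
    if abs(i_norm) < floor:
        raise ValueError(
            f"normalization current at {norm_voltage} mV is below floor for "
            f"sweep {rec.prepulse or '<unnamed>'}"
        )
    return rec.voltage, rec.current / i_norm


def ramp_delta_iv(
    pc40: RampRecording,
    pc130: RampRecording,
    norm_voltage: float = -130.0,
    grid: np.ndarray | None = None,
    floor: float = 1e-6,
    norm_window: float = 0.0,
) -> pd.DataFrame:
    """ΔI(V) between normalised ramp sweeps on a common voltage grid.

    Each sweep is divided by its current at the sample nearest
    ``norm_voltage`` (or the mean over ± ``norm_window`` mV when that is
    positive), linearly interpolated onto the grid (default 1 mV spacing
    over [−250, −130] mV), then ΔI(V) = norm(I_pc-130)(V) −
    norm(I_pc-40)(V). Invariant to a uniform scaling of either input
    trace.
    """
    if grid is None:
        grid = np.arange(-250.0, -130.0 + 0.5, 1.0)
    grid = np.asarray(grid, dtype=np.float64)
    for rec in (pc40, pc130):
        lo, hi = rec.voltage.min(), rec.voltage.max()
        if lo > grid.min() or hi < grid.max():
            raise ValueError("both ramps must cover the requested voltage grid")
    out = {}
    for name, rec in (("pc40", pc40), ("pc130", pc130)):
        v, i = _normalised(rec, norm_voltage, floor, norm_window)
        order = np.argsort(v)
        out[name] = np.interp(grid, v[order], i[order])
    return pd.DataFrame(
        {"voltage_mV": grid, "delta_i": out["pc130"] - out["pc40"]}
    )


def aggregate_delta_iv(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Pointwise mean ± sample SD (n−1) of per-cell ΔI/V curves.

    All curves must share the voltage grid; a single curve aggregates to
    itself with SD 0.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0]["voltage_mV"].to_numpy()
    for c in curves[1:]:
        if not np.array_equal(c["voltage_mV"].to_numpy(), grid):
            raise ValueError("voltage grids differ between curves")
    stack = np.stack([c["delta_i"].to_numpy() for c in curves])
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(len(grid))
    return pd.DataFrame(
        {"voltage_mV": grid, "mean": stack.mean(axis=0), "sd": sd, "n": len(curves)}
    )
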