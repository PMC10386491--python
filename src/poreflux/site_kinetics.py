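"""Site assignment, dwell times and permeation events from ion z-series.

The per-ion z trajectory is smoothed with a low-pass Butterworth filter
(default: third order, 10 ns⁻¹ cutoff, zero-phase) before being mapped to
discrete binding-site labels by z-interval containment. Dwell records,
multi-ion occupancy states and full Sa→cavity permeation events are then
pure functions of the label series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FilterSpec",
    "SiteBoundaries",
    "lowpass_filter",
    "derive_boundaries",
    "assign_sites",
    "extract_dwells",
    "detect_permeations",
    "occupancy_states",
    "dwell_summary",
]

#: assignable labels in +z order (extracellular -> cytosolic)
ASSIGN_ORDER = ("vestibule", "Sa", "S3", "Sb", "Sc", "cavity")
_FILTER = ("Sa", "S3", "Sb", "Sc")
_EXT = ("vestibule", "bulk_ext")
_INT = ("cavity", "bulk_int")


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth parameters for z-trajectory smoothing."""

    cutoff_ns: float = 10.0  # cutoff frequency, ns^-1
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_ns <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def lowpass_filter(z: np.ndarray, dt: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth low-pass filter a z-series sampled at spacing dt (ns).

    In zero-phase mode the filter is applied forward then backward, so the
    effective magnitude response is |H(f)|² = 1/(1 + (f/f_c)^(2·order))²
    with no group delay; causal mode is a single forward pass. The output
    has the same length as the input.
    """
    spec = spec or FilterSpec()
    z = np.asarray(z, dtype=np.float64)
    nyquist = 1.0 / (2.0 * dt)
    if spec.cutoff_ns >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_ns} ns^-1 is not below Nyquist {nyquist} ns^-1"
        )
    if z.size < 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    b, a = signal.butter(spec.order, spec.cutoff_ns / nyquist)
    if spec.zero_phase:
        return signal.filtfilt(b, a, z)
    zi = signal.lfilter_zi(b, a) * z[0]
    out, _ = signal.lfilter(b, a, z, zi=zi)
    return out


@dataclass(frozen=True)
class SiteBoundaries:
    """Contiguous half-open z-intervals for the six assignable regions.

    Intervals are [lo, hi) along +z; vestibule extends to −∞ and cavity to
    +∞. Constructed from the carbonyl plane centers via
    :func:`derive_boundaries`.
    """

    edges: tuple  # 5 interior edges between the 6 regions, increasing

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) != 5 or any(a >= b for a, b in zip(e, e[1:])):
            raise ValueError("boundary edges must be 5 strictly increasing values")

    def interval(self, site: str) -> tuple[float, float]:
        i = ASSIGN_ORDER.index(site)
        lo = -np.inf if i == 0 else self.edges[i - 1]
        hi = np.inf if i == 5 else self.edges[i]
        return lo, hi


#: default interval fractions of the plane gap g = z34 - z23
DEFAULT_FRACTIONS = {
    "sa_below_p23": 0.5,   # Sa starts 0.5 g above p23 (toward vestibule)
    "sa_above_p23": 0.25,  # Sa/S3 edge sits 0.25 g below p23
    "sb_half_width": 0.2,  # Sb spans ±0.2 g around p34
    "sc_extent": 0.8,      # Sc ends 0.8 g below p34 (toward cavity)
}


def derive_boundaries(
    z23: float, z34: float, fractions: dict | None = None
) -> SiteBoundaries:
    """Site z-windows from the p23/p34 plane centers.

    With gap g = z34 − z23 the defaults give Sa = [z23−0.5g, z23+0.25g),
    S3 = [z23+0.25g, z34−0.2g), Sb = [z34−0.2g, z34+0.2g),
    Sc = [z34+0.2g, z34+0.8g); vestibule above Sa, cavity below Sc.
    """
    if z34 <= z23:
        raise ValueError("z34 must exceed z23 along +z")
    f = {**DEFAULT_FRACTIONS, **(fractions or {})}
    g = z34 - z23
    edges = (
        z23 - f["sa_below_p23"] * g,
        z23 + f["sa_above_p23"] * g,
        z34 - f["sb_half_width"] * g,
        z34 + f["sb_half_width"] * g,
        z34 + f["sc_extent"] * g,
    )
    if any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("fraction set produces empty or inverted intervals")
    return SiteBoundaries(edges=edges)


def assign_sites(z: np.ndarray, boundaries: SiteBoundaries) -> np.ndarray:
    """Label each frame by the containing z-interval (half-open along +z)."""
    z = np.asarray(z, dtype=np.float64)
    idx = np.searchsorted(np.asarray(boundaries.edges), z, side="right")
    return np.asarray(ASSIGN_ORDER, dtype=object)[idx].astype(str)


def extract_dwells(
    labels: np.ndarray,
    times: np.ndarray,
    min_duration: float = 0.0,
    ion: int = 0,
) -> pd.DataFrame:
    """Run-length-encode a label series into dwell records.

    Each maximal constant-label run of n frames at spacing dt becomes a
    record of duration n·dt (so durations sum exactly to the covered
    span); runs shorter than ``min_duration`` ns are dropped.
    """
    labels = np.asarray(labels)
    times = np.asarray(times, dtype=np.float64)
    if labels.shape != times.shape:
        raise ValueError("labels and times must be aligned")
    if labels.size == 0:
        return pd.DataFrame(columns=["ion", "site", "t_start", "t_end", "duration"])
    dt = times[1] - times[0] if times.size > 1 else 0.0
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    t_start = times[starts]
    t_end = times[starts] + (ends - starts) * dt
    df = pd.DataFrame(
        {
            "ion": ion,
            "site": labels[starts],
            "t_start": t_start,
            "t_end": t_end,
            "duration": t_end - t_start,
        }
    )
    return df[df["duration"] >= min_duration].reset_index(drop=True)


def detect_permeations(
    labels: np.ndarray, times: np.ndarray, ion: int = 0
) -> pd.DataFrame:
    """Full filter crossings: Sa → cavity (inward) and Sc → vestibule (outward).

    An inward event is recorded when the label series visits Sa and later
    reaches the cavity without returning to the vestibule or external bulk
    in between; the outward rule is the mirror image. Events per ion are
    non-overlapping by construction.
    """
    labels = np.asarray(labels)
    times = np.asarray(times, dtype=np.float64)
    events = []
    armed_in = armed_out = None  # entry times
    prev = None
    for lab, t in zip(labels, times):
        if lab == prev:
            continue
        prev = lab
        if lab == "Sa" and armed_in is None:
            armed_in = t
        elif lab in _EXT:
            armed_in = None
            if armed_out is not None and lab == "vestibule":
                events.append((ion, armed_out, t, "outward"))
                armed_out = None
        if lab == "Sc" and armed_out is None:
            armed_out = t
        elif lab in _INT:
            armed_out = None
            if armed_in is not None and lab == "cavity":
                events.append((ion, armed_in, t, "inward"))
                armed_in = None
    return pd.DataFrame(
        events, columns=["ion", "t_enter", "t_exit", "direction"]
    )


def occupancy_states(labels_per_ion: dict | list) -> pd.DataFrame:
    """Per-frame multiset of occupied filter sites, e.g. ``{Sa,Sc}``.

    Accepts a mapping or sequence of per-ion label arrays (equal length).
    Returns a frame-indexed DataFrame with the state string and, as an
    attribute ``fractions``, the occupancy fraction of each state.
    """
    if isinstance(labels_per_ion, dict):
        series = list(labels_per_ion.values())
    else:
        series = list(labels_per_ion)
    arr = np.stack([np.asarray(s) for s in series], axis=1)
    states = []
    for row in arr:
        occ = sorted(lab for lab in row if lab in _FILTER)
        states.append("{" + ",".join(occ) + "}")
    df = pd.DataFrame({"state": states})
    df.attrs["fractions"] = df["state"].value_counts(normalize=True).to_dict()
    return df


def dwell_summary(records: pd.DataFrame, by: str | list = "site") -> pd.DataFrame:
    """Five-number boxplot statistics of dwell durations per group.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme observations within 1.5·IQR of the box, and everything beyond
    is counted as an outlier.
    """
    if records.empty:
        raise ValueError("no dwell records to summarise")

    def stats(g: pd.Series) -> pd.Series:
        d = g.to_numpy()
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = d[(d >= lo_fence) & (d <= hi_fence)]
        return pd.Series(
            {
                "n": len(d),
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_lo": inside.min(),
                "whisker_hi": inside.max(),
                "n_outliers": int(np.sum((d < lo_fence) | (d > hi_fence))),
            }
        )

    return records.groupby(by)["duration"].apply(stats).unstack()
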