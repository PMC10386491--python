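"""Filter breathing, density profiles, cavity hydration and gate distances.

The filter's structural adaptation to a bound cation is measured as the
inter-subunit distance between the carbonyl oxygens of opposing monomers
(diagonals A|C and B|D) in the p23 and p34 planes, gated on binding events
of at least 12 ns in the proximate site (Sa for p23; Sb/Sc for p34).
Along-axis occupancy is summarised as a Gaussian kernel density estimate;
cavity hydration counts waters within 5 Å of residues 507–511, and the
open/closed gate is monitored by the I511 and T515 Cα diagonal distances.
"""

from __future__ import annotations

import warnings


import numpy as np
import pandas as pd

from .trajectory_io import Selector, TrajectoryBundle, select_atoms

__all__ = [
    "interplane_distances",
    "binding_gated_histogram",
    "kde_profile",
    "cavity_hydration",
    "gating_distances",
    "DEFAULT_PAIRING",
]

#: opposing-monomer diagonals of the tetramer
DEFAULT_PAIRING = (("A", "C"), ("B", "D"))

#: plane → gating site(s): frames count toward a plane's histogram while an
#: ion dwells in a site adjacent to that plane
PLANE_GATING_SITES = {"p23": ("Sa",), "p34": ("Sb", "Sc")}


def interplane_distances(
    bundle: TrajectoryBundle,
    plane_residues: dict | None = None,
    pairing=DEFAULT_PAIRING,
) -> pd.DataFrame:
    """Per-frame opposing-monomer carbonyl-oxygen distances per plane.

    ``plane_residues`` maps plane name to the residue number whose backbone
    O defines it (default p23→480, p34→479). Exactly one plane O per chain
    is required. Returns a long DataFrame (time_ns, plane, pair, distance).
    """
    plane_residues = plane_residues or {"p23": 480, "p34": 479}
    rows = []
    for plane, resnum in plane_residues.items():
        chain_atom = {}
        for chain in {c for pair in pairing for c in pair}:
            idx = select_atoms(
                bundle.atoms,
                Selector(chain_id=chain, residue_number=resnum, atom_name="O"),
                allow_empty=True,
            )
            if idx.size != 1:
                raise ValueError(
                    f"chain {chain} must have exactly one plane O for residue "
                    f"{resnum}; found {idx.size}"
                )
            chain_atom[chain] = idx[0]
        for a, b in pairing:
            d = np.linalg.norm(
                bundle.coords[:, chain_atom[a]] - bundle.coords[:, chain_atom[b]],
                axis=1,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "time_ns": bundle.times,
                        "plane": plane,
                        "pair": f"{a}|{b}",
                        "distance": d,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def binding_gated_histogram(
    series: pd.DataFrame,
    dwells: pd.DataFrame,
    plane: str,
    min_dwell: float = 12.0,
    bin_width: float = 0.1,
    gating_sites: tuple | None = None,
) -> dict:
    """Area-normalised distance histogram gated on qualifying binding events.

    Only frames that fall inside a dwell of duration ≥ ``min_dwell`` ns in
    a site proximate to the plane contribute. Bin edges are anchored at 0
    with the given width and counts are normalised so the total histogram
    area is exactly 1. Returns a dict with ``counts``, ``edges``, the
    gated ``distances`` and an ``empty`` flag (no NaNs are produced).
    """
    gating_sites = gating_sites or PLANE_GATING_SITES[plane]
    sub = series[series["plane"] == plane]
    qual = dwells[
        (dwells["site"].isin(gating_sites)) & (dwells["duration"] >= min_dwell)
    ]
    mask = np.zeros(len(sub), dtype=bool)
    t = sub["time_ns"].to_numpy()
    for _, ev in qual.iterrows():
        mask |= (t >= ev["t_start"]) & (t < ev["t_end"])
    gated = sub.loc[mask, "distance"].to_numpy()
    if gated.size == 0:
        return {"empty": True, "counts": np.array([]), "edges": np.array([]),
                "distances": gated}
    hi = np.ceil(gated.max() / bin_width + 1) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(gated, bins=edges, density=True)
    return {"empty": False, "counts": counts, "edges": edges, "distances": gated}


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule of thumb, 1.06·σ̂·n^(−1/5)."""
    samples = np.asarray(samples, dtype=np.float64)
    return 1.06 * samples.std(ddof=1) * samples.size ** (-0.2)


def kde_profile(
    z_samples: np.ndarray,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    bandwidth_floor: float = 0.05,
) -> pd.DataFrame:
    """Gaussian kernel density estimate of along-axis occupancy.

    Bandwidth defaults to Silverman's rule; degenerate (zero-variance)
    samples fall back to ``bandwidth_floor`` (Å) with a warning. The grid
    defaults to the sample range padded by 4 bandwidths. The returned
    profile integrates to 1 over a sufficiently wide grid.
    """
    z = np.asarray(z_samples, dtype=np.float64)
    if z.size < 2:
        raise ValueError("KDE needs at least two samples")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(z)
    if bandwidth < bandwidth_floor:
        warnings.warn(
            f"degenerate samples: bandwidth floored at {bandwidth_floor} Å",
            RuntimeWarning,
        )
        bandwidth = bandwidth_floor
    if grid is None:
        pad = 4 * bandwidth
        grid = np.linspace(z.min() - pad, z.max() + pad, 512)
    grid = np.asarray(grid, dtype=np.float64)
    u = (grid[:, None] - z[None, :]) / bandwidth
    dens = np.exp(-0.5 * u**2).sum(axis=1) / (
        z.size * bandwidth * np.sqrt(2 * np.pi)
    )
    out = pd.DataFrame({"z": grid, "density": dens})
    out.attrs["bandwidth"] = bandwidth
    return out


def cavity_hydration(
    bundle: TrajectoryBundle,
    residue_window: tuple = (507, 511),
    cutoff: float = 5.0,
) -> np.ndarray:
    """Per-frame count of water oxygens near the lower-cavity residues.

    A water oxygen counts if it lies within ``cutoff`` Å of any atom of
    residues ``residue_window[0]``–``residue_window[1]`` of any chain.
    Returns zeros with a warning when the system has no waters.
    """
    lo, hi = residue_window
    res_idx = select_atoms(
        bundle.atoms, Selector(residue_number=range(lo, hi + 1), water=False)
    )
    wat_idx = select_atoms(
        bundle.atoms, Selector(water=True, element="O"), allow_empty=True
    )
    if wat_idx.size == 0:
        warnings.warn("no waters in system; cavity hydration is zero", RuntimeWarning)
        return np.zeros(bundle.n_frames, dtype=int)
    counts = np.empty(bundle.n_frames, dtype=int)
    for f in range(bundle.n_frames):
        d = np.linalg.norm(
            bundle.coords[f, wat_idx][:, None, :] - bundle.coords[f, res_idx][None, :, :],
            axis=-1,
        )
        counts[f] = int(np.sum(d.min(axis=1) <= cutoff))
    return counts


def gating_distances(
    bundle: TrajectoryBundle,
    residues: tuple = (511, 515),
    pairing=DEFAULT_PAIRING,
) -> pd.DataFrame:
    """Opposing-subunit Cα distances for the gate residues (I511, T515).

    Returns a long DataFrame (time_ns, residue, pair, distance) with two
    diagonal distances per residue per frame.
    """
    rows = []
    for resnum in residues:
        chain_atom = {}
        for chain in {c for pair in pairing for c in pair}:
            idx = select_atoms(
                bundle.atoms,
                Selector(chain_id=chain, residue_number=resnum, atom_name="CA"),
                allow_empty=True,
            )
            if idx.size != 1:
                raise ValueError(f"missing Cα for residue {resnum} chain {chain}")
            chain_atom[chain] = idx[0]
        for a, b in pairing:
            d = np.linalg.norm(
                bundle.coords[:, chain_atom[a]] - bundle.coords[:, chain_atom[b]],
                axis=1,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "time_ns": bundle.times,
                        "residue": resnum,
                        "pair": f"{a}|{b}",
                        "distance": d,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
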