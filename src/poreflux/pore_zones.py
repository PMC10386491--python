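"""Cylindrical volume elements along the pore axis and cation densities.

A stack of cylinders is built from the initial pore structure: centered on
the center of mass of the selectivity-filter carbonyl oxygens, with a
uniform height equal to the z-distance between the two carbonyl-oxygen
plane centers, 14 stacked pore cylinders spanning cavity to vestibule and
4 bulk cylinders on each side (22 total by default). Each pore cylinder's
radius is the minimal xy distance from any flanking Cα inside its height
interval to the cylinder axis; bulk cylinders use a fixed configured
radius. Per frame, the whole stack is recentered on the current center of
mass of the filter carbonyl oxygens, cations are counted per cylinder
(half-open z intervals, inclusive radius), and time-mean number densities
in counts/nm³ plus their empirical cumulative distribution along z are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_io import AtomTable, Selector, TrajectoryBundle, select_atoms

__all__ = [
    "CylinderConfig",
    "CylinderStack",
    "build_cylinder_stack",
    "recenter_offsets",
    "count_ions_per_zone",
    "zone_number_density",
    "density_cdf",
]

A3_PER_NM3 = 1000.0  # Å³ per nm³


@dataclass(frozen=True)
class CylinderConfig:
    """Construction parameters for the zone stack."""

    n_pore: int = 14
    n_bulk_per_side: int = 4
    bulk_radius: float = 15.0  # Å, fixed radius of bulk cylinders
    fallback_pore_radius: float = 6.0  # Å, used if no Cα falls in an interval
    sf_oxygen_residues: tuple = (479, 480)
    flanking_selector: Selector = field(
        default_factory=lambda: Selector(atom_name="CA")
    )
    recenter_xy_only: bool = False


@dataclass(frozen=True)
class CylinderStack:
    """Ordered cylindrical zones along z with centers, radii and volumes."""

    centers: np.ndarray  # (n, 3) Å, reference-frame centers
    radii: np.ndarray  # (n,) Å
    height: float  # Å, common height
    roles: np.ndarray  # (n,) 'pore' | 'bulk'
    sf_oxygen_indices: np.ndarray  # atoms defining the recentering COM
    ref_com: np.ndarray  # (3,) COM of SF oxygens in the reference frame

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("cylinder height must be positive")
        z = self.centers[:, 2]
        if np.any(np.diff(z) <= 0):
            raise ValueError("cylinders must be ordered by increasing center z")

    @property
    def n(self) -> int:
        return len(self.radii)

    @property
    def volumes_nm3(self) -> np.ndarray:
        """π r² h per cylinder, in nm³."""
        return np.pi * self.radii**2 * self.height / A3_PER_NM3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_center": self.centers[:, 2],
                "radius": self.radii,
                "height": self.height,
                "volume_nm3": self.volumes_nm3,
                "role": self.roles,
            }
        )


def _sf_oxygen_indices(atoms: AtomTable, residues) -> np.ndarray:
    return select_atoms(
        atoms, Selector(residue_number=list(residues), atom_name="O")
    )


def build_cylinder_stack(
    atoms: AtomTable,
    coords: np.ndarray,
    config: CylinderConfig | None = None,
) -> CylinderStack:
    """Build the zone stack from a reference (initial) structure.

    The common cylinder height is the z-distance between the centers of
    the two carbonyl-oxygen planes; pore cylinders are stacked
    symmetrically about the filter-oxygen center of mass, and bulk
    cylinders continue the stack on both sides.
    """
    config = config or CylinderConfig()
    coords = np.asarray(coords, dtype=np.float64)

    sf_idx = _sf_oxygen_indices(atoms, config.sf_oxygen_residues)
    com = coords[sf_idx].mean(axis=0)

    plane_z = []
    for res in config.sf_oxygen_residues:
        mask = (atoms.residue_numbers[sf_idx] == res)
        if not mask.any():
            raise ValueError(f"no carbonyl-plane oxygens for residue {res}")
        plane_z.append(coords[sf_idx[mask], 2].mean())
    height = float(abs(plane_z[1] - plane_z[0]))
    if height <= 0:
        raise ValueError("zero separation between carbonyl-oxygen planes")

    n_pore, n_side = config.n_pore, config.n_bulk_per_side
    n_total = n_pore + 2 * n_side
    # contiguous stack of n_total cylinders centered on the SF oxygen COM
    offsets = (np.arange(n_total) - (n_total - 1) / 2.0) * height
    centers = np.tile(com, (n_total, 1))
    centers[:, 2] = com[2] + offsets
    roles = np.array(
        ["bulk"] * n_side + ["pore"] * n_pore + ["bulk"] * n_side, dtype=object
    )

    ca_idx = select_atoms(atoms, config.flanking_selector, allow_empty=True)
    ca = coords[ca_idx] if ca_idx.size else np.empty((0, 3))
    radii = np.empty(n_total)
    for c in range(n_total):
        if roles[c] == "bulk":
            radii[c] = config.bulk_radius
            continue
        z_lo = centers[c, 2] - height / 2.0
        z_hi = centers[c, 2] + height / 2.0
        in_slab = (ca[:, 2] >= z_lo) & (ca[:, 2] < z_hi)
        if in_slab.any():
            dxy = np.linalg.norm(ca[in_slab, :2] - centers[c, :2], axis=1)
            radii[c] = dxy.min()
        else:
            radii[c] = config.fallback_pore_radius

    return CylinderStack(
        centers=centers,
        radii=radii,
        height=height,
        roles=roles,
        sf_oxygen_indices=sf_idx,
        ref_com=com,
    )


def recenter_offsets(
    stack: CylinderStack, coords: np.ndarray, xy_only: bool = False
) -> np.ndarray:
    """Per-frame displacement of the SF carbonyl-oxygen COM (n_frames, 3).

    Adding an offset to every cylinder center recenters the stack on the
    current filter position; radii and heights are unchanged. With
    ``xy_only`` the z component is zeroed.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    com = coords[:, stack.sf_oxygen_indices].mean(axis=1)
    offsets = com - stack.ref_com
    if xy_only:
        offsets = offsets.copy()
        offsets[:, 2] = 0.0
    return offsets


def count_ions_per_zone(
    bundle: TrajectoryBundle,
    stack: CylinderStack,
    ion_indices: np.ndarray,
    recenter: bool = True,
    xy_only: bool = False,
) -> pd.DataFrame:
    """Per-frame, per-cylinder cation counts after recentering.

    An ion is assigned to a cylinder iff its z lies in the cylinder's
    half-open height interval [z_lo, z_hi) and its xy distance to the
    cylinder center is ≤ radius; cylinders are non-overlapping, so each
    ion counts in at most one cylinder per frame.
    """
    ion_indices = np.asarray(ion_indices)
    ions = bundle.coords[:, ion_indices, :]  # (F, I, 3)
    if recenter:
        offsets = recenter_offsets(stack, bundle.coords, xy_only=xy_only)
    else:
        offsets = np.zeros((bundle.n_frames, 3))
    rel = ions - offsets[:, None, :]  # ion positions in the stack frame

    z_lo = stack.centers[:, 2] - stack.height / 2.0
    z_hi = stack.centers[:, 2] + stack.height / 2.0
    # (F, I, C) containment masks
    z = rel[:, :, 2][:, :, None]
    in_z = (z >= z_lo[None, None, :]) & (z < z_hi[None, None, :])
    dxy = np.linalg.norm(
        rel[:, :, None, :2] - stack.centers[None, None, :, :2], axis=-1
    )
    counts = np.sum(in_z & (dxy <= stack.radii[None, None, :]), axis=1)
    df = pd.DataFrame(counts.astype(int), columns=np.arange(stack.n))
    df.insert(0, "time_ns", bundle.times)
    return df


def zone_number_density(
    counts: pd.DataFrame,
    stack: CylinderStack,
    discard_ns: float = 50.0,
) -> pd.DataFrame:
    """Time-mean cation number density per cylinder in counts/nm³.

    Frames with t < ``discard_ns`` (equilibration) are excluded before
    averaging; density = mean count / cylinder volume.
    """
    retained = counts[counts["time_ns"] >= discard_ns]
    if retained.empty:
        raise ValueError("no frames remain after the equilibration discard")
    mean_counts = retained[np.arange(stack.n)].mean(axis=0).to_numpy()
    out = stack.to_frame()
    out["mean_count"] = mean_counts
    out["density_nm3"] = mean_counts / stack.volumes_nm3
    return out


def density_cdf(
    densities: pd.DataFrame, weight: str = "count", cyt_to_ext: bool = True
) -> pd.DataFrame:
    """Empirical CDF of zone occupancy along the pore axis.

    With the default count weighting, CDF(k) = Σ_{j≤k} mean_count_j /
    Σ mean_count_j over cylinders ordered along z (cytosolic bulk first
    when ``cyt_to_ext``); ``weight='density'`` uses the number densities
    instead. Monotone nondecreasing and ends at exactly 1.
    """
    col = {"count": "mean_count", "density": "density_nm3"}[weight]
    w = densities[col].to_numpy()
    z = densities["z_center"].to_numpy()
    order = np.argsort(z)[::-1] if cyt_to_ext else np.argsort(z)
    w, z = w[order], z[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("all zone weights are zero; CDF undefined")
    return pd.DataFrame({"z_center": z, "cdf": np.cumsum(w) / total})
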