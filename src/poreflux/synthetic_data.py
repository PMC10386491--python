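"""Synthetic channel topologies and trajectories with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes — without any force evaluation:

* a tetrameric pore template (chains A–D) whose two carbonyl-oxygen planes
  p23/p34 bracket the filter binding region, with flanking Cα markers that
  define cylindrical zone radii and the gate residues of the lower cavity;
* per-ion residence in discrete sites (bulk/vestibule/Sa/S3/Sb/Sc/cavity)
  generated either by an exact-stochastic (Gillespie) continuous-time
  Markov simulation with single-occupancy exclusion and optional knock-on
  coupling, or by deterministic scripts when an exact event count is
  wanted;
* noisy Cartesian coordinates for the ions and breathing carbonyl planes
  whose inter-subunit gap depends on the bound species;
* first solvation shells with a species-specific total coordinating-oxygen
  count.

Ground-truth site labels, dwell intervals and permeation schedules are
retained so that every downstream stage can be scored exactly.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import SPECIES, IonSpecies, get_species
from .trajectory_io import (
    AtomTable,
    TrajectoryBundle,
    write_topology,
    write_trajectory_tsv,
)

__all__ = [
    "SITE_ORDER",
    "FILTER_SITES",
    "SiteModel",
    "KineticsConfig",
    "GeometryNoiseConfig",
    "TemplateConfig",
    "Visit",
    "build_pore_template",
    "simulate_site_dynamics",
    "schedule_events",
    "labels_at_times",
    "emit_ion_z",
    "emit_coordinates",
    "decorate_solvation",
    "chain_kinetics",
    "make_fixture",
    "PRESETS",
]

#: site order along +z (extracellular -> cytosol)
SITE_ORDER = (
    "bulk_ext",
    "vestibule",
    "Sa",
    "S3",
    "Sb",
    "Sc",
    "cavity",
    "bulk_int",
)
FILTER_SITES = ("Sa", "S3", "Sb", "Sc")

_SITE_INDEX = {s: i for i, s in enumerate(SITE_ORDER)}


@dataclass(frozen=True)
class SiteModel:
    """Discrete binding-site geometry along the pore axis.

    ``z_centers`` are Å offsets relative to the filter midpoint; they must
    increase strictly in the order bulk_ext < vestibule < Sa < S3 < Sb <
    Sc < cavity < bulk_int. The p23 plane sits at z(Sa) and p34 at z(Sb),
    bracketing the binding region. ``carbonyl_donors`` records the nominal
    number of backbone carbonyl oxygens available at each site (S3 is the
    eight-carbonyl cage between the planes).
    """

    z_centers: dict = field(
        default_factory=lambda: {
            "bulk_ext": -20.0,
            "vestibule": -6.0,
            "Sa": -2.0,
            "S3": 0.0,
            "Sb": 2.0,
            "Sc": 4.0,
            "cavity": 9.0,
            "bulk_int": 20.0,
        }
    )
    carbonyl_donors: dict = field(
        default_factory=lambda: {
            "vestibule": 0,
            "Sa": 4,
            "S3": 8,
            "Sb": 4,
            "Sc": 4,
            "cavity": 0,
        }
    )

    def __post_init__(self) -> None:
        zs = [self.z_centers[s] for s in SITE_ORDER]
        if not all(a < b for a, b in zip(zs, zs[1:])):
            raise ValueError("site z-centers must increase strictly along +z")
        if self.carbonyl_donors.get("S3") != 8:
            raise ValueError("S3 is coordinated by eight carbonyl oxygens")
        if self.carbonyl_donors.get("Sb", 0) > 8:
            raise ValueError("Sb cannot offer more than eight carbonyl donors")

    @property
    def z_p23(self) -> float:
        return self.z_centers["Sa"]

    @property
    def z_p34(self) -> float:
        return self.z_centers["Sb"]


@dataclass(frozen=True)
class KineticsConfig:
    """Transition-rate table for the site-hopping Markov model.

    ``rates`` maps ``(from_site, to_site)`` to a rate in ns⁻¹. Only hops
    between adjacent sites are allowed, plus the bulk reservoir exchange
    bulk_int → bulk_ext used to recycle permeated ions. ``knock_on_factor``
    multiplies the +z-ward exit rates of ions in S3/Sb/Sc while Sa is
    occupied, emulating electrostatic knock-on.
    """

    rates: dict
    exclusion: bool = True
    knock_on_factor: float = 1.0
    voltage_mV: float = -700.0

    def __post_init__(self) -> None:
        for (src, dst), k in self.rates.items():
            if src not in _SITE_INDEX or dst not in _SITE_INDEX:
                raise ValueError(f"unknown site in transition {src}->{dst}")
            if k < 0 or not np.isfinite(k):
                raise ValueError(f"rate for {src}->{dst} must be finite and >= 0")
            adjacent = abs(_SITE_INDEX[src] - _SITE_INDEX[dst]) == 1
            recycle = (src, dst) == ("bulk_int", "bulk_ext")
            if not (adjacent or recycle):
                raise ValueError(
                    f"transition {src}->{dst} is neither adjacent nor bulk exchange"
                )


def chain_kinetics(
    mean_dwell_ns: float,
    entry_rate: float = 2.0,
    voltage_mV: float = -700.0,
) -> KineticsConfig:
    """Forward-only conduction-cycle rates with a common filter dwell scale.

    Each filter site (Sa, S3, Sb, Sc) gets exit rate 1/``mean_dwell_ns``;
    vestibule entry, cavity exit and bulk recycling run at ``entry_rate``.
    """
    k = 1.0 / mean_dwell_ns
    rates = {
        ("bulk_ext", "vestibule"): entry_rate,
        ("vestibule", "Sa"): entry_rate,
        ("Sa", "S3"): k,
        ("S3", "Sb"): k,
        ("Sb", "Sc"): k,
        ("Sc", "cavity"): k,
        ("cavity", "bulk_int"): entry_rate,
        ("bulk_int", "bulk_ext"): entry_rate,
    }
    return KineticsConfig(rates=rates, voltage_mV=voltage_mV)


#: default species-dependent mean inter-carbonyl gaps μΔ (Å) per plane.
#: Ordinal structure: μΔ grows with ionic radius at both planes; every
#: species contracts p23 relative to apo, while only species larger than
#: Na+ widen p34. Values are free placeholders recorded here as config.
DEFAULT_MU_DELTA = {
    ("p23", "apo"): 8.6,
    ("p23", "Li"): 6.8,
    ("p23", "Na"): 7.0,
    ("p23", "K"): 7.4,
    ("p23", "Rb"): 7.8,
    ("p23", "Cs"): 8.2,
    ("p34", "apo"): 7.0,
    ("p34", "Li"): 6.4,
    ("p34", "Na"): 6.8,
    ("p34", "K"): 7.2,
    ("p34", "Rb"): 7.8,
    ("p34", "Cs"): 8.4,
}


@dataclass(frozen=True)
class GeometryNoiseConfig:
    """Coordinate-noise parameters for emitted trajectories (all Å)."""

    sigma_z: float = 0.3
    sigma_xy: float = 0.3
    sigma_delta: float = 0.15
    mu_delta: dict = field(default_factory=lambda: dict(DEFAULT_MU_DELTA))

    def __post_init__(self) -> None:
        if self.sigma_z < 0 or self.sigma_xy < 0 or self.sigma_delta < 0:
            raise ValueError("noise sigmas must be >= 0")
        for plane in ("p23", "p34"):
            radii = sorted(
                (SPECIES[s].ionic_radius, self.mu_delta[(plane, s)])
                for s in SPECIES
                if (plane, s) in self.mu_delta
            )
            gaps = [g for _, g in radii]
            if any(a >= b for a, b in zip(gaps, gaps[1:])):
                raise ValueError(f"mu_delta at {plane} must increase with ionic radius")


@dataclass(frozen=True)
class TemplateConfig:
    """Layout parameters of the synthetic tetramer template."""

    p23_residue: int = 480  # I480 backbone O forms p23
    p34_residue: int = 479  # C479 backbone O forms p34
    pore_ca_radius: float = 5.0  # xy radius of the flanking Cα ladder, Å
    ca_ladder_spacing: float = 2.0  # Å between successive ladder Cα
    ca_ladder_halfspan: float = 30.0  # ladder extent either side of midpoint, Å
    gate_radius: float = 7.0  # I511/T515 Cα circle radius (diameter 14 Å)


_CHAINS = ("A", "B", "C", "D")
_CHAIN_ANGLES = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}


def build_pore_template(
    site_model: SiteModel | None = None,
    noise: GeometryNoiseConfig | None = None,
    config: TemplateConfig | None = None,
) -> tuple[AtomTable, np.ndarray]:
    """Build the tetramer template AtomTable and apo coordinates.

    Each chain carries: the p23 and p34 carbonyl oxygens (residues 480 and
    479) on circles of diameter μΔ(apo), a Cα ladder spanning the pore for
    zone-radius construction, Cα markers for residues 507–511 in the lower
    cavity, and the I511/T515 gate Cα atoms on a circle of diameter
    2·``gate_radius``.
    """
    site_model = site_model or SiteModel()
    noise = noise or GeometryNoiseConfig()
    config = config or TemplateConfig()

    rows: list[tuple[str, int, str, str, str]] = []
    coords: list[tuple[float, float, float]] = []

    def add(chain, resnum, resname, atom, element, r, z, angle_deg):
        theta = np.deg2rad(angle_deg)
        rows.append((chain, resnum, resname, atom, element))
        coords.append((r * np.cos(theta), r * np.sin(theta), z))

    r23 = noise.mu_delta[("p23", "apo")] / 2.0
    r34 = noise.mu_delta[("p34", "apo")] / 2.0
    if site_model.z_p34 <= site_model.z_p23:
        raise ValueError("p34 must lie below p23 along +z")

    ladder_z = np.arange(
        -config.ca_ladder_halfspan,
        config.ca_ladder_halfspan + 1e-9,
        config.ca_ladder_spacing,
    )
    midpoint = 0.5 * (site_model.z_p23 + site_model.z_p34)

    for chain in _CHAINS:
        ang = _CHAIN_ANGLES[chain]
        # selectivity-filter carbonyl oxygens
        add(chain, config.p34_residue, "CYS", "O", "O", r34, site_model.z_p34, ang)
        add(chain, config.p23_residue, "ILE", "O", "O", r23, site_model.z_p23, ang)
        # flanking Cα ladder used for cylinder radii
        for k, z in enumerate(ladder_z):
            add(chain, 412 + k, "GLY", "CA", "C", config.pore_ca_radius, midpoint + z, ang)
        # lower-cavity residues 507–511 (cavity hydration window)
        for j, resnum in enumerate(range(507, 512)):
            z = site_model.z_centers["cavity"] - 1.0 + 1.0 * j
            radius = config.gate_radius if resnum == 511 else 6.0
            add(chain, resnum, "LEU" if resnum != 511 else "ILE", "CA", "C", radius, z, ang)
        # T515 gate marker
        add(chain, 515, "THR", "CA", "C", config.gate_radius,
            site_model.z_centers["cavity"] + 6.0, ang)

    df = pd.DataFrame(
        rows,
        columns=["chain_id", "residue_number", "residue_name", "atom_name", "element"],
    )
    return AtomTable(df), np.asarray(coords, dtype=np.float64)


# ---------------------------------------------------------------------------
# Site dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Visit:
    """One contiguous residence of an ion in a site."""

    site: str
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


StatePath = list  # list[Visit] per ion


def simulate_site_dynamics(
    kinetics: KineticsConfig,
    n_ions: int,
    duration: float,
    seed: int,
    initial_sites: list[str] | None = None,
) -> list[StatePath]:
    """Exact-stochastic (event-driven) simulation of site hopping.

    Returns one piecewise-constant path per ion. Single-site occupancy is
    enforced at every instant when ``kinetics.exclusion`` is set (bulk
    reservoirs are exempt). A reachable state with zero total exit rate
    raises a warning and freezes the system there.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if initial_sites is None:
        sites = ["bulk_ext"] * n_ions
    else:
        if len(initial_sites) != n_ions:
            raise ValueError("initial_sites length must equal n_ions")
        sites = list(initial_sites)

    unlimited = {"bulk_ext", "bulk_int"}
    segments: list[list[Visit]] = [[] for _ in range(n_ions)]
    seg_start = [0.0] * n_ions
    t = 0.0
    warned = False
    while True:
        moves: list[tuple[int, str, float]] = []
        occupied = {s for s in sites if s not in unlimited}
        sa_occupied = "Sa" in sites
        for i, src in enumerate(sites):
            for (a, b), k in kinetics.rates.items():
                if a != src or k == 0.0:
                    continue
                if (
                    kinetics.exclusion
                    and b not in unlimited
                    and b in occupied
                ):
                    continue
                if (
                    sa_occupied
                    and src in ("S3", "Sb", "Sc")
                    and _SITE_INDEX[b] > _SITE_INDEX[src]
                ):
                    k = k * kinetics.knock_on_factor
                moves.append((i, b, k))
        total = sum(k for _, _, k in moves)
        if total == 0.0:
            if not warned and any(s not in unlimited for s in sites):
                warnings.warn("zero total exit rate: system frozen", RuntimeWarning)
                warned = True
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next >= duration:
            break
        probs = np.array([k for _, _, k in moves]) / total
        idx = rng.choice(len(moves), p=probs)
        ion, dst, _ = moves[idx]
        segments[ion].append(Visit(sites[ion], seg_start[ion], t_next))
        sites[ion] = dst
        seg_start[ion] = t_next
        t = t_next
    for i in range(n_ions):
        segments[i].append(Visit(sites[i], seg_start[i], duration))
    return segments


def schedule_events(
    script: list[tuple[int, str, float, float]],
    duration: float | None = None,
    n_ions: int | None = None,
) -> list[StatePath]:
    """Deterministic state paths from an explicit (ion, site, t0, t1) script.

    Intervals must be non-overlapping per ion; uncovered time is spent in
    bulk_ext. Used to build fixtures with an exactly known number of full
    permeations.
    """
    if n_ions is None:
        n_ions = max(ion for ion, *_ in script) + 1 if script else 0
    if duration is None:
        duration = max((t1 for *_, t1 in script), default=0.0)
    per_ion: list[list[tuple[float, float, str]]] = [[] for _ in range(n_ions)]
    for ion, site, t0, t1 in script:
        if site not in _SITE_INDEX:
            raise ValueError(f"unknown site {site!r}")
        if not 0.0 <= t0 < t1 <= duration:
            raise ValueError(f"bad interval [{t0}, {t1}] for ion {ion}")
        per_ion[ion].append((t0, t1, site))
    paths: list[StatePath] = []
    for ion, iv in enumerate(per_ion):
        iv.sort()
        for (a0, a1, _), (b0, _, _) in zip(iv, iv[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping intervals for ion {ion} at t={b0}")
        path: list[Visit] = []
        cursor = 0.0
        for t0, t1, site in iv:
            if t0 > cursor:
                path.append(Visit("bulk_ext", cursor, t0))
            path.append(Visit(site, t0, t1))
            cursor = t1
        if cursor < duration:
            path.append(Visit("bulk_ext", cursor, duration))
        paths.append(path)
    return paths


def labels_at_times(path: StatePath, times: np.ndarray) -> np.ndarray:
    """Sample a piecewise-constant path at the given times (site labels)."""
    times = np.asarray(times, dtype=np.float64)
    starts = np.array([v.t_start for v in path])
    labels = np.array([v.site for v in path], dtype=object)
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(path) - 1)
    return labels[idx].astype(str)


# ---------------------------------------------------------------------------
# Coordinate emission
# ---------------------------------------------------------------------------

def _check_nyquist(dt: float, cutoff_ns: float = 10.0) -> None:
    if dt >= 1.0 / (2.0 * cutoff_ns):
        raise ValueError(
            f"dt={dt} ns puts the {cutoff_ns} ns^-1 filter cutoff above Nyquist"
        )


def emit_ion_z(
    path: StatePath,
    site_model: SiteModel,
    noise: GeometryNoiseConfig,
    dt: float,
    seed: int,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame ion z with Gaussian site noise; returns (times, z, labels)."""
    _check_nyquist(dt)
    if duration is None:
        duration = path[-1].t_end
    times = np.arange(0.0, duration, dt)
    labels = labels_at_times(path, times)
    centers = np.array([site_model.z_centers[s] for s in labels])
    rng = np.random.default_rng(seed)
    z = centers + (rng.normal(0.0, noise.sigma_z, size=len(times))
                   if noise.sigma_z > 0 else 0.0)
    return times, z, labels


def emit_coordinates(
    paths: list[StatePath],
    species: list[str],
    site_model: SiteModel | None = None,
    noise: GeometryNoiseConfig | None = None,
    dt: float = 0.04,
    seed: int = 0,
    duration: float | None = None,
    include_template: bool = True,
    template_config: TemplateConfig | None = None,
) -> tuple[TrajectoryBundle, pd.DataFrame]:
    """Emit a Cartesian trajectory for the template plus ions.

    Ion position per frame: the site z-center plus N(0, σ_z) along z and
    N(0, σ_xy) in xy (bulk sites are parked on-axis at their nominal z).
    Plane carbonyl oxygens breathe: while a site adjacent to a plane is
    occupied (Sa for p23; Sb or Sc for p34), the inter-subunit gap for
    that frame is drawn from N(μΔ(bound species), σΔ), otherwise from
    N(μΔ(apo), σΔ).

    Returns the bundle and a long-format ground-truth label table
    (frame, ion, site).
    """
    site_model = site_model or SiteModel()
    noise = noise or GeometryNoiseConfig()
    _check_nyquist(dt)
    if len(species) != len(paths):
        raise ValueError("one species name per ion path required")
    if duration is None:
        duration = max(p[-1].t_end for p in paths)
    times = np.arange(0.0, duration, dt)
    n_frames = len(times)
    rng = np.random.default_rng(seed)

    atoms_tmpl, coords_tmpl = build_pore_template(site_model, noise, template_config)
    n_tmpl = len(atoms_tmpl) if include_template else 0

    label_mat = np.stack([labels_at_times(p, times) for p in paths], axis=1)

    n_ions = len(paths)
    n_atoms = n_tmpl + n_ions
    coords = np.empty((n_frames, n_atoms, 3), dtype=np.float64)
    if include_template:
        coords[:, :n_tmpl, :] = coords_tmpl[None, :, :]
        # breathing carbonyl planes: per-frame gap by bound species
        for plane, gate_sites, resnum in (
            ("p23", ("Sa",), (template_config or TemplateConfig()).p23_residue),
            ("p34", ("Sb", "Sc"), (template_config or TemplateConfig()).p34_residue),
        ):
            mu = np.full(n_frames, noise.mu_delta[(plane, "apo")])
            for ion in range(n_ions):
                bound = np.isin(label_mat[:, ion], gate_sites)
                mu[bound] = noise.mu_delta[(plane, species[ion])]
            gap = mu + rng.normal(0.0, noise.sigma_delta, size=n_frames)
            sel = atoms_tmpl.df.index[
                (atoms_tmpl.residue_numbers == resnum)
                & (atoms_tmpl.atom_names == "O")
            ].to_numpy()
            for j in sel:
                chain = atoms_tmpl.chain_ids[j]
                theta = np.deg2rad(_CHAIN_ANGLES[chain])
                coords[:, j, 0] = 0.5 * gap * np.cos(theta)
                coords[:, j, 1] = 0.5 * gap * np.sin(theta)

    for ion in range(n_ions):
        centers = np.array([site_model.z_centers[s] for s in label_mat[:, ion]])
        zn = rng.normal(0.0, noise.sigma_z, n_frames) if noise.sigma_z else 0.0
        xyn = (
            rng.normal(0.0, noise.sigma_xy, (n_frames, 2))
            if noise.sigma_xy
            else np.zeros((n_frames, 2))
        )
        col = n_tmpl + ion
        coords[:, col, 0] = xyn[:, 0]
        coords[:, col, 1] = xyn[:, 1]
        coords[:, col, 2] = centers + zn

    ion_rows = pd.DataFrame(
        {
            "chain_id": "I",
            "residue_number": 9000 + np.arange(n_ions),
            "residue_name": [s.upper() for s in species],
            "atom_name": [s.upper() for s in species],
            "element": [s.capitalize() for s in species],
        }
    )
    df = (
        pd.concat([atoms_tmpl.df, ion_rows], ignore_index=True)
        if include_template
        else ion_rows
    )
    atoms = AtomTable(df)
    bundle = TrajectoryBundle(times=times, coords=coords, atoms=atoms)

    truth = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_ions),
            "ion": np.tile(np.arange(n_ions), n_frames),
            "site": label_mat.reshape(-1),
        }
    )
    return bundle, truth


def decorate_solvation(
    bundle: TrajectoryBundle,
    species: IonSpecies | str,
    site_model: SiteModel | None = None,
    seed: int = 0,
) -> TrajectoryBundle:
    """Add first-shell water oxygens around each filter-resident ion.

    For every frame in which an ion's z lies inside the filter span
    (Sa through Sc), the number of carbonyl oxygens already within the
    species cutoff is counted geometrically and ``shell_total - n_carbonyl``
    water oxygens are placed isotropically at distances drawn uniformly
    from (0.7·cutoff, cutoff). The count is clamped at zero (with a
    warning) if the carbonyls alone exceed the shell. Unused water slots
    are parked far outside the system.
    """
    if isinstance(species, str):
        species = get_species(species)
    site_model = site_model or SiteModel()
    rng = np.random.default_rng(seed)

    ion_idx = np.flatnonzero(bundle.atoms.chain_ids == "I")
    if ion_idx.size == 0:
        raise ValueError("bundle contains no ions (chain I)")
    carb_idx = np.flatnonzero(
        (bundle.atoms.atom_names == "O")
        & np.isin(bundle.atoms.residue_numbers, (479, 480, 481))
    )
    cutoff = species.coordination_cutoff
    # filter span along z, halfway to the neighbouring sites
    z_lo = 0.5 * (site_model.z_centers["vestibule"] + site_model.z_centers["Sa"])
    z_hi = 0.5 * (site_model.z_centers["Sc"] + site_model.z_centers["cavity"])

    n_frames = bundle.n_frames
    slots = species.shell_total
    n_waters = slots * ion_idx.size
    park = np.array([500.0, 500.0, 500.0])
    wcoords = np.full((n_frames, n_waters, 3), park, dtype=np.float64)

    clamped = False
    for f in range(n_frames):
        carb = bundle.coords[f, carb_idx]
        for k, ai in enumerate(ion_idx):
            pos = bundle.coords[f, ai]
            if not (z_lo <= pos[2] < z_hi):
                continue
            n_carb = int(np.sum(np.linalg.norm(carb - pos, axis=1) <= cutoff))
            n_w = species.shell_total - n_carb
            if n_w < 0:
                clamped = True
                n_w = 0
            if n_w == 0:
                continue
            vec = rng.normal(size=(n_w, 3))
            vec /= np.linalg.norm(vec, axis=1)[:, None]
            dist = rng.uniform(0.7 * cutoff, cutoff, size=n_w)
            wcoords[f, k * slots : k * slots + n_w] = pos + vec * dist[:, None]
    if clamped:
        warnings.warn(
            "carbonyl donors alone exceed shell_total; water count clamped at 0",
            RuntimeWarning,
        )

    wrows = pd.DataFrame(
        {
            "chain_id": "W",
            "residue_number": 8000 + np.arange(n_waters),
            "residue_name": "HOH",
            "atom_name": "O",
            "element": "O",
        }
    )
    atoms = AtomTable(pd.concat([bundle.atoms.df, wrows], ignore_index=True))
    coords = np.concatenate([bundle.coords, wcoords], axis=1)
    return TrajectoryBundle(times=bundle.times, coords=coords, atoms=atoms,
                            box=bundle.box)


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

def _passage_script(ion, t0, dwell):
    """One full inward passage vestibule→…→cavity starting at t0."""
    rows, t = [], t0
    for site in ("vestibule", "Sa", "S3", "Sb", "Sc", "cavity"):
        d = dwell[site]
        rows.append((ion, site, t, t + d))
        t += d
    return rows, t


def _preset_rb_conduction(seed):
    """Eight scripted full Rb+ passages in a 500-ns window (−700 mV)."""
    dwell = {"vestibule": 4.0, "Sa": 5.0, "S3": 3.0, "Sb": 4.0, "Sc": 4.0, "cavity": 6.0}
    script = []
    for k in range(8):
        rows, _ = _passage_script(k, 25.0 + 55.0 * k, dwell)
        script += rows
    paths = schedule_events(script, duration=500.0, n_ions=8)
    return {
        "species": ["Rb"] * 8,
        "voltage_mV": -700.0,
        "duration_ns": 500.0,
        "paths": paths,
        "expected_inward_permeations": 8,
    }


def _preset_cs_block(seed):
    """Three scripted Cs+ passages with long S3 holds in 500 ns (−700 mV)."""
    dwell = {"vestibule": 4.0, "Sa": 6.0, "S3": 80.0, "Sb": 4.0, "Sc": 6.0, "cavity": 8.0}
    script = []
    for k in range(3):
        rows, _ = _passage_script(k, 20.0 + 160.0 * k, dwell)
        script += rows
    paths = schedule_events(script, duration=500.0, n_ions=3)
    return {
        "species": ["Cs"] * 3,
        "voltage_mV": -700.0,
        "duration_ns": 500.0,
        "paths": paths,
        "expected_inward_permeations": 3,
    }


#: per-site mean dwell (ns) for the two-species dwell-ratio preset;
#: Cs+ filter dwells are 6x the K+ dwells by construction.
DWELL_RATIO_MEAN_NS = {"K": 2.0, "Cs": 12.0}
DWELL_RATIO_N_RUNS = 140


def single_pass_kinetics(mean_dwell_ns: float, entry_rate: float = 2.0,
                         voltage_mV: float = -500.0) -> KineticsConfig:
    """Forward-only rates with an absorbing internal bulk (no recycling).

    Used for independent one-permeation runs whose dwell records are
    pooled, mirroring the aggregation of multiple short trajectories.
    """
    kin = chain_kinetics(mean_dwell_ns, entry_rate, voltage_mV)
    rates = dict(kin.rates)
    del rates[("bulk_int", "bulk_ext")]
    return KineticsConfig(rates=rates, voltage_mV=voltage_mV)


def run_duration(path: StatePath, pad_ns: float = 1.0) -> float:
    """Emission window: end of the last non-absorbed visit plus a pad."""
    ends = [v.t_end for v in path if v.site != "bulk_int"]
    return (ends[-1] if ends else path[-1].t_end) + pad_ns


def _preset_dwell_ratio(seed, n_runs: int = DWELL_RATIO_N_RUNS):
    """Independent single-pass runs for K+ and Cs+ with a 6x dwell ratio.

    Each run is one ion started in the vestibule that permeates once and
    is absorbed in the internal bulk, so no ion ever teleports back
    through the filter; dwell records are pooled across runs.
    """
    caps = {"K": 150.0, "Cs": 700.0}
    runs = {}
    for i, (sp, mean) in enumerate(DWELL_RATIO_MEAN_NS.items()):
        kin = single_pass_kinetics(mean_dwell_ns=mean)
        paths = []
        for r in range(n_runs):
            path = simulate_site_dynamics(
                kin, n_ions=1, duration=caps[sp],
                seed=seed + 1000 * i + r, initial_sites=["vestibule"],
            )[0]
            paths.append(path)
        runs[sp] = paths
    return {
        "species": list(DWELL_RATIO_MEAN_NS),
        "voltage_mV": -500.0,
        "runs": runs,
        "mean_dwell_ns": dict(DWELL_RATIO_MEAN_NS),
        "n_runs": n_runs,
    }


PRESETS = {
    "rb_conduction": _preset_rb_conduction,
    "cs_block": _preset_cs_block,
    "dwell_ratio_cs_k": _preset_dwell_ratio,
}


def make_fixture(preset_name: str, out_dir: str | os.PathLike, seed: int = 0,
                 dt: float = 0.02) -> dict:
    """Materialise a preset on disk: topology PDB, TSV trajectories, manifest.

    Output is reproducible for a fixed seed. The manifest records species,
    voltage tag, dt, duration, the generating seed and the ground-truth
    visit schedule of every ion.
    """
    if preset_name not in PRESETS:
        raise KeyError(f"unknown preset {preset_name!r}; known: {sorted(PRESETS)}")
    os.makedirs(out_dir, exist_ok=True)
    spec = PRESETS[preset_name](seed)
    site_model = SiteModel()
    noise = GeometryNoiseConfig()

    manifest = {
        "preset": preset_name,
        "seed": seed,
        "dt_ns": dt,
        "voltage_mV": spec["voltage_mV"],
        "site_z_centers": site_model.z_centers,
        "trajectories": {},
    }

    def _emit(tag, paths, species_list, duration):
        bundle, truth = emit_coordinates(
            paths, species_list, site_model, noise, dt=dt, seed=seed,
            duration=duration, include_template=False,
        )
        traj_path = os.path.join(out_dir, f"trajectory_{tag}.tsv")
        write_trajectory_tsv(traj_path, bundle)
        top_path = os.path.join(out_dir, f"topology_{tag}.pdb")
        write_topology(top_path, bundle.atoms, bundle.coords[0])
        manifest["trajectories"][tag] = {
            "species": species_list,
            "duration_ns": duration,
            "trajectory": os.path.basename(traj_path),
            "topology": os.path.basename(top_path),
            "ground_truth": [
                [
                    {"site": v.site, "t_start": v.t_start, "t_end": v.t_end}
                    for v in path
                ]
                for path in paths
            ],
        }

    if preset_name == "dwell_ratio_cs_k":
        manifest["mean_dwell_ns"] = spec["mean_dwell_ns"]
        manifest["n_runs"] = spec["n_runs"]
        for sp, paths in spec["runs"].items():
            for r, path in enumerate(paths):
                _emit(f"{sp}_run{r:03d}", [path], [sp], run_duration(path))
    else:
        manifest["expected_inward_permeations"] = spec["expected_inward_permeations"]
        _emit("ions", spec["paths"], spec["species"], spec["duration_ns"])

    tmpl_atoms, tmpl_coords = build_pore_template(site_model, noise)
    write_topology(os.path.join(out_dir, "template.pdb"), tmpl_atoms, tmpl_coords)

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
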