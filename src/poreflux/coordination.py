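"""Coordinating-oxygen counts around filter-bound cations.

For each tracked cation and frame, the water oxygens and backbone carbonyl
oxygens within the species-specific first-shell cutoff (2.74/3.21/3.55/
3.8/4.1 Å for Li⁺/Na⁺/K⁺/Rb⁺/Cs⁺) are counted separately; per-site time
averages and the filter-site-aggregated median of the total count are the
headline summaries. Distances are plain Euclidean with an inclusive
cutoff — no minimum-image convention, which is appropriate for ions deep
inside the filter, far from the box edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .species import IonSpecies, get_species
from .trajectory_io import TrajectoryBundle

__all__ = ["coordination_counts", "site_average_coordination"]

_FILTER_SITES = ("Sa", "S3", "Sb", "Sc")


def coordination_counts(
    bundle: TrajectoryBundle,
    ion_indices: np.ndarray,
    species: IonSpecies | str,
    water_o_indices: np.ndarray,
    carbonyl_o_indices: np.ndarray,
    site_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ion, per-frame counts of coordinating oxygens.

    ``site_labels`` is an optional (n_frames, n_ions) array of binding-site
    labels carried through to the records so site tables can be built.
    Returns a long-format DataFrame with columns ion, frame, time_ns,
    site, n_water_O, n_carbonyl_O, n_total.
    """
    if isinstance(species, str):
        species = get_species(species)
    cutoff = species.coordination_cutoff
    ion_indices = np.atleast_1d(np.asarray(ion_indices))
    water_o = bundle.coords[:, np.asarray(water_o_indices, dtype=int), :]
    carb_o = bundle.coords[:, np.asarray(carbonyl_o_indices, dtype=int), :]

    rows = []
    for k, ai in enumerate(ion_indices):
        pos = bundle.coords[:, ai, :]  # (F, 3)
        d_w = np.linalg.norm(water_o - pos[:, None, :], axis=-1)
        d_c = np.linalg.norm(carb_o - pos[:, None, :], axis=-1)
        n_w = np.sum(d_w <= cutoff, axis=1)
        n_c = np.sum(d_c <= cutoff, axis=1)
        df = pd.DataFrame(
            {
                "ion": k,
                "frame": np.arange(bundle.n_frames),
                "time_ns": bundle.times,
                "n_water_O": n_w.astype(int),
                "n_carbonyl_O": n_c.astype(int),
            }
        )
        df["n_total"] = df["n_water_O"] + df["n_carbonyl_O"]
        if site_labels is not None:
            labs = np.asarray(site_labels)
            df["site"] = labs[:, k] if labs.ndim == 2 else labs
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def site_average_coordination(
    records: pd.DataFrame,
    discard_ns: float = 50.0,
) -> tuple[pd.DataFrame, float]:
    """Per-site time averages and the filter-aggregated median n_total.

    Frames before ``discard_ns`` and frames where the ion is outside all
    filter sites are excluded. Returns (site table with mean ± SD per
    count, median of n_total pooled over all filter-site frames).
    """
    if "site" not in records.columns:
        raise ValueError("records lack site labels; pass site_labels when counting")
    kept = records[
        (records["time_ns"] >= discard_ns)
        & records["site"].isin(_FILTER_SITES)
    ]
    if kept.empty:
        raise ValueError("no filter-resident frames after the discard window")
    table = (
        kept.groupby("site")[["n_water_O", "n_carbonyl_O", "n_total"]]
        .agg(["mean", "std", "count"])
        .reindex([s for s in _FILTER_SITES if s in kept["site"].unique()])
    )
    pooled_median = float(kept["n_total"].median())
    return table, pooled_median
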