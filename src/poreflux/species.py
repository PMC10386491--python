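"""Alkali-cation species parameters.

Each species carries the first-shell coordination cutoff used to count
oxygen donors around a bound cation, its Shannon ionic radius, and the
target total number of coordinating oxygens (water + backbone carbonyl)
its solvation shell is generated with.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IonSpecies:
    """A monovalent alkali cation and its coordination parameters.

    Attributes
    ----------
    name : str
        Element symbol (Li, Na, K, Rb, Cs).
    charge : int
        Formal charge in units of e; +1 for all alkali cations.
    coordination_cutoff : float
        First-shell oxygen cutoff in Å used for coordination counting.
    ionic_radius : float
        Shannon ionic radius in Å (6-coordinate).
    shell_total : int
        Target total number of coordinating oxygens in the first shell.
    """

    name: str
    coordination_cutoff: float
    ionic_radius: float
    shell_total: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.coordination_cutoff <= 0:
            raise ValueError("coordination cutoff must be positive")
        if self.shell_total < 0:
            raise ValueError("shell_total must be non-negative")


#: Default species registry. Cutoffs increase strictly with ionic radius.
SPECIES: dict[str, IonSpecies] = {
    "Li": IonSpecies("Li", coordination_cutoff=2.74, ionic_radius=0.76, shell_total=6),
    "Na": IonSpecies("Na", coordination_cutoff=3.21, ionic_radius=1.02, shell_total=6),
    "K": IonSpecies("K", coordination_cutoff=3.55, ionic_radius=1.38, shell_total=7),
    "Rb": IonSpecies("Rb", coordination_cutoff=3.80, ionic_radius=1.52, shell_total=8),
    "Cs": IonSpecies("Cs", coordination_cutoff=4.10, ionic_radius=1.67, shell_total=9),
}


def get_species(name: str) -> IonSpecies:
    """Look up a species by (case-insensitive) element symbol."""
    key = name.strip().capitalize()
    try:
        return SPECIES[key]
    except KeyError:
        raise KeyError(
            f"no registered coordination cutoff for species {name!r}; "
            f"known species: {sorted(SPECIES)}"
        ) from None
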