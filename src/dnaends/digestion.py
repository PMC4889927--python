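"""In-silico tryptic digestion and observable-peptide counting.

A peptide is *observable* when, at some allowed precursor charge state, its
monoisotopic mass maps into the instrument's precursor m/z scan window.
Defaults mirror the acquisition settings used to generate the data this
pipeline analyses: scan range 400-2000 Th, precursor charges 2+, 3+ and 4+.
All constants are exposed as parameters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .model import ProteinSeq

__all__ = [
    "Peptide",
    "RESIDUE_MONO_MASS",
    "WATER_MONO_MASS",
    "PROTON_MASS",
    "peptide_mass",
    "digest",
    "is_observable",
    "count_observable",
    "count_observable_for_protein",
]

#: Monoisotopic proton mass used to convert neutral mass to precursor m/z.
PROTON_MASS = 1.00728
#: Monoisotopic mass of water, added once per peptide (terminal H and OH).
WATER_MONO_MASS = 18.010565

DEFAULT_MZ_MIN = 400.0
DEFAULT_MZ_MAX = 2000.0
DEFAULT_CHARGES: tuple[int, ...] = (2, 3, 4)


def _load_residue_masses() -> dict[str, float]:
    table = resources.files("dnaends.data").joinpath("residue_masses.tsv")
    with table.open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return {row["residue"]: float(row["monoisotopic_mass"]) for row in reader}


#: Residue monoisotopic masses (Da), loaded from the shipped data table.
RESIDUE_MONO_MASS: dict[str, float] = _load_residue_masses()


@dataclass(frozen=True)
class Peptide:
    sequence: str
    monoisotopic_mass: float


def peptide_mass(sequence: str) -> float:
    """Monoisotopic mass of an unmodified peptide (residues + water)."""
    if not sequence:
        raise ValueError("cannot compute the mass of an empty peptide")
    try:
        return sum(RESIDUE_MONO_MASS[r] for r in sequence) + WATER_MONO_MASS
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


def _cleavage_boundaries(sequence: str) -> list[int]:
    """Tryptic cut points: C-terminal to K/R except before P."""
    cuts = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    return [0] + cuts + [len(sequence)]


def digest(protein: ProteinSeq | str, missed_cleavages: int = 0) -> list[Peptide]:
    """Tryptic digest of a protein.

    Returns every peptide with 0..``missed_cleavages`` internal uncut
    sites, in N- to C-terminal order of the start position (shorter spans
    first at a given start).  Duplicate sequences from repeated sites are
    kept, so with ``missed_cleavages=0`` the peptides concatenate back to
    the protein sequence.
    """
    sequence = protein.sequence if isinstance(protein, ProteinSeq) else protein
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    bounds = _cleavage_boundaries(sequence)
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for missed in range(missed_cleavages + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            fragment = sequence[bounds[i] : bounds[j]]
            peptides.append(Peptide(fragment, peptide_mass(fragment)))
    return peptides


def is_observable(
    mass: float,
    mz_min: float = DEFAULT_MZ_MIN,
    mz_max: float = DEFAULT_MZ_MAX,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> bool:
    """True if (mass + z * proton) / z falls in [mz_min, mz_max] for some z."""
    return any(
        mz_min <= (mass + z * PROTON_MASS) / z <= mz_max for z in charges
    )


def count_observable(
    peptides: Iterable[Peptide],
    mz_min: float = DEFAULT_MZ_MIN,
    mz_max: float = DEFAULT_MZ_MAX,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> int:
    """Number of distinct observable peptide sequences."""
    if not charges:
        raise ValueError("charges must be non-empty")
    if not mz_min < mz_max:
        raise ValueError("mz_min must be < mz_max")
    observable = {
        p.sequence
        for p in peptides
        if is_observable(p.monoisotopic_mass, mz_min, mz_max, charges)
    }
    return len(observable)


def count_observable_for_protein(
    protein: ProteinSeq | str,
    missed_cleavages: int = 0,
    mz_min: float = DEFAULT_MZ_MIN,
    mz_max: float = DEFAULT_MZ_MAX,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> int:
    """Observable-peptide count of a protein's tryptic digest."""
    return count_observable(
        digest(protein, missed_cleavages), mz_min, mz_max, charges
    )
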