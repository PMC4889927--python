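"""Core data model for a paired-phase, band-resolved pulldown experiment.

The experimental unit is a *sample*: one blue-native-PAGE band excised from
one phase lane (DNA-ends phase or control phase) of one experiment.  Bands
are a closed enumeration — the four reproducible bands of the native gel
(720, 480, 240 kDa and the band common to both phases); an unknown band
label is an input error, never a new category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Phase(str, Enum):
    """Which affinity phase a sample came from.

    ``ENDS``: duplex DNA attached by one end, exposing a free double-strand
    end (monobiotinylated oligonucleotide).  ``CONTROL``: the same duplex
    attached by both ends, exposing no free end (bibiotinylated).
    """

    ENDS = "ends"
    CONTROL = "control"


class Band(str, Enum):
    """The four reproducible native-gel bands of the purified complexes."""

    B720 = "720"
    B480 = "480"
    B240 = "240"
    COMMON = "common"


#: Canonical display/sort order of the bands (heaviest first, common last).
BAND_ORDER: tuple[Band, ...] = (Band.B720, Band.B480, Band.B240, Band.COMMON)

_BAND_SORT = {b: i for i, b in enumerate(BAND_ORDER)}


def parse_phase(value: str | Phase) -> Phase:
    if isinstance(value, Phase):
        return value
    try:
        return Phase(str(value).strip().lower())
    except ValueError:
        raise ValueError(
            f"unknown phase label {value!r}; expected one of "
            f"{[p.value for p in Phase]}"
        ) from None


def parse_band(value: str | Band) -> Band:
    if isinstance(value, Band):
        return value
    label = str(value).strip().lower()
    label = label.removeprefix("b").removesuffix("kda").strip()
    try:
        return Band(label)
    except ValueError:
        raise ValueError(
            f"unknown band label {value!r}; expected one of "
            f"{[b.value for b in Band]}"
        ) from None


def band_sort_key(band: Band) -> int:
    return _BAND_SORT[band]


@dataclass(frozen=True)
class ProteinSeq:
    """A protein database entry: accession plus amino-acid sequence."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        for pos, residue in enumerate(self.sequence):
            if residue not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"{self.accession}: non-canonical residue {residue!r} "
                    f"at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identifies one (experiment, phase, band) sample."""

    experiment_id: int
    phase: Phase
    band: Band

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", parse_phase(self.phase))
        object.__setattr__(self, "band", parse_band(self.band))
        if not isinstance(self.experiment_id, int) or self.experiment_id < 1:
            raise ValueError(
                f"experiment_id must be a positive integer, got "
                f"{self.experiment_id!r}"
            )


@dataclass(frozen=True)
class IdentificationRecord:
    """One protein observed in one sample, with its distinct peptide evidence.

    Either ``peptides`` (a set of distinct peptide sequences) or, in
    count-only mode, ``n_peptides`` is given.  A record with zero observed
    peptides is not a valid identification and is rejected.
    """

    key: SampleKey
    accession: str
    peptides: frozenset[str] | None = None
    n_peptides: int | None = None

    def __post_init__(self) -> None:
        if (self.peptides is None) == (self.n_peptides is None):
            raise ValueError(
                f"{self.accession}: exactly one of peptides / n_peptides "
                "must be given"
            )
        if self.peptides is not None:
            object.__setattr__(self, "peptides", frozenset(self.peptides))
        if self.n_observed <= 0:
            raise ValueError(
                f"{self.accession}: an identification requires at least one "
                "observed peptide"
            )

    @property
    def n_observed(self) -> int:
        """Number of distinct observed peptides."""
        if self.peptides is not None:
            return len(self.peptides)
        return int(self.n_peptides)  # type: ignore[arg-type]


def merge_records(records: Iterable[IdentificationRecord]) -> list[IdentificationRecord]:
    """Merge duplicate (sample, accession) records.

    Peptide sets are unioned; in count-only mode counts are summed (rows for
    one accession in one sample are taken as disjoint evidence partitions).
    Mixing modes for the same (sample, accession) is an error.
    """
    merged: dict[tuple[SampleKey, str], IdentificationRecord] = {}
    for rec in records:
        slot = (rec.key, rec.accession)
        prev = merged.get(slot)
        if prev is None:
            merged[slot] = rec
            continue
        if (prev.peptides is None) != (rec.peptides is None):
            raise ValueError(
                f"{rec.accession}: cannot merge peptide-sequence and "
                "count-only records for the same sample"
            )
        if prev.peptides is not None:
            merged[slot] = IdentificationRecord(
                rec.key, rec.accession, peptides=prev.peptides | rec.peptides
            )
        else:
            merged[slot] = IdentificationRecord(
                rec.key,
                rec.accession,
                n_peptides=prev.n_peptides + rec.n_peptides,  # type: ignore[operator]
            )
    return list(merged.values())


@dataclass
class ExperimentDesign:
    """Study design and all analysis thresholds.

    Defaults reproduce the published study conditions: six ends-phase
    experiments paired with five control-phase experiments, four gel bands,
    proteins called identified on >= 3 distinct sequenced peptides, the
    band-membership (Venn) analysis restricted to proteins seen in >= 4 of
    the 6 ends experiments, all other reporting restricted to >= 3 of 6, and
    DNA-ends specificity retained at index I >= 0.9.
    """

    n_ends_experiments: int = 6
    n_control_experiments: int = 5
    bands: tuple[Band, ...] = BAND_ORDER
    min_peptides: int = 3
    min_experiments_report: int = 3
    min_experiments_venn: int = 4
    specificity_cutoff: float = 0.9

    def __post_init__(self) -> None:
        self.bands = tuple(parse_band(b) for b in self.bands)
        if self.n_ends_experiments < 1:
            raise ValueError("n_ends_experiments must be >= 1")
        if not 0 <= self.n_control_experiments <= self.n_ends_experiments:
            raise ValueError(
                "n_control_experiments must lie in "
                "[0, n_ends_experiments]"
            )
        for name in ("min_experiments_report", "min_experiments_venn"):
            value = getattr(self, name)
            if not 1 <= value <= self.n_ends_experiments:
                raise ValueError(
                    f"{name} must lie in [1, n_ends_experiments], got {value}"
                )
        if not 0.0 <= self.specificity_cutoff <= 1.0:
            raise ValueError("specificity_cutoff must lie in [0, 1]")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentDesign":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown design keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "n_ends_experiments": self.n_ends_experiments,
            "n_control_experiments": self.n_control_experiments,
            "bands": [b.value for b in self.bands],
            "min_peptides": self.min_peptides,
            "min_experiments_report": self.min_experiments_report,
            "min_experiments_venn": self.min_experiments_venn,
            "specificity_cutoff": self.specificity_cutoff,
        }
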