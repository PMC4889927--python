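"""emPAI label-free semi-quantitation.

The exponentially modified protein abundance index is

    emPAI = 10^(N_observed / N_observable) - 1

with N_observed the number of distinct observed peptides of the protein in
a sample and N_observable its observable tryptic peptide count.  emPAI is a
within-protein abundance proxy: the pipeline only ever compares a protein
with itself across samples, never two proteins with each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import digestion
from .model import ExperimentDesign, IdentificationRecord, ProteinSeq, SampleKey, merge_records

__all__ = ["QuantifiedObservation", "compute_empai", "quantify"]

logger = logging.getLogger("dnaends")


@dataclass(frozen=True)
class QuantifiedObservation:
    """An identification augmented with its emPAI value."""

    key: SampleKey
    accession: str
    n_observed: int
    n_observable: int
    empai: float

    def as_row(self) -> dict:
        return {
            "experiment": self.key.experiment_id,
            "phase": self.key.phase.value,
            "band": self.key.band.value,
            "accession": self.accession,
            "n_observed": self.n_observed,
            "n_observable": self.n_observable,
            "empai": self.empai,
        }


def compute_empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(n_observed / n_observable) - 1.

    ``n_observed`` above ``n_observable`` is clamped (with a warning):
    missed-cleavage peptides in real searches can exceed the fully-tryptic
    observable count, and clamping keeps emPAI bounded at 9.
    """
    if n_observable < 1:
        raise ValueError(
            "protein has no observable peptides and cannot be quantified"
        )
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    if n_observed > n_observable:
        logger.warning(
            "n_observed=%d exceeds n_observable=%d; clamping",
            n_observed,
            n_observable,
        )
        n_observed = n_observable
    return 10.0 ** (n_observed / n_observable) - 1.0


def quantify(
    records: Iterable[IdentificationRecord],
    proteins: Iterable[ProteinSeq],
    design: ExperimentDesign | None = None,
    *,
    missed_cleavages: int = 0,
    mz_min: float = digestion.DEFAULT_MZ_MIN,
    mz_max: float = digestion.DEFAULT_MZ_MAX,
    charges: Sequence[int] = digestion.DEFAULT_CHARGES,
) -> list[QuantifiedObservation]:
    """Quantify identification records against a protein database.

    Duplicate (sample, accession) records are merged first.  Records with
    fewer than ``design.min_peptides`` distinct peptides are dropped (and
    the drop count logged); every surviving record yields one
    :class:`QuantifiedObservation`.  The observable-peptide count is
    computed once per accession and cached.
    """
    design = design or ExperimentDesign()
    database = {}
    for protein in proteins:
        if protein.accession in database:
            raise ValueError(f"duplicate accession {protein.accession!r}")
        database[protein.accession] = protein

    merged = merge_records(records)
    missing = sorted({r.accession for r in merged} - set(database))
    if missing:
        raise KeyError(
            f"{len(missing)} accession(s) not in the protein database: "
            f"{', '.join(missing)}"
        )

    observable_cache: dict[str, int] = {}
    clamp_warned: set[str] = set()
    observations: list[QuantifiedObservation] = []
    n_dropped = 0
    for record in merged:
        if record.n_observed < design.min_peptides:
            n_dropped += 1
            continue
        accession = record.accession
        if accession not in observable_cache:
            observable_cache[accession] = digestion.count_observable_for_protein(
                database[accession], missed_cleavages, mz_min, mz_max, charges
            )
        n_observable = observable_cache[accession]
        if n_observable < 1:
            raise ValueError(
                f"{accession}: no observable peptides under the acquisition "
                "settings; cannot be quantified"
            )
        n_observed = record.n_observed
        if n_observed > n_observable:
            if accession not in clamp_warned:
                clamp_warned.add(accession)
                logger.warning(
                    "%s: n_observed=%d exceeds n_observable=%d; clamping",
                    accession,
                    n_observed,
                    n_observable,
                )
            n_observed = n_observable
        observations.append(
            QuantifiedObservation(
                key=record.key,
                accession=accession,
                n_observed=n_observed,
                n_observable=n_observable,
                empai=compute_empai(n_observed, n_observable),
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d record(s) with fewer than %d distinct peptides",
            n_dropped,
            design.min_peptides,
        )
    observations.sort(key=lambda o: (o.key, o.accession))
    return observations
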