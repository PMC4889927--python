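"""Ends/control sample pairing and the DNA-ends specificity index.

For each protein the index is the mean, over the experiments in which the
protein was identified, of the per-experiment enrichment ratio:

    I = ( sum_{i=1}^{N} M_i / (M_i + B_i) ) / N

where M_i and B_i are the protein's emPAI values on the DNA-ends phase and
the control phase in experiment i, and N is the number of experiments in
which the protein was identified (on either phase).  A protein absent from
one phase contributes 0 emPAI on that side; an experiment where it is
absent from both phases does not count toward N.  Only proteins with
N >= 3 (configurable) are considered, and only those with I >= 0.9
(configurable) are retained as DNA-ends specific.

Each band excised from the ends-phase lane is paired with the matching
band of the control lane, so the index exists at two scopes: per band, and
pooled per protein (per-experiment emPAI summed across bands).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import Band, ExperimentDesign, Phase, band_sort_key
from .quant import QuantifiedObservation

__all__ = [
    "POOLED",
    "PairedAbundance",
    "SpecificityResult",
    "pair_samples",
    "pool_pairs",
    "specificity_index",
    "compute_specificity",
    "apply_specificity_filter",
    "replicate_presence",
]

#: Scope marker for the protein-level (across-band) index.
POOLED = "pooled"


@dataclass(frozen=True)
class PairedAbundance:
    """One protein's (ends, control) emPAI pair in one experiment.

    ``band`` is None for the pooled (across-band) scope.  ``paired`` is
    False for an ends experiment that has no control-phase twin (the study
    ran six ends experiments against five control experiments).
    """

    experiment_id: int
    band: Band | None
    accession: str
    M: float
    B: float
    paired: bool = True

    def __post_init__(self) -> None:
        if self.M < 0 or self.B < 0:
            raise ValueError("emPAI values must be non-negative")
        if self.M + self.B <= 0:
            raise ValueError(
                f"{self.accession}: a pair requires M + B > 0 "
                f"(experiment {self.experiment_id})"
            )


@dataclass(frozen=True)
class SpecificityResult:
    """Specificity verdict for one protein at one scope."""

    accession: str
    scope: str  # a band label or POOLED
    n_experiments: int
    index: float | None  # None when N < the design minimum
    retained: bool
    exclusive_to_ends: bool

    def as_row(self) -> dict:
        return {
            "accession": self.accession,
            "scope": self.scope,
            "n_experiments": self.n_experiments,
            "index": self.index,
            "retained": self.retained,
            "exclusive_to_ends": self.exclusive_to_ends,
        }


def pair_samples(
    quantified: Iterable[QuantifiedObservation],
    design: ExperimentDesign | None = None,
    *,
    paired_only: bool = False,
) -> list[PairedAbundance]:
    """Pair ends/control observations per (experiment, band, accession).

    Ends experiments 1..n_control_experiments have a control twin; the
    remainder are emitted with B = 0 and flagged unpaired (or dropped with
    ``paired_only=True``).  A control observation whose experiment id has
    no ends counterpart is an error.  (M, B) = (0, 0) pairs never arise:
    a pair exists only where at least one phase observed the protein.
    """
    design = design or ExperimentDesign()
    slots: dict[tuple[int, Band, str], list[float]] = {}
    for obs in quantified:
        experiment = obs.key.experiment_id
        if obs.key.phase is Phase.CONTROL:
            if experiment > design.n_ends_experiments:
                raise ValueError(
                    f"control experiment {experiment} has no ends-phase "
                    f"counterpart (design has {design.n_ends_experiments} "
                    "ends experiments)"
                )
            if experiment > design.n_control_experiments:
                raise ValueError(
                    f"control observation in experiment {experiment} but the "
                    f"design declares only {design.n_control_experiments} "
                    "control experiments"
                )
        elif experiment > design.n_ends_experiments:
            raise ValueError(
                f"ends observation in experiment {experiment} exceeds the "
                f"design's {design.n_ends_experiments} ends experiments"
            )
        slot = slots.setdefault((experiment, obs.key.band, obs.accession), [0.0, 0.0])
        side = 0 if obs.key.phase is Phase.ENDS else 1
        slot[side] += obs.empai

    pairs = []
    for (experiment, band, accession), (m_val, b_val) in sorted(
        slots.items(), key=lambda kv: (kv[0][0], band_sort_key(kv[0][1]), kv[0][2])
    ):
        is_paired = experiment <= design.n_control_experiments
        if paired_only and not is_paired:
            continue
        pairs.append(
            PairedAbundance(experiment, band, accession, m_val, b_val, is_paired)
        )
    return pairs


def pool_pairs(pairs: Iterable[PairedAbundance]) -> list[PairedAbundance]:
    """Sum band-scope pairs into one pooled pair per (experiment, protein)."""
    pooled: dict[tuple[int, str], list] = {}
    for pair in pairs:
        slot = pooled.setdefault(
            (pair.experiment_id, pair.accession), [0.0, 0.0, pair.paired]
        )
        slot[0] += pair.M
        slot[1] += pair.B
    return [
        PairedAbundance(experiment, None, accession, m_val, b_val, paired)
        for (experiment, accession), (m_val, b_val, paired) in sorted(pooled.items())
    ]


def specificity_index(
    pairs: Sequence[PairedAbundance], design: ExperimentDesign | None = None
) -> SpecificityResult:
    """Compute the index for one protein at one scope.

    N is the number of distinct contributing experiments.  When N is below
    the design minimum the index is undefined and the protein is excluded.
    """
    design = design or ExperimentDesign()
    if not pairs:
        raise ValueError("cannot compute a specificity index from no pairs")
    accessions = {p.accession for p in pairs}
    scopes = {p.band for p in pairs}
    if len(accessions) != 1 or len(scopes) != 1:
        raise ValueError(
            "all pairs must share one accession and one scope; got "
            f"accessions={sorted(accessions)} scopes={sorted(map(str, scopes))}"
        )
    experiments = [p.experiment_id for p in pairs]
    if len(set(experiments)) != len(experiments):
        raise ValueError("duplicate experiment in pair list; pool bands first")

    accession = pairs[0].accession
    scope = POOLED if pairs[0].band is None else pairs[0].band.value
    n = len(pairs)
    exclusive = all(p.B == 0.0 for p in pairs)
    if n < design.min_experiments_report:
        return SpecificityResult(accession, scope, n, None, False, exclusive)
    index = sum(p.M / (p.M + p.B) for p in pairs) / n
    return SpecificityResult(
        accession,
        scope,
        n,
        index,
        retained=index >= design.specificity_cutoff,
        exclusive_to_ends=exclusive,
    )


def compute_specificity(
    quantified: Iterable[QuantifiedObservation],
    design: ExperimentDesign | None = None,
    *,
    scope: str = "both",
    paired_only: bool = False,
    identified_on: str = "either",
) -> list[SpecificityResult]:
    """Pair samples and compute indices at band and/or pooled scope.

    ``scope`` is one of ``"band"``, ``"pooled"``, ``"both"``.
    ``identified_on`` selects which experiments count toward N: ``"either"``
    (the protein was seen on at least one phase; the default) or ``"ends"``
    (only experiments where it was seen on the ends phase; a control-only
    experiment then contributes neither to N nor to the sum).
    """
    if scope not in ("band", "pooled", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    if identified_on not in ("either", "ends"):
        raise ValueError(f"unknown identified_on convention {identified_on!r}")
    design = design or ExperimentDesign()
    band_pairs = pair_samples(quantified, design, paired_only=paired_only)

    def eligible(pairs: list[PairedAbundance]) -> list[PairedAbundance]:
        if identified_on == "ends":
            return [p for p in pairs if p.M > 0.0]
        return pairs

    results: list[SpecificityResult] = []
    if scope in ("pooled", "both"):
        groups: dict[str, list[PairedAbundance]] = {}
        for pair in eligible(pool_pairs(band_pairs)):
            groups.setdefault(pair.accession, []).append(pair)
        for accession in sorted(groups):
            results.append(specificity_index(groups[accession], design))
    if scope in ("band", "both"):
        band_groups: dict[tuple[str, Band], list[PairedAbundance]] = {}
        for pair in eligible(band_pairs):
            band_groups.setdefault((pair.accession, pair.band), []).append(pair)
        for accession, band in sorted(
            band_groups, key=lambda k: (k[0], band_sort_key(k[1]))
        ):
            results.append(specificity_index(band_groups[(accession, band)], design))
    return results


def apply_specificity_filter(
    results: Iterable[SpecificityResult], cutoff: float | None = None
) -> tuple[list[SpecificityResult], list[SpecificityResult]]:
    """Partition results into (retained, removed) at the cutoff.

    Retained means the index is defined and >= cutoff (an exact tie is
    retained; removal is for index strictly below the cutoff).  Undefined
    indices (insufficient replicates) are removed.  The partition is
    exhaustive and disjoint.
    """
    retained: list[SpecificityResult] = []
    removed: list[SpecificityResult] = []
    for result in results:
        effective = (
            result.retained
            if cutoff is None
            else result.index is not None and result.index >= cutoff
        )
        (retained if effective else removed).append(result)
    return retained, removed


def replicate_presence(
    quantified: Iterable[QuantifiedObservation],
    phase: Phase = Phase.ENDS,
    min_experiments: int = 3,
) -> set[str]:
    """Accessions identified on *phase*, any band, in >= min_experiments
    distinct experiments."""
    if min_experiments < 1:
        raise ValueError("min_experiments must be >= 1")
    seen: dict[str, set[int]] = {}
    for obs in quantified:
        if obs.key.phase is phase:
            seen.setdefault(obs.accession, set()).add(obs.key.experiment_id)
    return {
        accession
        for accession, experiments in seen.items()
        if len(experiments) >= min_experiments
    }
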