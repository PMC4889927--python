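"""Band-membership set algebra and per-band abundance profiles.

The four native-gel bands define a 4-set Venn universe.  A protein's band
set is the union of the bands where it was identified on the ends phase in
at least one experiment, restricted to proteins passing the replicate
threshold (>= 4 of 6 experiments for the Venn analysis by default).  The
core proteome is the pair of sets occupying all four bands, or all bands
but the common one.  Per-band "relative abundance" is the protein's
across-band fraction of its mean per-band emPAI — emPAI values are only
ever compared within one protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import BAND_ORDER, Band, Phase, band_sort_key
from .quant import QuantifiedObservation

__all__ = [
    "BandProfile",
    "VennCounts",
    "band_membership",
    "venn_counts",
    "core_proteome",
    "relative_distribution",
    "band_profiles",
    "rank_by_abundance",
    "class_histograms",
    "presence_rates",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class BandProfile:
    """Per-band mean emPAI and relative fractions for one protein."""

    accession: str
    bands: frozenset[Band]
    mean_empai: dict[Band, float]
    fraction: dict[Band, float]

    def as_row(self) -> dict:
        row: dict = {"accession": self.accession}
        for band in BAND_ORDER:
            row[f"mean_empai_{band.value}"] = self.mean_empai.get(band, 0.0)
        for band in BAND_ORDER:
            row[f"fraction_{band.value}"] = self.fraction.get(band, 0.0)
        return row


@dataclass(frozen=True)
class VennCounts:
    """Counts over the 15 non-empty regions of the 4-band Venn diagram."""

    region_counts: Mapping[frozenset[Band], int]
    pairwise: Mapping[frozenset[Band], int]

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())

    @property
    def n_exclusive(self) -> int:
        return sum(c for r, c in self.region_counts.items() if len(r) == 1)

    @property
    def n_shared(self) -> int:
        return sum(c for r, c in self.region_counts.items() if len(r) >= 2)

    @property
    def n_all_bands(self) -> int:
        return self.region_counts.get(frozenset(BAND_ORDER), 0)

    @property
    def n_all_but_common(self) -> int:
        return self.region_counts.get(
            frozenset({Band.B720, Band.B480, Band.B240}), 0
        )

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(
            self.region_counts,
            key=lambda r: (len(r), tuple(band_sort_key(b) for b in sorted(r, key=band_sort_key))),
        ):
            label = "+".join(b.value for b in sorted(region, key=band_sort_key))
            rows.append({"region": label, "n_proteins": self.region_counts[region]})
        return pd.DataFrame(rows, columns=["region", "n_proteins"])


def band_membership(
    quantified: Iterable[QuantifiedObservation],
    presence_set: set[str],
) -> dict[str, frozenset[Band]]:
    """Map each protein in *presence_set* to the bands where it was seen.

    A band belongs to the set iff the protein was identified there on the
    ends phase in at least one experiment.  A presence-set accession with
    no ends-phase band observation means the inputs are inconsistent.
    """
    seen: dict[str, set[Band]] = {}
    for obs in quantified:
        if obs.key.phase is Phase.ENDS and obs.accession in presence_set:
            seen.setdefault(obs.accession, set()).add(obs.key.band)
    orphans = presence_set - set(seen)
    if orphans:
        raise ValueError(
            "presence set contains accessions with no ends-phase band "
            f"observation: {', '.join(sorted(orphans))}"
        )
    return {accession: frozenset(bands) for accession, bands in seen.items()}


def venn_counts(membership: Mapping[str, frozenset[Band]]) -> VennCounts:
    """Count proteins per Venn region, plus pairwise sharing counts.

    Pairwise counts use simple intersection of membership sets: a protein
    occupying three bands counts toward each of the three pairs it covers.
    """
    regions: dict[frozenset[Band], int] = {}
    for accession, bands in membership.items():
        if not bands:
            raise ValueError(f"{accession}: empty band set in membership map")
        region = frozenset(bands)
        regions[region] = regions.get(region, 0) + 1
    pairwise: dict[frozenset[Band], int] = {
        frozenset(pair): 0 for pair in combinations(BAND_ORDER, 2)
    }
    for bands in membership.values():
        for pair in combinations(sorted(bands, key=band_sort_key), 2):
            pairwise[frozenset(pair)] += 1
    return VennCounts(regions, pairwise)


def core_proteome(
    membership: Mapping[str, frozenset[Band]]
) -> tuple[set[str], set[str]]:
    """(proteins in all four bands, proteins in exactly the three resolved
    bands — everything but the common one)."""
    all_bands = frozenset(BAND_ORDER)
    all_but_common = frozenset({Band.B720, Band.B480, Band.B240})
    return (
        {a for a, bands in membership.items() if bands == all_bands},
        {a for a, bands in membership.items() if bands == all_but_common},
    )


def relative_distribution(
    quantified: Sequence[QuantifiedObservation],
) -> BandProfile:
    """Across-band relative abundance profile of one protein.

    Input: this protein's ends-phase observations.  Per band the mean
    emPAI across the experiments where it was observed there (absent bands
    get 0); fractions normalise the means to sum to 1.
    """
    if not quantified:
        raise ValueError("relative_distribution requires at least one observation")
    accessions = {o.accession for o in quantified}
    if len(accessions) != 1:
        raise ValueError(f"observations span several accessions: {sorted(accessions)}")
    per_band: dict[Band, list[float]] = {}
    for obs in quantified:
        if obs.key.phase is not Phase.ENDS:
            continue
        per_band.setdefault(obs.key.band, []).append(obs.empai)
    means = {
        band: sum(values) / len(values) for band, values in per_band.items()
    }
    total = sum(means.values())
    if total <= 0:
        raise ValueError(
            f"{next(iter(accessions))}: all-zero emPAI; cannot normalise"
        )
    return BandProfile(
        accession=next(iter(accessions)),
        bands=frozenset(band for band, mean in means.items() if mean > 0),
        mean_empai={band: means.get(band, 0.0) for band in BAND_ORDER},
        fraction={band: means.get(band, 0.0) / total for band in BAND_ORDER},
    )


def band_profiles(
    quantified: Iterable[QuantifiedObservation],
    accessions: set[str] | None = None,
) -> list[BandProfile]:
    """Relative-distribution profiles for many proteins (ends phase only)."""
    groups: dict[str, list[QuantifiedObservation]] = {}
    for obs in quantified:
        if obs.key.phase is Phase.ENDS:
            if accessions is None or obs.accession in accessions:
                groups.setdefault(obs.accession, []).append(obs)
    return [relative_distribution(groups[a]) for a in sorted(groups)]


def rank_by_abundance(
    quantified: Iterable[QuantifiedObservation],
) -> list[str]:
    """Proteins sorted by total ends-phase emPAI, descending.

    Ties break lexicographically on accession, so the order is
    deterministic.
    """
    totals: dict[str, float] = {}
    for obs in quantified:
        if obs.key.phase is Phase.ENDS:
            totals[obs.accession] = totals.get(obs.accession, 0.0) + obs.empai
    return sorted(totals, key=lambda a: (-totals[a], a))


def class_histograms(
    membership: Mapping[str, frozenset[Band]],
    retained: set[str],
    class_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-class, per-band protein counts before/after the specificity filter.

    A protein carrying several class labels counts once in each class;
    unmapped proteins fall into ``unclassified``.  Rows with band ``all``
    aggregate over bands (each protein counted once).  The removal
    fraction is 1 - post/pre.
    """
    class_map = class_map or {}
    rows = []
    by_class: dict[str, set[str]] = {}
    for accession in membership:
        labels = class_map.get(accession) or (UNCLASSIFIED,)
        for label in labels:
            by_class.setdefault(label, set()).add(accession)
    for label in sorted(by_class):
        members = by_class[label]
        scopes: list[tuple[str, set[str]]] = [
            (band.value, {a for a in members if band in membership[a]})
            for band in BAND_ORDER
        ]
        scopes.append(("all", members))
        for band_label, accs in scopes:
            pre = len(accs)
            post = len(accs & retained)
            rows.append(
                {
                    "class": label,
                    "band": band_label,
                    "n_pre_filter": pre,
                    "n_post_filter": post,
                    "removal_fraction": (1.0 - post / pre) if pre else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["class", "band", "n_pre_filter", "n_post_filter", "removal_fraction"],
    )


def presence_rates(
    quantified: Iterable[QuantifiedObservation],
    accession: str,
    phase: Phase = Phase.ENDS,
) -> dict[str, float]:
    """Fraction of band-samples and of experiments on *phase* containing
    the protein (both denominators, since either may be meant by a
    "present in X% of the purified material" statement)."""
    samples: set = set()
    experiments: set[int] = set()
    hit_samples: set = set()
    hit_experiments: set[int] = set()
    for obs in quantified:
        if obs.key.phase is not phase:
            continue
        samples.add((obs.key.experiment_id, obs.key.band))
        experiments.add(obs.key.experiment_id)
        if obs.accession == accession:
            hit_samples.add((obs.key.experiment_id, obs.key.band))
            hit_experiments.add(obs.key.experiment_id)
    return {
        "by_sample": len(hit_samples) / len(samples) if samples else 0.0,
        "by_experiment": len(hit_experiments) / len(experiments) if experiments else 0.0,
    }
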