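"""Readers and writers for the file formats the pipeline touches.

Identification tables come in two equivalent dialects:

* per-sample: one TSV per (experiment, phase, band) with columns
  ``accession`` and either ``peptides`` (semicolon-joined distinct peptide
  sequences) or ``n_peptides`` (an integer count);
* long: one TSV with explicit ``experiment``, ``phase``, ``band`` columns
  ahead of the same evidence columns.

Both map to the same internal :class:`~dnaends.model.IdentificationRecord`
model.  Parsing is strict: malformed rows fail loudly with their line
number, nothing is silently dropped.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .model import (
    Band,
    ExperimentDesign,
    IdentificationRecord,
    ProteinSeq,
    SampleKey,
    band_sort_key,
    merge_records,
    parse_band,
    parse_phase,
)

__all__ = [
    "read_fasta",
    "read_identifications",
    "load_identifications",
    "read_identification_table",
    "write_identification_table",
    "write_table",
    "read_table",
    "load_design",
    "dump_design",
    "read_class_map",
]


def read_fasta(path: str | os.PathLike) -> list[ProteinSeq]:
    """Read a protein FASTA database.

    The accession is the first whitespace-delimited token of the header;
    record order is preserved.  Duplicate accessions and non-canonical
    residues are errors.
    """
    proteins: list[ProteinSeq] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        proteins.append(
            ProteinSeq(
                accession=accession,
                sequence=str(record.seq).upper(),
                description=record.description.removeprefix(record.id).strip(),
            )
        )
    return proteins


def _parse_peptides(cell: str, line_no: int) -> frozenset[str]:
    peptides = frozenset(p.strip() for p in str(cell).split(";") if p.strip())
    if not peptides:
        raise ValueError(
            f"line {line_no}: empty peptide list is not a valid identification"
        )
    return peptides


def _parse_count(cell, line_no: int) -> int:
    try:
        count = int(cell)
    except (TypeError, ValueError):
        raise ValueError(
            f"line {line_no}: malformed peptide count {cell!r}"
        ) from None
    if count <= 0:
        raise ValueError(
            f"line {line_no}: a valid identification needs n_peptides >= 1, "
            f"got {count}"
        )
    return count


def _records_from_frame(
    frame: pd.DataFrame, key_for_row, source: str
) -> list[IdentificationRecord]:
    columns = set(frame.columns)
    if "accession" not in columns:
        raise ValueError(f"{source}: missing required column 'accession'")
    if ("peptides" in columns) == ("n_peptides" in columns):
        raise ValueError(
            f"{source}: exactly one of columns 'peptides' / 'n_peptides' "
            "is required"
        )
    sequence_mode = "peptides" in columns
    records: list[IdentificationRecord] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is line 1
        accession = str(row["accession"]).strip()
        if not accession or accession.lower() == "nan":
            raise ValueError(f"{source}: line {line_no}: empty accession")
        key = key_for_row(row, line_no)
        if sequence_mode:
            records.append(
                IdentificationRecord(
                    key, accession, peptides=_parse_peptides(row["peptides"], line_no)
                )
            )
        else:
            records.append(
                IdentificationRecord(
                    key, accession, n_peptides=_parse_count(row["n_peptides"], line_no)
                )
            )
    return merge_records(records)


def read_identifications(
    path: str | os.PathLike, key: SampleKey
) -> list[IdentificationRecord]:
    """Read one per-sample identification TSV; all records are tagged *key*.

    Rows repeating an accession are merged (peptide sets unioned).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return _records_from_frame(frame, lambda row, line: key, str(path))


def load_identifications(path: str | os.PathLike) -> list[IdentificationRecord]:
    """Load identifications from either accepted layout.

    A file is read as a long table (explicit experiment/phase/band
    columns).  A directory is read as one per-sample TSV per excised band,
    named ``<experiment>_<phase>_<band>.tsv`` (e.g. ``3_ends_720.tsv``).
    A paired band with no control-phase file simply contributes no control
    identifications — the band was excised even if not visible, and came
    up empty.
    """
    path = Path(path)
    if path.is_file():
        return read_identification_table(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no such identification file or directory: {path}")
    records: list[IdentificationRecord] = []
    for sample_file in sorted(path.glob("*.tsv")):
        tokens = sample_file.stem.split("_")
        if len(tokens) != 3:
            raise ValueError(
                f"{sample_file.name}: per-sample files must be named "
                "<experiment>_<phase>_<band>.tsv"
            )
        try:
            experiment = int(tokens[0])
        except ValueError:
            raise ValueError(
                f"{sample_file.name}: malformed experiment id {tokens[0]!r}"
            ) from None
        key = SampleKey(experiment, parse_phase(tokens[1]), parse_band(tokens[2]))
        records.extend(read_identifications(sample_file, key))
    return merge_records(records)


def read_identification_table(path: str | os.PathLike) -> list[IdentificationRecord]:
    """Read a long identification table with experiment/phase/band columns."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for column in ("experiment", "phase", "band"):
        if column not in frame.columns:
            raise ValueError(f"{path}: missing required column {column!r}")

    def key_for_row(row, line_no: int) -> SampleKey:
        try:
            experiment = int(row["experiment"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: line {line_no}: malformed experiment id "
                f"{row['experiment']!r}"
            ) from None
        return SampleKey(experiment, parse_phase(row["phase"]), parse_band(row["band"]))

    return _records_from_frame(frame, key_for_row, str(path))


def write_identification_table(
    records: Iterable[IdentificationRecord], path: str | os.PathLike
) -> None:
    """Write records as a long table (deterministic row order)."""
    rows = []
    for rec in records:
        row = {
            "experiment": rec.key.experiment_id,
            "phase": rec.key.phase.value,
            "band": rec.key.band.value,
            "accession": rec.accession,
        }
        if rec.peptides is not None:
            row["peptides"] = ";".join(sorted(rec.peptides))
        else:
            row["n_peptides"] = rec.n_peptides
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["_band"] = frame["band"].map(lambda b: band_sort_key(parse_band(b)))
        frame = frame.sort_values(
            ["experiment", "phase", "_band", "accession"], kind="mergesort"
        ).drop(columns="_band")
    write_table(frame, path, sort=False)


_SORT_PREFERENCE = ("accession", "band", "scope", "experiment", "phase", "class")


def write_table(
    records, path: str | os.PathLike, *, columns: Sequence[str] | None = None,
    sort: bool = True,
) -> None:
    """Write any homogeneous tabular result as a TSV with a header.

    Accepts a DataFrame or an iterable of dataclass-like/mapping rows.
    Column order is the natural field order; rows are sorted on the
    preferred keys present (accession, then band) so output is
    byte-deterministic across runs.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        rows = []
        for item in records:
            if hasattr(item, "as_row"):
                rows.append(item.as_row())
            elif hasattr(item, "__dataclass_fields__"):
                rows.append(
                    {f: getattr(item, f) for f in item.__dataclass_fields__}
                )
            else:
                rows.append(dict(item))
        frame = pd.DataFrame(rows)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    for column in frame.columns:
        frame[column] = frame[column].map(_cell_text)
    if sort and not frame.empty:
        keys = [c for c in _SORT_PREFERENCE if c in frame.columns]
        if keys:
            frame = frame.sort_values(keys, kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _cell_text(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return format(value, ".10g")
    if hasattr(value, "value"):  # enums
        return str(value.value)
    if isinstance(value, (frozenset, set, tuple, list)):
        return ";".join(sorted(str(getattr(v, "value", v)) for v in value))
    return str(value)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (cells as text)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_design(path: str | os.PathLike) -> ExperimentDesign:
    """Load an :class:`ExperimentDesign` from a YAML file."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: design YAML must be a mapping")
    if "bands" in data:
        data["bands"] = tuple(parse_band(b) for b in data["bands"])
    return ExperimentDesign.from_dict(data)


def dump_design(design: ExperimentDesign, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(design.to_dict(), handle, sort_keys=False)


def read_class_map(path: str | os.PathLike) -> dict[str, tuple[str, ...]]:
    """Read an accession -> functional-class mapping TSV.

    Columns ``accession`` and ``classes`` (semicolon-joined labels; a
    protein may belong to more than one class).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for column in ("accession", "classes"):
        if column not in frame.columns:
            raise ValueError(f"{path}: missing required column {column!r}")
    mapping: dict[str, tuple[str, ...]] = {}
    for _, row in frame.iterrows():
        labels = tuple(
            sorted({c.strip() for c in str(row["classes"]).split(";") if c.strip()})
        )
        mapping[str(row["accession"]).strip()] = labels
    return mapping
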