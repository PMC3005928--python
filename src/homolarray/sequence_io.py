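"""Readers and writers for every external format the pipeline touches.

Transcript sets arrive as FASTA (one file per species); everything else —
probe tables, intensity tables, known-homolog tables, annotation tables —
is plain tab-separated text with a fixed header.  All coordinates are
0-based, half-open.  Records are validated on ingest and every write/read
pair is a lossless round trip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Scanner saturation ceiling: a 20-bit dynamic range.
INTENSITY_CEILING = 2**20

_VALID_BASES = frozenset("ACGTN")


class ValidationError(ValueError):
    """A record or table violated an invariant on ingest."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One gene/EST sequence with a species tag; the unit probes come from."""

    id: str
    species: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProbeTableRow:
    """An accepted probe with its specificity score and provenance.

    ``probe_id`` is ``"<source_id>_<start>"`` with the 0-based start.
    ``min_cross_distance`` is stored capped: a value equal to the screening
    cap means "at least this far from every non-target gene".
    ``nearest_nontarget`` is empty when no gene came within the cap.
    """

    probe_id: str
    gene_id: str
    start: int
    length: int
    sequence: str
    min_cross_distance: int
    nearest_nontarget: str
    dist_to_3prime: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.length <= 0:
            raise ValidationError(f"probe {self.probe_id}: bad coordinates")
        if self.min_cross_distance < 0:
            raise ValidationError(f"probe {self.probe_id}: negative distance")
        if self.dist_to_3prime < 0:
            raise ValidationError(f"probe {self.probe_id}: negative 3' distance")
        if len(self.sequence) != self.length:
            raise ValidationError(
                f"probe {self.probe_id}: sequence length != declared length"
            )


@dataclass(frozen=True)
class IntensityRecord:
    """One probe x sample signal on the linear scale, with a detection flag."""

    probe_id: str
    sample_id: str
    intensity: float
    detected: bool = False

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError(f"probe {self.probe_id}: negative intensity")
        if self.intensity > INTENSITY_CEILING:
            raise ValidationError(
                f"probe {self.probe_id}: intensity above 2^20 ceiling"
            )


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    for pos, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValidationError(
                f"record {record_id}: invalid character {base!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | Path, species_label: str) -> list[TranscriptRecord]:
    """Read a FASTA transcript set, normalizing and validating each record.

    Sequences are uppercased and U is mapped to T.  Duplicate ids, empty
    files, empty sequences and non-IUPAC characters (outside A/C/G/T/N) are
    hard errors.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate transcript id: {rec.id}")
        seen.add(rec.id)
        seq = _normalize_sequence(str(rec.seq), rec.id)
        if len(seq) < 1:
            raise ValidationError(f"record {rec.id}: empty sequence")
        records.append(
            TranscriptRecord(
                id=rec.id,
                species=species_label,
                sequence=seq,
                description=rec.description,
            )
        )
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


PROBE_TABLE_COLUMNS = [
    "probe_id",
    "gene_id",
    "start",
    "length",
    "sequence",
    "min_cross_distance",
    "nearest_nontarget",
    "dist_to_3prime",
]


def write_probe_table(rows: Sequence[ProbeTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                r.probe_id,
                r.gene_id,
                r.start,
                r.length,
                r.sequence,
                r.min_cross_distance,
                r.nearest_nontarget if r.nearest_nontarget else "NA",
                r.dist_to_3prime,
            )
            for r in rows
        ],
        columns=PROBE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> list[ProbeTableRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PROBE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    rows: list[ProbeTableRow] = []
    for idx, rec in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        try:
            rows.append(
                ProbeTableRow(
                    probe_id=rec.probe_id,
                    gene_id=rec.gene_id,
                    start=int(rec.start),
                    length=int(rec.length),
                    sequence=rec.sequence,
                    min_cross_distance=int(rec.min_cross_distance),
                    nearest_nontarget=""
                    if rec.nearest_nontarget == "NA"
                    else rec.nearest_nontarget,
                    dist_to_3prime=int(rec.dist_to_3prime),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: malformed row at line {line_no}: {exc}")
    return rows


INTENSITY_TABLE_COLUMNS = ["probe_id", "sample_id", "intensity", "detected"]


def write_intensity_table(
    records: Sequence[IntensityRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(r.probe_id, r.sample_id, repr(r.intensity), r.detected) for r in records],
        columns=INTENSITY_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_intensity_table(path: str | Path) -> list[IntensityRecord]:
    """Read a probe x sample intensity table.

    Intensities above the 2^20 scanner ceiling are clamped with a logged
    warning; negative or non-finite intensities are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INTENSITY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records: list[IntensityRecord] = []
    for idx, rec in enumerate(df.itertuples(index=False)):
        line_no = idx + 2
        try:
            intensity = float(rec.intensity)
        except ValueError:
            raise ValidationError(f"{path}: bad intensity at line {line_no}")
        if not math.isfinite(intensity) or intensity < 0:
            raise ValidationError(
                f"{path}: negative or non-finite intensity at line {line_no}"
            )
        if intensity > INTENSITY_CEILING:
            logger.warning(
                "%s line %d: intensity %g above 2^20 ceiling, clamped",
                path,
                line_no,
                intensity,
            )
            intensity = float(INTENSITY_CEILING)
        detected = rec.detected.strip().lower() in {"true", "1", "yes"}
        records.append(
            IntensityRecord(
                probe_id=rec.probe_id,
                sample_id=rec.sample_id,
                intensity=intensity,
                detected=detected,
            )
        )
    return records


def read_known_homologs(path: str | Path) -> list[tuple[str, str]]:
    """Known-homolog pairs: columns gene_id_species_A, gene_id_species_B."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id_species_A", "gene_id_species_B"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    return list(zip(df["gene_id_species_A"], df["gene_id_species_B"]))


def write_known_homologs(
    pairs: Iterable[tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(pairs, columns=["gene_id_species_A", "gene_id_species_B"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> dict[str, str]:
    """Gene annotation table: columns gene_id, annotation."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "annotation"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    return dict(zip(df["gene_id"], df["annotation"]))


def write_annotations(annotations: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(annotations.items()), columns=["gene_id", "annotation"]
    ).to_csv(path, sep="\t", index=False)
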