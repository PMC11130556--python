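"""Reading and writing aligned barcode data.

The on-disk formats are deliberately plain: aligned FASTA for sequences, a
two-column TSV (``record_id<TAB>species``, ``#`` comments allowed) for species
labels, and a square CSV of percent distances for matrices.  Species labels in
a TSV are canonical; when no table is supplied the token after the final ``|``
of a FASTA header is used, and records without either get ``"unassigned"``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

#: IUPAC nucleotide alphabet plus the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: IUPAC code -> set of bases it covers.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: set of bases -> minimal IUPAC code covering it.
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

UNASSIGNED = "unassigned"


class SequenceError(ValueError):
    """A sequence violates the IUPAC-plus-gap alphabet or an alignment invariant."""


def normalize_sequence(raw: str) -> str:
    """Normalise a raw nucleotide string to the IUPAC alphabet.

    Uppercases, maps U to T, strips whitespace and digits (as found in
    GenBank-style formatted sequence blocks).  Any remaining character outside
    ``{A,C,G,T,R,Y,S,W,K,M,B,D,H,V,N,-}`` raises :class:`SequenceError` naming
    the character and its 1-based position in the cleaned sequence.
    """
    cleaned = "".join(
        ch for ch in raw.upper() if not (ch.isspace() or ch.isdigit())
    ).replace("U", "T")
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in IUPAC_CHARS:
            raise SequenceError(
                f"invalid character {ch!r} at position {pos}: not an IUPAC nucleotide code"
            )
    return cleaned


@dataclass
class BarcodeRecord:
    """One identified barcode sequence.

    ``species`` is a free-text label (``"unassigned"`` when unknown);
    ``metadata`` holds free-form key/value pairs such as locality or a BOLD
    process ID.
    """

    record_id: str
    sequence: str
    species: str = UNASSIGNED
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        self.sequence = normalize_sequence(self.sequence)
        if not self.sequence:
            raise SequenceError(f"record {self.record_id!r}: empty sequence")

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")


class Alignment:
    """An ordered collection of equal-length :class:`BarcodeRecord`."""

    def __init__(self, records: Iterable[BarcodeRecord]):
        self.records: list[BarcodeRecord] = list(records)
        if not self.records:
            raise ValueError("alignment needs at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)
        lengths = {rec.record_id: len(rec.sequence) for rec in self.records}
        if len(set(lengths.values())) > 1:
            detail = ", ".join(f"{rid}={n}" for rid, n in sorted(lengths.items()))
            raise SequenceError(f"records differ in aligned length: {detail}")
        self.length: int = len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> BarcodeRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    @property
    def ids(self) -> list[str]:
        return [rec.record_id for rec in self.records]

    @property
    def labels(self) -> dict[str, str]:
        """record_id -> species mapping."""
        return {rec.record_id: rec.species for rec in self.records}

    def to_array(self) -> np.ndarray:
        """Alignment as an (n_records, length) array of single-byte strings."""
        return np.array([list(rec.sequence) for rec in self.records], dtype="U1")


def read_labels(labels_path: str | Path) -> dict[str, str]:
    """Read a record_id<TAB>species table; ``#`` starts a comment line."""
    labels: dict[str, str] = {}
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{labels_path}:{lineno}: expected record_id<TAB>species, got {line!r}"
                )
            labels[parts[0].strip()] = parts[1].strip()
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# record_id\tspecies\n")
        for rid, sp in labels.items():
            fh.write(f"{rid}\t{sp}\n")


def _parse_header(seq_id: str, description: str) -> tuple[str, str]:
    """Split a FASTA header into (record_id, species).

    The convention is ``>record_id|species`` with the species taken after the
    final ``|`` (it may contain spaces); headers without a ``|`` keep the
    whitespace-delimited id and get ``"unassigned"``.
    """
    if "|" in description:
        head, tail = description.rsplit("|", 1)
        if tail.strip():
            return head.strip(), tail.strip()
    return seq_id, UNASSIGNED


def read_alignment(
    fasta_path: str | Path, labels_path: str | Path | None = None
) -> Alignment:
    """Read an aligned FASTA, normalise every sequence, attach species labels.

    A labels TSV takes precedence; records absent from it fall back to the
    FASTA-header convention (token after the final ``|``) and finally to
    ``"unassigned"``.  Label-table ids without a sequence, and sequences
    without a label entry when a table was given, each emit a warning.
    """
    labels = read_labels(labels_path) if labels_path is not None else None
    records = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid, species = _parse_header(seq_rec.id, seq_rec.description)
        if labels is not None:
            if rid in labels:
                species = labels[rid]
            else:
                warnings.warn(
                    f"record {rid!r} has no entry in the labels table",
                    stacklevel=2,
                )
        records.append(BarcodeRecord(rid, str(seq_rec.seq), species))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    if labels is not None:
        present = {rec.record_id for rec in records}
        for rid in labels:
            if rid not in present:
                warnings.warn(
                    f"labels table id {rid!r} has no sequence in {fasta_path}",
                    stacklevel=2,
                )
    return Alignment(records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write aligned FASTA, wrapped at 80 columns, ``>record_id|species``
    headers (plain ``>record_id`` for unassigned records)."""
    with open(path, "w") as fh:
        for rec in aln:
            if rec.species != UNASSIGNED:
                fh.write(f">{rec.record_id}|{rec.species}\n")
            else:
                fh.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


def write_distance_csv(matrix, path: str | Path) -> None:
    """Write a square labelled CSV of percent distances to one decimal.

    Mirrors the shape of published barcode distance matrices: header row and
    column of record ids, percent cells, 0.0 diagonal.  Undefined entries
    (zero comparable sites) are written as ``NA``.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(matrix.ids))
        for i, rid in enumerate(matrix.ids):
            row = [rid]
            for j in range(len(matrix.ids)):
                if matrix.comparable[i, j] == 0 and i != j:
                    row.append("NA")
                else:
                    row.append(f"{100.0 * matrix.d[i, j]:.1f}")
            w.writerow(row)


def read_distance_csv(path: str | Path):
    """Read a matrix written by :func:`write_distance_csv` (percent, one decimal)."""
    from .distances import DistanceMatrix, DistancePolicy

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    ids = rows[0][1:]
    n = len(ids)
    d = np.zeros((n, n))
    comparable = np.ones((n, n), dtype=int)
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            if cell == "NA":
                d[i, j] = np.nan
                comparable[i, j] = 0
            else:
                d[i, j] = float(cell) / 100.0
    return DistanceMatrix(ids=ids, d=d, comparable=comparable,
                          policy=DistancePolicy.STRICT)
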