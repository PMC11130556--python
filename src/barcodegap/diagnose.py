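"""Detection of clade-diagnostic in-frame deletions in barcode alignments.

A deletion shared by every member of a clade and absent outside it is a
synapomorphy usable as a molecular diagnostic character.  For a
protein-coding marker the interesting case is a frame-preserving gap (length
divisible by 3), which deletes whole amino acids instead of wrecking the
reading frame.  This module infers the reading frame of a gap-free reference
by minimising internal stop codons under the invertebrate mitochondrial code
(NCBI translation table 5, the appropriate code for insect COI, where ATA is
Met and TGA is Trp), translates sequences, finds maximal gap runs shared
across the ingroup relative to the reference, and renders a verdict against
an expected gap length and alignment region.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

from Bio.Data import CodonTable

from .seqio import IUPAC_SETS, Alignment

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_STOPS = frozenset(_TABLE5.stop_codons)

#: default alignment-column window in which the genus-diagnostic gap is
#: expected; a window rather than a point because the surrounding region is
#: highly variable and the exact homologous position is uncertain.
DEFAULT_EXPECTED_REGION = (450, 510)
DEFAULT_EXPECTED_LENGTH = 6


@dataclass
class IndelReport:
    """A maximal run of shared gap columns, 1-based inclusive coordinates."""

    column_start: int
    length_bp: int
    shared_by: frozenset[str]
    reference_id: str

    @property
    def frame_preserving(self) -> bool:
        return self.length_bp % 3 == 0

    @property
    def aa_deleted(self) -> int | None:
        return self.length_bp // 3 if self.frame_preserving else None

    @property
    def column_end(self) -> int:
        return self.column_start + self.length_bp - 1


@dataclass
class DiagnosticVerdict:
    positive: bool
    reports: list[IndelReport]
    failing_records: list[str]
    detail: str


def _codon_resolutions(codon: str) -> list[str]:
    sets = [sorted(IUPAC_SETS[c]) for c in codon]
    return ["".join(p) for p in product(*sets)]


def detect_reading_frame(seq: str, table_id: int = 5) -> int:
    """Frame offset (0, 1 or 2) minimising internal stop codons.

    Codons containing ambiguity codes are skipped when counting stops; ties
    go to the smallest offset.  Requires a gap-free sequence of >= 30 bp.
    """
    if "-" in seq:
        raise ValueError("reading-frame detection requires a gap-free sequence")
    if len(seq) < 30:
        raise ValueError("sequence shorter than 30 bp; frame detection unreliable")
    stops = frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    counts = []
    for off in range(3):
        n = 0
        for i in range(off, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGT") and codon in stops:
                n += 1
        counts.append(n)
    return counts.index(min(counts))


def translate_mito(seq: str, offset: int = 0, table_id: int = 5) -> str:
    """Translate under the invertebrate mitochondrial code.

    Codons containing ambiguity codes are translated when every resolution
    yields the same amino acid (e.g. GGR -> G), otherwise emitted as X; stop
    codons become ``*``; a trailing partial codon is dropped.
    """
    if "-" in seq:
        raise ValueError("translation requires a gap-free sequence")
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aas = set()
        for res in _codon_resolutions(codon):
            aas.add("*" if res in table.stop_codons else table.forward_table[res])
        out.append(aas.pop() if len(aas) == 1 else "X")
    return "".join(out)


def detect_shared_deletions(
    aln: Alignment, reference_id: str, min_share: float = 1.0
) -> list[IndelReport]:
    """Maximal gap runs shared by the ingroup and absent in the reference.

    A column qualifies when the reference carries a base there and at least
    ``min_share`` of the non-reference records have a gap; qualifying columns
    are merged into maximal runs.  ``shared_by`` lists the records gapped
    across the entire run.  The default ``min_share`` of 1.0 demands a
    universal (diagnostic) character; relax it for exploratory scans.
    """
    ref = aln[reference_id]
    others = [rec for rec in aln if rec.record_id != reference_id]
    if not others:
        raise ValueError("alignment holds only the reference record")
    n = len(others)
    qualifying = []
    for col in range(aln.length):
        if ref.sequence[col] == "-":
            qualifying.append(False)
            continue
        gapped = sum(1 for rec in others if rec.sequence[col] == "-")
        qualifying.append(gapped / n >= min_share)
    reports: list[IndelReport] = []
    col = 0
    while col < aln.length:
        if not qualifying[col]:
            col += 1
            continue
        start = col
        while col < aln.length and qualifying[col]:
            col += 1
        length = col - start
        carriers = frozenset(
            rec.record_id
            for rec in others
            if all(rec.sequence[c] == "-" for c in range(start, col))
        )
        reports.append(
            IndelReport(
                column_start=start + 1,
                length_bp=length,
                shared_by=carriers,
                reference_id=reference_id,
            )
        )
    return reports


def diagnose_genus(
    aln: Alignment,
    reference_id: str,
    expected_length: int = DEFAULT_EXPECTED_LENGTH,
    expected_region: tuple[int, int] = DEFAULT_EXPECTED_REGION,
    min_share: float = 1.0,
) -> DiagnosticVerdict:
    """Verdict on a clade-diagnostic deletion of the expected size and place.

    Positive iff exactly one shared deletion of ``expected_length`` bp
    overlaps ``expected_region`` (1-based inclusive alignment columns) and is
    carried by every non-reference record; otherwise negative, naming the
    records that lack the gap.
    """
    reports = detect_shared_deletions(aln, reference_id, min_share=min_share)
    lo, hi = expected_region
    in_region = [
        r for r in reports if r.column_start <= hi and r.column_end >= lo
    ]
    matching = [r for r in in_region if r.length_bp == expected_length]
    all_ids = {rec.record_id for rec in aln if rec.record_id != reference_id}
    if len(matching) != 1:
        detail = (
            f"expected exactly one shared {expected_length} bp deletion in "
            f"columns {lo}-{hi}; found {len(matching)} "
            f"(all shared gaps in region: {[ (r.column_start, r.length_bp) for r in in_region ]})"
        )
        return DiagnosticVerdict(False, reports, sorted(all_ids), detail)
    report = matching[0]
    failing = sorted(all_ids - report.shared_by)
    positive = not failing
    detail = (
        f"{report.length_bp} bp deletion at columns "
        f"{report.column_start}-{report.column_end}"
        + (
            f" ({report.aa_deleted} amino acids, frame-preserving)"
            if report.frame_preserving
            else " (frame-disrupting)"
        )
        + (
            "; carried by all queried records"
            if positive
            else f"; absent in: {', '.join(failing)}"
        )
    )
    return DiagnosticVerdict(positive, reports, failing, detail)


def diagnostic_report(verdict: DiagnosticVerdict) -> str:
    lines = [
        f"verdict\t{'positive' if verdict.positive else 'negative'}",
        f"detail\t{verdict.detail}",
    ]
    for r in verdict.reports:
        lines.append(
            f"gap\tcolumns {r.column_start}-{r.column_end}\t{r.length_bp} bp\t"
            f"frame_preserving={r.frame_preserving}\tshared_by={len(r.shared_by)} records"
        )
    return "\n".join(lines) + "\n"
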