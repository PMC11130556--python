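"""Packaged reference dataset: the seven published *Phaenoglyphis* barcodes.

The seven published consensus/representative CO1 barcodes (652 bp each, one
per species) ship with the package as an aligned FASTA plus a species-label
table, so the whole pipeline runs without any download.  All seven carry the
genus-diagnostic 6 bp deletion, so a full-length (658-column) outgroup-like
reference for indel detection is reconstructed by re-inserting six neutral
bases at the deletion site of the *P. villosa* sequence.  That reference is
synthetic — a stand-in for a full-length relative lacking the deletion — and
is only used as the gap-free baseline for the indel detector.
"""

from __future__ import annotations

from importlib import resources

from .seqio import Alignment, BarcodeRecord, read_alignment

#: 1-based alignment column at which the diagnostic deletion is re-inserted.
DELETION_POSITION = 476
DELETION_LENGTH = 6

#: the record whose sequence seeds the reconstructed full-length reference
_REFERENCE_SOURCE = "P_villosa_CO1"
REFERENCE_ID = "REF_full_length_synthetic"

#: six neutral bases (two leucine codons in the barcode reading frame) used to
#: fill the re-opened deletion window; chosen to keep the reference
#: translation stop-free.
_NEUTRAL_INSERT = "TTATTA"


def _data_path(name: str):
    return resources.files("barcodegap.data").joinpath(name)


def load_printed_barcodes() -> Alignment:
    """The seven published 652 bp barcodes, one per species, species-labelled."""
    fasta = _data_path("phaenoglyphis_co1.fasta")
    labels = _data_path("phaenoglyphis_labels.tsv")
    with resources.as_file(fasta) as fp, resources.as_file(labels) as lp:
        return read_alignment(fp, lp)


def fixture_published_dataset() -> tuple[Alignment, dict[str, str]]:
    """Fixture alignment for the diagnostic-indel analysis.

    Returns an 8-record, 658-column alignment — the seven published barcodes
    padded with a 6-column gap at the deletion site, plus the reconstructed
    gap-free reference — together with the record->species labels (the
    synthetic reference is labelled ``"reference"``).
    """
    printed = load_printed_barcodes()
    cut = DELETION_POSITION - 1
    records = []
    for rec in printed:
        padded = rec.sequence[:cut] + "-" * DELETION_LENGTH + rec.sequence[cut:]
        records.append(BarcodeRecord(rec.record_id, padded, species=rec.species))
    source = printed[_REFERENCE_SOURCE].sequence
    ref_seq = source[:cut] + _NEUTRAL_INSERT + source[cut:]
    records.append(BarcodeRecord(REFERENCE_ID, ref_seq, species="reference"))
    aln = Alignment(records)
    return aln, aln.labels
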