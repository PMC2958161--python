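"""Sequence input/output, ORF inference and UTR extraction.

Coordinates are 0-based half-open everywhere inside the package; the
rendering helpers (:func:`to_one_based`) convert to 1-based inclusive for
human-readable reports.  Only forward-strand ORFs are considered because the
inputs are transcripts, not genomic contigs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_IUPAC = frozenset("ACGTRYSWKMBDHVN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBJOUXZ*")
START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FastaParseError(ValueError):
    """Raised when a FASTA entry is malformed or contains illegal characters."""


@dataclass(frozen=True)
class Region:
    """Half-open interval [start, end) on a sequence, with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.start < other.end and other.start < self.end

    def intersection_length(self, other: "Region") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def to_one_based(region: Region) -> tuple[int, int]:
    """Render a half-open region as 1-based inclusive (start, end) for reports."""
    return region.start + 1, region.end


@dataclass(frozen=True)
class NucleotideRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        for pos, ch in enumerate(self.sequence):
            if ch not in DNA_IUPAC:
                raise FastaParseError(
                    f"record {self.id!r}: illegal nucleotide {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        for pos, ch in enumerate(self.sequence):
            if ch not in PROTEIN_ALPHABET:
                raise FastaParseError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame on the forward strand of a transcript.

    ``orf`` spans start codon through stop codon inclusive.  ``source`` records
    whether the coordinates were supplied by the caller ("provided") or found
    by :func:`find_orf` ("inferred").
    """

    orf: Region
    source: str

    def __post_init__(self) -> None:
        if self.source not in ("provided", "inferred"):
            raise ValueError(f"unknown ORF source {self.source!r}")
        if len(self.orf) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.orf.strand != "+":
            raise ValueError("only forward-strand ORFs are supported")


def read_fasta(
    path: Union[str, Path], alphabet: str = "dna"
) -> list:
    """Read a multi-record FASTA file.

    Identifiers are the first whitespace-delimited token of each header;
    sequences are upper-cased.  ``alphabet`` selects validation: "dna" accepts
    IUPAC nucleotide codes, "protein" accepts amino-acid codes.  Record order
    is preserved.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    cls = NucleotideRecord if alphabet == "dna" else ProteinRecord
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(cls(id=rec.id, sequence=str(rec.seq), description=rec.description))
    return records


def write_fasta(records: Iterable, path: Union[str, Path], width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def find_orf(
    record: NucleotideRecord, provided: Optional[Region] = None
) -> Optional[OrfAnnotation]:
    """Locate the transcript's ORF.

    With ``provided``, the coordinates are validated and returned verbatim
    (source="provided").  Otherwise the longest forward-strand ORF starting at
    an ATG and ending at the first in-frame stop codon (stop included) is
    returned, ties broken toward the smallest start.  Codons containing
    ambiguity codes are never accepted as start or stop.  Returns ``None`` when
    no ORF exists — an explicit "no ORF" result, not an error.
    """
    seq = record.sequence
    n = len(seq)
    if provided is not None:
        if provided.end > n:
            raise ValueError(
                f"provided ORF [{provided.start}, {provided.end}) exceeds "
                f"sequence length {n}"
            )
        return OrfAnnotation(orf=provided, source="provided")

    # Per-frame sorted stop positions allow O(log n) lookup of the first
    # in-frame stop after each ATG.
    stops_by_frame: list[list[int]] = [[], [], []]
    for i in range(n - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)

    best: Optional[tuple[int, int]] = None  # (length, -start) maximised
    best_region: Optional[Region] = None
    for i in range(n - 2):
        if seq[i : i + 3] != START_CODON:
            continue
        stops = stops_by_frame[i % 3]
        j = bisect.bisect_left(stops, i + 3)
        if j == len(stops):
            continue
        stop = stops[j]
        length = stop + 3 - i
        key = (length, -i)
        if best is None or key > best:
            best = key
            best_region = Region(i, stop + 3)
    if best_region is None:
        return None
    return OrfAnnotation(orf=best_region, source="inferred")


def extract_utrs(
    record: NucleotideRecord, orf: OrfAnnotation
) -> tuple[Optional[Region], Optional[Region]]:
    """Derive the 5' and 3' UTRs flanking an ORF.

    Returns ``(five_prime, three_prime)``; either may be ``None`` when the ORF
    abuts the corresponding transcript end.  Together with the ORF the regions
    partition the record.
    """
    n = len(record)
    if orf.orf.end > n:
        raise ValueError("ORF extends beyond the record")
    five = Region(0, orf.orf.start) if orf.orf.start > 0 else None
    three = Region(orf.orf.end, n) if orf.orf.end < n else None
    return five, three


def write_bed6(
    intervals: Sequence[tuple[str, int, int, str, int, str]],
    path: Union[str, Path],
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6.

    Coordinates are the package's native 0-based half-open, matching BED.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
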