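"""Reading and writing per-species proteome FASTA files.

Each proteome file is a multi-record FASTA; every record is tagged with a
short species label (e.g. ``"flaxseed"``) so that downstream uniqueness
screening can attribute peptides to species. Parsing is intentionally
permissive about headers (UniProt-style or ad hoc) and strict about
content: empty sequences and duplicate accessions are hard errors rather
than silent drops.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["AMBIGUOUS_LETTERS", "ProteinRecord", "read_fasta", "write_fasta"]

#: Letters legal in FASTA protein records but without a defined residue mass.
AMBIGUOUS_LETTERS = frozenset("BJZXUO")

_VALID_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY") | AMBIGUOUS_LETTERS


@dataclass(frozen=True)
class ProteinRecord:
    """One protein entry of a species proteome.

    Attributes
    ----------
    accession:
        First whitespace-delimited token of the FASTA header.
    description:
        The full header line (without ``>``), preserved verbatim.
    species_tag:
        Short species label attached at read time, e.g. ``"quinoa"``.
    sequence:
        Uppercase amino-acid sequence; may contain ambiguity letters
        (B/J/Z/X/U/O), which downstream digestion excludes from peptides.
    """

    accession: str
    description: str
    species_tag: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        if not self.species_tag:
            raise ValueError(f"record {self.accession!r}: species_tag must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.accession!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_LETTERS
        if bad:
            raise ValueError(
                f"record {self.accession!r} contains non-amino-acid letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, species_tag: str) -> list[ProteinRecord]:
    """Parse one proteome FASTA file and tag every record with a species.

    Sequences are uppercased and trailing stop characters (``*``) stripped;
    record order is preserved. Wrapped and single-line sequences are both
    accepted.

    Raises
    ------
    ValueError
        On an empty file, a header with no sequence, or a duplicate
        accession within the file (the offending header is named).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        sequence = str(entry.seq).upper().rstrip("*")
        if not sequence:
            raise ValueError(f"{path}: record {header!r} has an empty sequence")
        accession = entry.id
        if accession in seen:
            raise ValueError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                description=header,
                species_tag=species_tag,
                sequence=sequence,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records back to FASTA (60-column wrapped)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
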