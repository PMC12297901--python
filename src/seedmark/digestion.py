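"""In silico tryptic digestion.

Trypsin cleaves C-terminal to lysine (K) and arginine (R); under the
classical Keil rule the cut is suppressed when the next residue is
proline. Peptides carrying up to a configurable number of missed
cleavages (internal uncut K/R sites) are enumerated, then filtered by a
length window. The defaults — no missed cleavages, length 5–30, proline
rule on — reflect common targeted-proteomics practice for marker-peptide
selection.

Peptides containing ambiguity letters (B/J/Z/X/U/O) have no defined mass
and are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .proteome_io import AMBIGUOUS_LETTERS, ProteinRecord

__all__ = ["DigestParams", "PeptideOccurrence", "cleavage_sites", "digest", "digest_sequence"]


@dataclass(frozen=True)
class DigestParams:
    """Tryptic-digestion parameters.

    Attributes
    ----------
    max_missed_cleavages:
        Maximum internal uncut K/R sites per peptide (default 0).
    min_length, max_length:
        Inclusive peptide-length window (default 5–30 residues).
    proline_rule:
        If true (default), no cleavage when K/R is followed by P.
    exclude_ambiguous:
        If true (default), peptides containing B/J/Z/X/U/O are dropped.
    """

    max_missed_cleavages: int = 0
    min_length: int = 5
    max_length: int = 30
    proline_rule: bool = True
    exclude_ambiguous: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


@dataclass(frozen=True)
class PeptideOccurrence:
    """One digestion product located within its parent protein.

    Coordinates are 1-based and inclusive, so
    ``end - start + 1 == len(sequence)`` and the peptide equals the parent
    subsequence at ``[start, end]``.
    """

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates [{self.start}, {self.end}] do not span "
                f"{len(self.sequence)}-residue peptide {self.sequence!r}"
            )


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based positions *after* which trypsin cuts.

    A site ``i`` means the bond between ``sequence[i]`` and
    ``sequence[i+1]`` is cleaved; the sequence terminus is not a site.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def digest_sequence(
    sequence: str, params: DigestParams = DigestParams(), parent_accession: str = ""
) -> list[PeptideOccurrence]:
    """Digest a bare sequence; see :func:`digest`."""
    sites = cleavage_sites(sequence, params.proline_rule)
    # fragment boundaries: 0-based [begin, stop) half-open
    begins = [0] + [s + 1 for s in sites]
    stops = [s + 1 for s in sites] + [len(sequence)]

    out: list[PeptideOccurrence] = []
    n_frag = len(begins)
    for i in range(n_frag):
        for mc in range(0, params.max_missed_cleavages + 1):
            j = i + mc
            if j >= n_frag:
                break
            begin, stop = begins[i], stops[j]
            length = stop - begin
            if not (params.min_length <= length <= params.max_length):
                continue
            pep = sequence[begin:stop]
            if params.exclude_ambiguous and set(pep) & AMBIGUOUS_LETTERS:
                continue
            out.append(
                PeptideOccurrence(
                    sequence=pep,
                    parent_accession=parent_accession,
                    start=begin + 1,
                    end=stop,
                    missed_cleavages=mc,
                )
            )
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def digest(record: ProteinRecord, params: DigestParams = DigestParams()) -> list[PeptideOccurrence]:
    """Enumerate tryptic peptides of one protein.

    Cleavage occurs after every K/R (suppressed before P when the proline
    rule is active); peptides spanning 0..``max_missed_cleavages`` internal
    sites are enumerated; the length filter applies afterwards. The
    C-terminal peptide is included even without a terminal K/R. Output is
    deterministically ordered by start position, then length.
    """
    return digest_sequence(record.sequence, params, record.accession)
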