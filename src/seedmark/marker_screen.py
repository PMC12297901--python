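"""Cross-proteome peptide uniqueness screening and marker ranking.

A peptide can only serve as a species marker if it occurs in exactly one
species across the combined proteomes of every species under
consideration. This module digests all background proteomes into a
peptide → (species, accession) index, classifies each candidate peptide
as unique / shared / I-L-ambiguous, and ranks the surviving candidates
into quantifier and qualifier roles.

Isoleucine and leucine are isobaric and indistinguishable by low-energy
CID m/z alone, so uniqueness is additionally assessed on I/L-collapsed
sequences: a peptide whose exact sequence is species-specific but whose
I/L isomer occurs elsewhere is flagged ``il_ambiguous`` rather than
silently accepted or rejected.

Ranking follows four marker-selection criteria: high and reproducible
signal intensity; good intensity distribution among the monitored
transitions; chromatographic/spectral stability (represented through a
penalty on oxidation-prone residues, Cys in particular, plus Trp and
Met); and minimal cysteine content. The combined score is

    score = w1 * log10(median normalized area)        (0 without data)
          - w2 * #C - w3 * #W - w4 * #M
          + w5 * transition-distribution evenness

with documented default weights. Per parent protein the top-scoring
unique peptide becomes the quantifier and the next one or two become
qualifiers (at most three markers per protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .digestion import DigestParams, digest
from .proteome_io import ProteinRecord
from .transition_builder import transition_distribution_score

__all__ = [
    "BackgroundProteomeSet",
    "PeptideIndex",
    "Uniqueness",
    "ScoreWeights",
    "MarkerCandidate",
    "collapse_il",
    "build_peptide_index",
    "screen_uniqueness",
    "screen_proteome",
    "rank_candidates",
]

#: Joint symbol for the I/L isobaric pair in canonical peptide forms.
_IL_SYMBOL = "J"


def collapse_il(sequence: str) -> str:
    """Map I and L to a joint symbol (isobaric under low-energy CID)."""
    return sequence.replace("I", _IL_SYMBOL).replace("L", _IL_SYMBOL)


@dataclass(frozen=True)
class BackgroundProteomeSet:
    """The combined per-species proteomes screened against."""

    proteomes: Mapping[str, Sequence[ProteinRecord]]
    digest_params: DigestParams = DigestParams()

    def __post_init__(self) -> None:
        if not self.proteomes:
            raise ValueError("background proteome set must contain >= 1 species")
        for tag, records in self.proteomes.items():
            for rec in records:
                if rec.species_tag != tag:
                    raise ValueError(
                        f"record {rec.accession!r} tagged {rec.species_tag!r} "
                        f"listed under species {tag!r}"
                    )


@dataclass(frozen=True)
class Uniqueness:
    """Classification of a peptide against the combined background.

    ``status`` is one of ``"unique"``, ``"shared"``, ``"il_ambiguous"``;
    ``species`` lists every species hit (for unique peptides, exactly one).
    """

    status: str
    species: frozenset[str]

    @property
    def is_unique(self) -> bool:
        return self.status == "unique"


class PeptideIndex:
    """Exact and I/L-collapsed tryptic-peptide indexes over a background.

    Maps each canonical peptide to the set of ``(species_tag, accession)``
    pairs whose digestion produces it.
    """

    def __init__(self, background: BackgroundProteomeSet, il_collapse: bool = True):
        self.background = background
        self.il_collapse = il_collapse
        self.exact: dict[str, set[tuple[str, str]]] = {}
        self.collapsed: dict[str, set[tuple[str, str]]] = {}
        for tag, records in background.proteomes.items():
            for rec in records:
                for occ in digest(rec, background.digest_params):
                    hit = (tag, rec.accession)
                    self.exact.setdefault(occ.sequence, set()).add(hit)
                    if il_collapse:
                        self.collapsed.setdefault(collapse_il(occ.sequence), set()).add(hit)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.exact

    def species_of(self, peptide: str, collapsed: bool = False) -> frozenset[str]:
        table = self.collapsed if collapsed else self.exact
        key = collapse_il(peptide) if collapsed else peptide
        return frozenset(s for s, _ in table.get(key, ()))


def build_peptide_index(
    proteomes: BackgroundProteomeSet | Mapping[str, Sequence[ProteinRecord]],
    params: DigestParams | None = None,
    il_collapse: bool = True,
) -> PeptideIndex:
    """Digest every background protein and index peptides by origin."""
    if not isinstance(proteomes, BackgroundProteomeSet):
        proteomes = BackgroundProteomeSet(proteomes, params or DigestParams())
    elif params is not None and params != proteomes.digest_params:
        proteomes = BackgroundProteomeSet(proteomes.proteomes, params)
    return PeptideIndex(proteomes, il_collapse=il_collapse)


def screen_uniqueness(peptide: str, index: PeptideIndex, il_collapse: bool | None = None) -> Uniqueness:
    """Classify one tryptic peptide against the combined background.

    ``unique``: every exact (and, when I/L collapsing is active,
    collapsed) hit lies in a single species. ``shared``: the exact
    sequence occurs in more than one species. ``il_ambiguous``: the exact
    sequence is single-species but an I/L isomer occurs in another.

    Raises
    ------
    KeyError
        If the peptide is not a tryptic product of the background at all.
    """
    if il_collapse is None:
        il_collapse = index.il_collapse
    exact_species = index.species_of(peptide)
    if not exact_species:
        raise KeyError(
            f"peptide {peptide!r} is not a tryptic product of the background proteomes"
        )
    if len(exact_species) > 1:
        return Uniqueness("shared", exact_species)
    if il_collapse:
        collapsed_species = index.species_of(peptide, collapsed=True)
        if len(collapsed_species) > 1:
            return Uniqueness("il_ambiguous", collapsed_species)
    return Uniqueness("unique", exact_species)


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the marker-candidate score; all configurable."""

    intensity: float = 1.0  # on log10 median normalized area
    cysteine: float = 2.0
    tryptophan: float = 0.5
    methionine: float = 0.5
    distribution: float = 0.5


@dataclass(frozen=True)
class MarkerCandidate:
    """A candidate marker peptide with uniqueness, score, and role."""

    sequence: str
    species_tag: str
    parent_accessions: frozenset[str]
    uniqueness: Uniqueness
    score: float = 0.0
    score_components: Mapping[str, float] = field(default_factory=dict)
    role: str = "unassigned"  # quantifier | qualifier | disqualified | unassigned

    def __post_init__(self) -> None:
        if not self.uniqueness.is_unique and self.role not in ("disqualified", "unassigned"):
            raise ValueError(
                f"non-unique peptide {self.sequence!r} cannot hold role {self.role!r}"
            )


def screen_proteome(
    records: Sequence[ProteinRecord],
    index: PeptideIndex,
    params: DigestParams | None = None,
) -> list[MarkerCandidate]:
    """Digest one species' proteins and classify every peptide.

    Returns one candidate per distinct peptide sequence, with parent
    accessions merged; non-unique peptides arrive pre-disqualified.
    """
    params = params or index.background.digest_params
    by_seq: dict[str, set[str]] = {}
    species = None
    for rec in records:
        if species is None:
            species = rec.species_tag
        elif rec.species_tag != species:
            raise ValueError("screen_proteome expects records from a single species")
        for occ in digest(rec, params):
            by_seq.setdefault(occ.sequence, set()).add(rec.accession)
    out = []
    for seq in sorted(by_seq):
        uniq = screen_uniqueness(seq, index)
        out.append(
            MarkerCandidate(
                sequence=seq,
                species_tag=species or "",
                parent_accessions=frozenset(by_seq[seq]),
                uniqueness=uniq,
                role="unassigned" if uniq.is_unique else "disqualified",
            )
        )
    return out


def _score(
    candidate: MarkerCandidate,
    intensities: Mapping[str, Sequence[float]] | None,
    transition_intensities: Mapping[str, Sequence[float]] | None,
    weights: ScoreWeights,
) -> MarkerCandidate:
    seq = candidate.sequence
    values = list(intensities.get(seq, ())) if intensities else []
    if values:
        med = float(_median(values))
        intensity_term = math.log10(med) if med > 0 else 0.0
    else:
        intensity_term = 0.0
    dist_term = 0.0
    if transition_intensities and seq in transition_intensities:
        dist_term = transition_distribution_score(transition_intensities[seq])
    n_c, n_w, n_m = seq.count("C"), seq.count("W"), seq.count("M")
    components = {
        "intensity": weights.intensity * intensity_term,
        "cysteine_penalty": -weights.cysteine * n_c,
        "tryptophan_penalty": -weights.tryptophan * n_w,
        "methionine_penalty": -weights.methionine * n_m,
        "distribution": weights.distribution * dist_term,
    }
    return replace(candidate, score=sum(components.values()), score_components=components)


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def rank_candidates(
    candidates: Iterable[MarkerCandidate],
    intensities: Mapping[str, Sequence[float]] | None = None,
    transition_intensities: Mapping[str, Sequence[float]] | None = None,
    weights: ScoreWeights = ScoreWeights(),
    max_markers_per_protein: int = 3,
) -> list[MarkerCandidate]:
    """Score candidates and assign quantifier/qualifier roles.

    Non-unique candidates are disqualified and excluded from roles. Per
    parent protein, the highest-scoring unique peptide becomes the
    quantifier and the next ``max_markers_per_protein - 1`` (default two)
    become qualifiers. Ties break deterministically by fewer cysteines,
    then fewer Trp+Met, then longer peptide, then lexicographic order.

    ``intensities`` maps peptide → replicate normalized areas (area per mg
    defatted flour); ``transition_intensities`` maps peptide → per-
    transition intensities for the distribution-evenness term.
    """
    candidates = list(candidates)
    if not candidates:
        return []
    species = {c.species_tag for c in candidates}
    if len(species) > 1:
        raise ValueError(f"candidates must belong to one species, got {sorted(species)}")

    scored = [_score(c, intensities, transition_intensities, weights) for c in candidates]

    def sort_key(c: MarkerCandidate):
        return (
            -c.score,
            c.sequence.count("C"),
            c.sequence.count("W") + c.sequence.count("M"),
            -len(c.sequence),
            c.sequence,
        )

    out: list[MarkerCandidate] = []
    disqualified = [replace(c, role="disqualified") for c in scored if not c.uniqueness.is_unique]
    eligible = [c for c in scored if c.uniqueness.is_unique]

    by_protein: dict[tuple[str, ...], list[MarkerCandidate]] = {}
    for c in eligible:
        by_protein.setdefault(tuple(sorted(c.parent_accessions)), []).append(c)
    for protein in sorted(by_protein):
        group = sorted(by_protein[protein], key=sort_key)
        for rank, cand in enumerate(group):
            if rank == 0:
                role = "quantifier"
            elif rank < max_markers_per_protein:
                role = "qualifier"
            else:
                role = "unassigned"
            out.append(replace(cand, role=role))
    out.extend(disqualified)
    out.sort(key=sort_key)
    return out
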