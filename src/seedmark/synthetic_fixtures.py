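"""Synthetic proteomes and peak-area datasets with known ground truth.

Every stage of the marker workflow is testable offline against fixtures
generated here: toy species proteomes with planted unique / shared /
I-L-variant peptides, replicate peak-area tables with prescribed
intra-/inter-day coefficients of variation, serial-dilution calibration
series, and authentic single-species sample sets.

Noise model: peak areas are positive and their scatter is relative, so
replicate and day effects are multiplicative lognormal factors with unit
mean and the requested CV (``sigma² = ln(1 + CV²)``, ``mu = −sigma²/2``).
Calibration series use additive gaussian noise, matching how departures
from linearity are assessed. Everything is reproducible from the fixture
seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import DigestParams, digest_sequence
from .marker_screen import MarkerCandidate, collapse_il
from .mrm_validation import PeakAreaRecord, records_to_frame
from .proteome_io import ProteinRecord, write_fasta

__all__ = [
    "FixtureSpec",
    "validate_planted_peptide",
    "make_synthetic_proteomes",
    "simulate_peak_areas",
    "simulate_dilution_series",
    "simulate_authentic_samples",
]

_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Proteome side: ``planted_unique`` maps species → peptides that must be
    species-specific; ``planted_shared`` lists (peptide, species set)
    pairs embedded in several species. Peak-area side: per-peptide true
    mean normalized areas plus intra-/inter-day CVs and the replication
    design (days × replicates).
    """

    n_species: int = 3
    proteins_per_species: int = 2
    protein_length: tuple[int, int] = (120, 240)
    planted_unique: Mapping[str, Sequence[str]] = field(default_factory=dict)
    planted_shared: Sequence[tuple[str, frozenset[str]]] = field(default_factory=tuple)
    rng_seed: int = 0
    true_mean_area: Mapping[str, float] = field(default_factory=dict)
    intra_day_cv: float = 0.05
    inter_day_cv: float = 0.03
    n_days: int = 3
    n_reps: int = 3
    flour_mg: float = 1.0
    dilution_levels: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.proteins_per_species < 1:
            raise ValueError("need >= 1 species and >= 1 protein per species")
        if self.intra_day_cv < 0 or self.inter_day_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        lo, hi = self.protein_length
        if not (10 <= lo <= hi):
            raise ValueError("protein_length must be an increasing range >= 10")

    def species_tags(self) -> list[str]:
        tags = [f"species_{i + 1}" for i in range(self.n_species)]
        extra = set(self.planted_unique) - set(tags)
        for pep, group in self.planted_shared:
            extra |= set(group) - set(tags)
        return tags + sorted(extra)


def validate_planted_peptide(peptide: str, params: DigestParams = DigestParams()) -> None:
    """Check that a planted peptide is a legal tryptic product.

    It must be over the 20 standard letters, within the digestion length
    window, end in K/R, not start with P (the flanking cleavage would be
    blocked), and contain no internal K/R except immediately before P.
    """
    if not set(peptide) <= set(_LETTERS.tolist()):
        raise ValueError(f"planted peptide {peptide!r} contains non-standard letters")
    if not (params.min_length <= len(peptide) <= params.max_length):
        raise ValueError(
            f"planted peptide {peptide!r} outside length window "
            f"[{params.min_length}, {params.max_length}]"
        )
    if peptide[-1] not in "KR":
        raise ValueError(f"planted peptide {peptide!r} must end in K or R")
    if peptide[0] == "P":
        raise ValueError(f"planted peptide {peptide!r} starts with P; flank cleavage blocked")
    for i, letter in enumerate(peptide[:-1]):
        if letter in "KR" and not (params.proline_rule and peptide[i + 1] == "P"):
            raise ValueError(
                f"planted peptide {peptide!r} has an internal cleavage site at {i + 1}"
            )


def _random_background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_LETTERS, size=length))


def _build_planted_protein(
    peptides: Sequence[str], total_length: int, rng: np.random.Generator
) -> str:
    """Background chunks interleaved with K-flanked planted peptides.

    Each peptide is preceded by a K flank and followed by a chunk that
    does not start with P, so both of its cleavage boundaries are intact.
    """
    n_chunks = len(peptides) + 1
    chunk_len = max(total_length // n_chunks, 5)
    parts = [_random_background(rng, chunk_len)]
    for pep in peptides:
        follower = _random_background(rng, chunk_len)
        while follower[0] == "P":  # would suppress cleavage after the peptide
            follower = _random_background(rng, chunk_len)
        parts.append("K" + pep + follower)
    return "".join(parts)


def _planting_plan(spec: FixtureSpec) -> dict[str, list[str]]:
    plan: dict[str, list[str]] = {tag: [] for tag in spec.species_tags()}
    for tag, peptides in spec.planted_unique.items():
        plan[tag].extend(peptides)
    for peptide, group in spec.planted_shared:
        for tag in group:
            plan[tag].append(peptide)
    return plan


def expected_uniqueness(spec: FixtureSpec) -> dict[str, tuple[str, frozenset[str]]]:
    """Ground-truth labels implied by the planting plan.

    A planted peptide is ``shared`` when its exact sequence sits in more
    than one species, ``il_ambiguous`` when the exact sequence is
    species-specific but an I/L isomer is planted elsewhere, else
    ``unique``.
    """
    plan = _planting_plan(spec)
    exact: dict[str, set[str]] = {}
    collapsed: dict[str, set[str]] = {}
    for tag, peptides in plan.items():
        for pep in peptides:
            exact.setdefault(pep, set()).add(tag)
            collapsed.setdefault(collapse_il(pep), set()).add(tag)
    truth = {}
    for pep, tags in exact.items():
        if len(tags) > 1:
            truth[pep] = ("shared", frozenset(tags))
        elif len(collapsed[collapse_il(pep)]) > 1:
            truth[pep] = ("il_ambiguous", frozenset(collapsed[collapse_il(pep)]))
        else:
            truth[pep] = ("unique", frozenset(tags))
    return truth


def make_synthetic_proteomes(
    spec: FixtureSpec,
    params: DigestParams = DigestParams(),
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[ProteinRecord]], pd.DataFrame]:
    """Generate per-species toy proteomes with planted peptides.

    Background sequences are uniform random over the 20 standard letters;
    planted peptides are embedded with a K flank at proline-free
    positions. A post-generation scan re-digests every protein and
    resamples any background that accidentally reproduces a planted
    peptide (exact or I/L-collapsed) outside its planting plan, so the
    ground truth is exact by construction.

    Returns the proteome mapping and a ground-truth table (peptide,
    expected status, species set). With ``out_dir``, one
    ``<species>.fasta`` per species and a ``ground_truth.csv`` are written.
    """
    for tag, peptides in spec.planted_unique.items():
        for pep in peptides:
            validate_planted_peptide(pep, params)
    for pep, _ in spec.planted_shared:
        validate_planted_peptide(pep, params)

    rng = np.random.default_rng(spec.rng_seed)
    plan = _planting_plan(spec)
    truth = expected_uniqueness(spec)
    planted_collapsed = {collapse_il(p) for p in truth}

    proteomes: dict[str, list[ProteinRecord]] = {}
    lo, hi = spec.protein_length
    for tag in spec.species_tags():
        records = []
        to_plant = list(plan[tag])
        for i in range(spec.proteins_per_species):
            allowed = {collapse_il(p) for p in to_plant} if i == 0 else set()
            for _ in range(200):
                length = int(rng.integers(lo, hi + 1))
                if i == 0 and to_plant:
                    seq = _build_planted_protein(to_plant, length, rng)
                else:
                    seq = _random_background(rng, length)
                products = {
                    collapse_il(o.sequence) for o in digest_sequence(seq, params)
                }
                if (products & planted_collapsed) <= allowed and allowed <= products:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("failed to generate a collision-free background")
            records.append(
                ProteinRecord(
                    accession=f"{tag.upper()}_{i + 1:03d}",
                    description=f"{tag} synthetic protein {i + 1}",
                    species_tag=tag,
                    sequence=seq,
                )
            )
        proteomes[tag] = records

    truth_df = pd.DataFrame(
        [
            {"peptide": pep, "expected_status": status, "species": ";".join(sorted(tags))}
            for pep, (status, tags) in sorted(truth.items())
        ],
        columns=["peptide", "expected_status", "species"],
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for tag, records in proteomes.items():
            write_fasta(records, out_dir / f"{tag}.fasta")
        truth_df.to_csv(out_dir / "ground_truth.csv", index=False)
    return proteomes, truth_df


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_peak_areas(
    spec: FixtureSpec,
    panel: Sequence[MarkerCandidate] | Mapping[str, str],
) -> pd.DataFrame:
    """Simulate a replicate peak-area table for a marker panel.

    For each panel peptide, day d and replicate r:
    ``area = true_mean · day_effect(d) · rep_noise(d, r)`` with lognormal
    day effects (CV = ``inter_day_cv``) and replicate noise
    (CV = ``intra_day_cv``). Raw areas carry the flour mass back in so
    that normalization recovers the simulated normalized scale.

    ``panel`` is either ranked marker candidates or a peptide → species
    mapping.
    """
    if not len(panel):
        raise ValueError("panel must be non-empty")
    if isinstance(panel, Mapping):
        pep_species = dict(panel)
    else:
        pep_species = {c.sequence: c.species_tag for c in panel}
    rng = np.random.default_rng(spec.rng_seed)
    records = []
    for pep in sorted(pep_species):
        true_mean = float(spec.true_mean_area.get(pep, 1_000_000.0))
        day_effects = _lognormal_factors(rng, spec.inter_day_cv, spec.n_days)
        rep_noise = _lognormal_factors(rng, spec.intra_day_cv, (spec.n_days, spec.n_reps))
        for d in range(spec.n_days):
            for r in range(spec.n_reps):
                normalized = true_mean * day_effects[d] * rep_noise[d, r]
                records.append(
                    PeakAreaRecord(
                        sample_id=f"sim_{pep_species[pep]}",
                        species_label=pep_species[pep],
                        peptide=pep,
                        replicate=r + 1,
                        day=d + 1,
                        raw_area=normalized * spec.flour_mg,
                        flour_mg=spec.flour_mg,
                    )
                )
    return records_to_frame(records)


def simulate_dilution_series(
    true_slope: float,
    levels: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    peptide: str = "PEPTIDER",
    species: str = "species_1",
    replicates: int = 1,
) -> pd.DataFrame:
    """Simulate a calibration series: area = slope · level + N(0, sd)."""
    levels = [float(x) for x in levels]
    if len(set(levels)) < 3:
        raise ValueError("dilution series requires >= 3 distinct levels")
    rng = np.random.default_rng(seed)
    records = []
    for level in levels:
        for r in range(replicates):
            area = true_slope * level + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            records.append(
                PeakAreaRecord(
                    sample_id=f"cal_{level:g}",
                    species_label=species,
                    peptide=peptide,
                    replicate=r + 1,
                    day=1,
                    raw_area=max(area, 0.0),
                    flour_mg=1.0,
                    dilution_level=level,
                )
            )
    return records_to_frame(records)


def simulate_authentic_samples(
    panel: Sequence[MarkerCandidate],
    true_mean_area: Mapping[str, float] | None = None,
    seed: int = 0,
    cv: float = 0.05,
    n_blanks: int = 1,
    flour_mg: float = 1.0,
) -> pd.DataFrame:
    """One authentic sample per panel species, plus blank injections.

    In a species' own sample every quantifier/qualifier marker of that
    species gets its true mean area under multiplicative noise; markers of
    every other species get zero area (no cross-detection). Blanks carry
    zero area for all markers.
    """
    species = sorted({c.species_tag for c in panel})
    rng = np.random.default_rng(seed)
    records = []
    for sp in species:
        for cand in panel:
            present = cand.species_tag == sp and cand.role in ("quantifier", "qualifier")
            mean = (true_mean_area or {}).get(cand.sequence, 1_000_000.0)
            area = mean * _lognormal_factors(rng, cv, None) if present else 0.0
            records.append(
                PeakAreaRecord(
                    sample_id=f"authentic_{sp}",
                    species_label=sp,
                    peptide=cand.sequence,
                    replicate=1,
                    day=1,
                    raw_area=float(area) * flour_mg,
                    flour_mg=flour_mg,
                )
            )
    for b in range(n_blanks):
        for cand in panel:
            records.append(
                PeakAreaRecord(
                    sample_id=f"blank_{b + 1}",
                    species_label="blank",
                    peptide=cand.sequence,
                    replicate=1,
                    day=1,
                    raw_area=0.0,
                    flour_mg=flour_mg,
                    record_class="blank",
                )
            )
    return records_to_frame(records)
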