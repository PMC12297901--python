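"""MRM transition-list construction.

For each marker peptide an initial set of 8–10 candidate transitions is
generated from the singly charged b/y fragment ions falling in the
monitored m/z window (200–1200 by default), then the four most intense
transitions are retained once measured intensities are available. Without
intensity data, a documented preference order stands in: y-ions before
b-ions, longer fragments first — the y series dominates low-energy CID
spectra of tryptic peptides on triple-quadrupole instruments.

Collision energy is a passthrough field (vendor tools optimize it
empirically); an optional linear-in-m/z ramp can prefill it.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .mass_spec_math import (
    DEFAULT_FIXED_MODS,
    FixedModification,
    FragmentIon,
    fragment_ions,
    precursor_mz,
    round_mz,
)

__all__ = [
    "TransitionParams",
    "Transition",
    "transition_distribution_score",
    "candidate_transitions",
    "select_top_transitions",
    "assign_collision_energies",
    "export_transition_list",
    "read_transition_list",
]


@dataclass(frozen=True)
class TransitionParams:
    """Transition-generation parameters.

    ``n_initial`` is the target range for the initial candidate set size;
    ``n_final`` the number retained after intensity-based selection.
    """

    precursor_charge: int = 2
    product_charge: int = 1
    mz_min: float = 200.0
    mz_max: float = 1200.0
    n_initial: tuple[int, int] = (8, 10)
    n_final: int = 4
    series: tuple[str, ...] = ("b", "y")

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        lo, hi = self.n_initial
        if not (1 <= lo <= hi):
            raise ValueError("n_initial must be an increasing range of positive ints")
        if not (1 <= self.n_final <= lo):
            raise ValueError("n_final must be between 1 and the lower n_initial bound")


@dataclass(frozen=True)
class Transition:
    """One monitored precursor → product ion pair."""

    peptide: str
    precursor_mz: float
    precursor_charge: int
    product: FragmentIon
    collision_energy: float | None = None
    rank: int | None = None
    role: str = "unassigned"
    accession: str = ""
    species: str = ""


def _preference_key(t: Transition) -> tuple:
    # y before b, then longer fragments (descending ordinal), then m/z desc
    return (0 if t.product.series == "y" else 1, -t.product.ordinal, -t.product.mz)


def transition_distribution_score(intensities: Sequence[float]) -> float:
    """Evenness of intensity distribution across a peptide's transitions.

    Normalized Shannon entropy of the intensity shares, in [0, 1]: 1 when
    every monitored transition contributes equally, approaching 0 when a
    single transition carries all the signal. Returns 0 for fewer than two
    positive intensities.
    """
    pos = [x for x in intensities if x > 0]
    if len(pos) < 2:
        return 0.0
    total = sum(pos)
    shares = [x / total for x in pos]
    entropy = -sum(p * math.log(p) for p in shares)
    return entropy / math.log(len(pos))


def candidate_transitions(
    peptide: str,
    params: TransitionParams = TransitionParams(),
    mods: Iterable[FixedModification] | None = None,
    accession: str = "",
    species: str = "",
    role: str = "unassigned",
) -> list[Transition]:
    """Generate the initial candidate transition set for one peptide.

    All singly charged b/y ions (per ``params.series`` / product charge)
    are computed and filtered to the monitored m/z window. If more than
    the upper initial bound survive, the list is truncated by the default
    preference order (y over b, descending ordinal); if fewer than the
    lower bound survive, all are returned and a ``UserWarning`` is issued.
    """
    mods = tuple(DEFAULT_FIXED_MODS if mods is None else mods)
    prec = precursor_mz(peptide, params.precursor_charge, mods)
    ions = fragment_ions(peptide, params.series, params.product_charge, mods)
    kept = [ion for ion in ions if params.mz_min <= ion.mz <= params.mz_max]
    transitions = [
        Transition(
            peptide=peptide,
            precursor_mz=prec,
            precursor_charge=params.precursor_charge,
            product=ion,
            accession=accession,
            species=species,
            role=role,
        )
        for ion in kept
    ]
    transitions.sort(key=_preference_key)
    lo, hi = params.n_initial
    if len(transitions) > hi:
        transitions = transitions[:hi]
    elif len(transitions) < lo:
        warnings.warn(
            f"peptide {peptide!r}: only {len(transitions)} candidate transitions "
            f"in window [{params.mz_min}, {params.mz_max}] (target {lo}-{hi})",
            UserWarning,
            stacklevel=2,
        )
    return transitions


def select_top_transitions(
    candidates: Sequence[Transition],
    intensities: Mapping[str, float] | None = None,
    n_final: int = 4,
) -> list[Transition]:
    """Retain the ``n_final`` most intense transitions of one peptide.

    ``intensities`` maps fragment labels (e.g. ``"y7"``) to measured
    intensities; transitions without a measurement count as zero. Without
    intensity data the default preference order decides. Ties break by
    preference order, then descending m/z. Ranks 1..n are assigned;
    selection is idempotent.
    """
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    candidates = list(candidates)
    if not candidates:
        return []
    peptides = {t.peptide for t in candidates}
    if len(peptides) > 1:
        raise ValueError(f"candidates must come from one peptide, got {sorted(peptides)}")
    if intensities is not None:
        key = lambda t: (-intensities.get(t.product.label, 0.0),) + _preference_key(t)
    else:
        key = _preference_key
    ordered = sorted(candidates, key=key)
    if len(ordered) < n_final:
        warnings.warn(
            f"peptide {candidates[0].peptide!r}: only {len(ordered)} transitions "
            f"available for a top-{n_final} selection",
            UserWarning,
            stacklevel=2,
        )
    return [replace(t, rank=i) for i, t in enumerate(ordered[:n_final], start=1)]


def assign_collision_energies(
    transitions: Iterable[Transition], slope: float = 0.036, intercept: float = -4.8
) -> list[Transition]:
    """Prefill collision energies with a linear-in-precursor-m/z ramp (V).

    Default coefficients follow the common QQQ vendor formula for doubly
    charged precursors; instruments typically re-optimize empirically.
    """
    return [
        replace(t, collision_energy=round(slope * t.precursor_mz + intercept, 1))
        for t in transitions
    ]


_COLUMNS = [
    "protein_accession",
    "species",
    "peptide",
    "precursor_mz",
    "precursor_charge",
    "product_mz",
    "product_charge",
    "fragment",
    "collision_energy",
    "role",
    "rank",
]


def export_transition_list(transitions: Sequence[Transition], path: str | Path) -> None:
    """Write a vendor-neutral transition-list CSV.

    One row per transition with m/z values at 4 decimals, a header row,
    and stable row order (as given).
    """
    transitions = list(transitions)
    if not transitions:
        raise ValueError("cannot export an empty transition list")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for t in transitions:
            writer.writerow(
                [
                    t.accession,
                    t.species,
                    t.peptide,
                    f"{round_mz(t.precursor_mz):.4f}",
                    t.precursor_charge,
                    f"{round_mz(t.product.mz):.4f}",
                    t.product.charge,
                    t.product.label,
                    "" if t.collision_energy is None else t.collision_energy,
                    t.role,
                    "" if t.rank is None else t.rank,
                ]
            )


def read_transition_list(path: str | Path) -> list[dict[str, str]]:
    """Read an exported transition list back as rows of strings."""
    with Path(path).open(newline="") as fh:
        return list(csv.DictReader(fh))
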