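"""Monoisotopic peptide mass and b/y fragment-ion m/z arithmetic.

All masses are monoisotopic and in daltons. A peptide's neutral
(uncharged) mass is the sum of its residue masses plus one water; an
``n``-fold protonated species has m/z ``(M + n * proton) / n``. The b/y
backbone fragment series follow the usual CID conventions for tryptic
peptides: ``b_i`` carries the N-terminal ``i`` residues (no water),
``y_i`` the C-terminal ``i`` residues plus water.

Fixed modifications are applied as per-residue mass deltas; the default
modification set carries carbamidomethylation of cysteine (+57.021464 Da,
the iodoacetamide adduct), the standard fixed modification of bottom-up
proteomics sample preparation.

Residue masses are carried at 6-decimal precision; rounding to the 4
decimals conventionally printed on transition lists happens only at the
reporting boundary (:func:`round_mz`), never inside the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "WATER_MONO",
    "PROTON_MASS",
    "RESIDUE_MONO_MASSES",
    "CARBAMIDOMETHYL",
    "DEFAULT_FIXED_MODS",
    "FixedModification",
    "FragmentIon",
    "round_mz",
    "residue_masses",
    "peptide_neutral_mass",
    "precursor_mz",
    "fragment_ions",
]

#: Monoisotopic mass of H2O (Da), added once per intact peptide / y ion.
WATER_MONO: float = 18.010565

#: Monoisotopic mass of a proton (Da) — the charge carrier in positive ESI.
PROTON_MASS: float = 1.007276

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MONO_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}


@dataclass(frozen=True)
class FixedModification:
    """A fixed (always-applied) modification on one residue letter."""

    name: str
    target: str  # single residue letter
    delta: float  # Da

    def __post_init__(self) -> None:
        if self.target not in RESIDUE_MONO_MASSES:
            raise ValueError(
                f"modification {self.name!r} targets unknown residue {self.target!r}"
            )
        if self.delta == 0.0:
            raise ValueError(f"modification {self.name!r} has zero mass delta")


#: Carbamidomethylation of cysteine (iodoacetamide alkylation).
CARBAMIDOMETHYL = FixedModification("carbamidomethyl", "C", 57.021464)

#: Default fixed-modification set.
DEFAULT_FIXED_MODS: tuple[FixedModification, ...] = (CARBAMIDOMETHYL,)


@dataclass(frozen=True)
class FragmentIon:
    """One b- or y-series backbone fragment ion."""

    series: str  # "b" or "y"
    ordinal: int  # 1 .. len(peptide) - 1
    charge: int
    mz: float  # full precision; round_mz() for display

    @property
    def label(self) -> str:
        """Conventional fragment label, e.g. ``y7`` or ``b3++``."""
        return f"{self.series}{self.ordinal}" + "+" * (self.charge - 1)


def round_mz(mz: float) -> float:
    """Round an m/z value to the 4 decimals printed on transition lists."""
    return round(mz, 4)


def _mod_deltas(mods: Iterable[FixedModification] | None) -> Mapping[str, float]:
    deltas: dict[str, float] = {}
    for mod in DEFAULT_FIXED_MODS if mods is None else mods:
        deltas[mod.target] = deltas.get(mod.target, 0.0) + mod.delta
    return deltas


def residue_masses(
    sequence: str, mods: Iterable[FixedModification] | None = None
) -> list[float]:
    """Per-residue masses of ``sequence`` with fixed modifications applied.

    Raises
    ------
    ValueError
        If ``sequence`` is empty or contains a letter without a defined
        monoisotopic mass (ambiguity letters B/J/Z/X and the rare U/O are
        deliberately undefined here).
    """
    if not sequence:
        raise ValueError("empty peptide sequence has no mass")
    deltas = _mod_deltas(mods)
    masses: list[float] = []
    for pos, letter in enumerate(sequence, start=1):
        try:
            base = RESIDUE_MONO_MASSES[letter]
        except KeyError:
            raise ValueError(
                f"residue {letter!r} at position {pos} has no defined monoisotopic mass"
            ) from None
        masses.append(base + deltas.get(letter, 0.0))
    return masses


def peptide_neutral_mass(
    sequence: str, mods: Iterable[FixedModification] | None = None
) -> float:
    """Monoisotopic neutral mass (Da): sum of modified residues + water."""
    return sum(residue_masses(sequence, mods)) + WATER_MONO


def precursor_mz(
    sequence: str, charge: int, mods: Iterable[FixedModification] | None = None
) -> float:
    """m/z of the ``charge``-fold protonated peptide: (M + z·H⁺) / z."""
    if charge < 1:
        raise ValueError(f"precursor charge must be >= 1, got {charge}")
    return (peptide_neutral_mass(sequence, mods) + charge * PROTON_MASS) / charge


def fragment_ions(
    sequence: str,
    series: Sequence[str] = ("b", "y"),
    charge: int = 1,
    mods: Iterable[FixedModification] | None = None,
) -> list[FragmentIon]:
    """All b/y fragment ions of ``sequence`` at the given charge.

    For a peptide of length n, ordinals 1..n-1 are returned per series:
    ``b_i = (Σ first i residues + z·H⁺)/z`` and
    ``y_i = (Σ last i residues + H₂O + z·H⁺)/z``.

    Parameters
    ----------
    series:
        Subset of {"b", "y"} to generate.
    charge:
        Product-ion charge (singly charged ions are the QQQ standard).
    """
    if len(sequence) < 2:
        raise ValueError("fragment ions require a peptide of length >= 2")
    if charge < 1:
        raise ValueError(f"fragment charge must be >= 1, got {charge}")
    bad = set(series) - {"b", "y"}
    if bad:
        raise ValueError(f"unsupported ion series: {sorted(bad)}")

    masses = residue_masses(sequence, mods)
    n = len(masses)
    ions: list[FragmentIon] = []
    if "b" in series:
        running = 0.0
        for i in range(1, n):
            running += masses[i - 1]
            ions.append(
                FragmentIon("b", i, charge, (running + charge * PROTON_MASS) / charge)
            )
    if "y" in series:
        running = WATER_MONO
        for i in range(1, n):
            running += masses[n - i]
            ions.append(
                FragmentIon("y", i, charge, (running + charge * PROTON_MASS) / charge)
            )
    return ions
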