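"""Monoisotopic peptide and fragment-ion mass arithmetic.

All calculations are monoisotopic: a 2 ppm accuracy claim on a ~2 kDa
precursor is only meaningful against the monoisotopic peak, never the
average mass.  Neutral peptide mass is the sum of residue masses plus one
water (the termini), plus any modification deltas; an [M+zH]z+ ion adds z
proton masses and divides by z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASSES",
    "WATER_MONO",
    "PROTON_MASS",
    "Modification",
    "ModificationRegistry",
    "DEFAULT_MODIFICATIONS",
    "Peptide",
    "monoisotopic_mass",
    "precursor_mz",
    "ppm_error",
    "fragment_series",
]

#: Monoisotopic residue (amino-acid minus water) masses in Da, standard
#: elemental compositions of the 20 proteinogenic residues.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Monoisotopic mass of H2O (Da) — the peptide termini.
WATER_MONO: float = 18.0105646863
#: Mass of a proton (Da) — charge carrier for positive-mode m/z.
PROTON_MASS: float = 1.00727646688


@dataclass(frozen=True)
class Modification:
    """A covalent modification with a fixed monoisotopic mass shift.

    Static modifications apply to every occurrence of a target residue;
    variable modifications apply only where declared on a peptide.
    """

    name: str
    target_residues: frozenset[str]
    delta_mass: float
    mode: Literal["static", "variable"]

    def __post_init__(self) -> None:
        if self.mode not in ("static", "variable"):
            raise ValueError(f"mode must be 'static' or 'variable', got {self.mode!r}")
        if not self.target_residues:
            raise ValueError("modification needs at least one target residue")
        import math

        if not math.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")


class ModificationRegistry:
    """Named lookup of :class:`Modification` definitions."""

    def __init__(self, mods: Iterable[Modification] = ()) -> None:
        self._mods: dict[str, Modification] = {}
        for m in mods:
            self.add(m)

    def add(self, mod: Modification) -> None:
        if mod.name in self._mods:
            raise ValueError(f"duplicate modification name {mod.name!r}")
        self._mods[mod.name] = mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise KeyError(f"unknown modification {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def __iter__(self):
        return iter(self._mods.values())

    @property
    def static_mods(self) -> list[Modification]:
        return [m for m in self._mods.values() if m.mode == "static"]


def default_registry() -> ModificationRegistry:
    """Search-configuration modification set for in-gel tryptic digests.

    Propionamide on Cys (acrylamide adduct from gel electrophoresis) is
    static; Met oxidation, Lys acetylation, Ser/Thr/Tyr phosphorylation and
    Lys GG (the ubiquitination remnant) are variable.  Deltas are standard
    elemental-composition sums.
    """
    return ModificationRegistry(
        [
            Modification("propionamide", frozenset("C"), 71.03711, "static"),
            Modification("oxidation", frozenset("M"), 15.99491, "variable"),
            Modification("acetyl", frozenset("K"), 42.01057, "variable"),
            Modification("phospho", frozenset("STY"), 79.96633, "variable"),
            Modification("gg", frozenset("K"), 114.04293, "variable"),
        ]
    )


DEFAULT_MODIFICATIONS = default_registry()


@dataclass(frozen=True)
class Peptide:
    """A residue string with positioned variable modifications and a charge.

    ``mods`` holds ``(position, modification_name)`` pairs with 1-based
    positions on the sequence.  Terminal modifications are not modelled.
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        for pos, name in self.mods:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _residue_mass(residue: str, table: Mapping[str, float]) -> float:
    try:
        return table[residue]
    except KeyError:
        raise ValueError(f"unknown residue code {residue!r}") from None


def _per_position_masses(
    peptide: Peptide,
    table: Mapping[str, float],
    registry: ModificationRegistry,
) -> list[float]:
    """Residue mass at each position, with static and declared variable mods."""
    masses = [_residue_mass(r, table) for r in peptide.sequence]
    for mod in registry.static_mods:
        for i, r in enumerate(peptide.sequence):
            if r in mod.target_residues:
                masses[i] += mod.delta_mass
    for pos, name in peptide.mods:
        mod = registry[name]
        residue = peptide.sequence[pos - 1]
        if residue not in mod.target_residues:
            raise ValueError(
                f"modification {name!r} does not target residue {residue!r} "
                f"at position {pos}"
            )
        if mod.mode == "variable":
            masses[pos - 1] += mod.delta_mass
        # static mods are already applied to every target occurrence
    return masses


def monoisotopic_mass(
    peptide: Peptide,
    table: Mapping[str, float] | None = None,
    registry: ModificationRegistry | None = None,
) -> float:
    """Neutral monoisotopic mass of a (modified) peptide in Da."""
    table = MONOISOTOPIC_RESIDUE_MASSES if table is None else table
    registry = DEFAULT_MODIFICATIONS if registry is None else registry
    return sum(_per_position_masses(peptide, table, registry)) + WATER_MONO


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """[M+zH]z+ mass-to-charge for a neutral mass M and charge z >= 1."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def ppm_error(experimental_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (experimental_mz - theoretical_mz) / theoretical_mz * 1e6


def fragment_series(
    peptide: Peptide,
    series: Literal["b", "y"],
    frag_charge: int = 1,
    table: Mapping[str, float] | None = None,
    registry: ModificationRegistry | None = None,
) -> list[float]:
    """m/z ladder of backbone fragment ions (full-length ion excluded).

    b ions are the N-terminal pieces (residue sum plus charging protons);
    y ions are the C-terminal pieces and retain the water of the C terminus.
    Returns n-1 values ordered by fragment index.
    """
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if frag_charge < 1:
        raise ValueError(f"fragment charge must be >= 1, got {frag_charge}")
    table = MONOISOTOPIC_RESIDUE_MASSES if table is None else table
    registry = DEFAULT_MODIFICATIONS if registry is None else registry
    masses = _per_position_masses(peptide, table, registry)
    n = len(masses)
    out: list[float] = []
    if series == "b":
        acc = 0.0
        for i in range(n - 1):
            acc += masses[i]
            out.append((acc + frag_charge * PROTON_MASS) / frag_charge)
    else:
        acc = WATER_MONO
        for j in range(1, n):
            acc += masses[n - j]
            out.append((acc + frag_charge * PROTON_MASS) / frag_charge)
    return out
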