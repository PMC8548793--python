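"""Deterministic collagen peptide chemistry.

Monoisotopic mass arithmetic for tryptic collagen peptides, including the
post-translational modifications that dominate collagen mass fingerprints:
hydroxylation of proline/lysine (+15.99491 Da per site, hydroxyproline being
near-ubiquitous in the Gly-X-Y repeat) and deamidation of asparagine/glutamine
(+0.98402 Da, common in degraded archaeological collagen).

Modifications are modelled as *counts* with site-capacity checks, not as
positioned assignments: positional isomers are mass-identical and MALDI-TOF
fingerprints cannot localize them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from Bio import SeqIO

__all__ = [
    "WATER",
    "PROTON",
    "HYDROXYLATION",
    "DEAMIDATION",
    "RESIDUE_MASSES",
    "ResidueMassTable",
    "ModificationSpec",
    "PeptideVariant",
    "monoisotopic_mhplus",
    "infer_hydroxylations",
    "digest",
    "extract_locus_peptide",
    "read_chains",
]

#: Monoisotopic mass of H2O in Da.
WATER = 18.010565
#: Monoisotopic mass of a proton in Da ([M+H]+ charge carrier).
PROTON = 1.007276
#: Mass shift of one hydroxylation (oxidation) in Da.
HYDROXYLATION = 15.99491
#: Mass shift of one deamidation in Da.
DEAMIDATION = 0.98402

# Standard monoisotopic residue masses (Da), 20 canonical amino acids.
_RESIDUE_MASSES = {
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

RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(_RESIDUE_MASSES)

#: Residues that can carry a hydroxylation. Methionine oxidation carries the
#: same mass shift and may be enabled by passing ``allow_met_oxidation=True``
#: where supported; no bundled marker requires it.
HYDROXYLATION_SITES = frozenset("PK")
DEAMIDATION_SITES = frozenset("NQ")


@dataclass(frozen=True)
class ResidueMassTable:
    """Immutable residue mass table plus the water/proton constants."""

    residues: Mapping[str, float] = field(default_factory=lambda: RESIDUE_MASSES)
    water: float = WATER
    proton: float = PROTON

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residues.values()) or self.water <= 0 or self.proton <= 0:
            raise ValueError("all masses must be strictly positive")

    def mass(self, residue: str) -> float:
        return self.residues[residue]


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, aa in enumerate(sequence):
        if aa not in _RESIDUE_MASSES:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1} in {sequence!r}"
            )


def _hydroxylation_capacity(sequence: str, allow_met_oxidation: bool = False) -> int:
    sites = HYDROXYLATION_SITES | ({"M"} if allow_met_oxidation else set())
    return sum(1 for aa in sequence if aa in sites)


def _deamidation_capacity(sequence: str) -> int:
    return sum(1 for aa in sequence if aa in DEAMIDATION_SITES)


@dataclass(frozen=True)
class ModificationSpec:
    """Counts of mass-shifting modifications carried by a peptide.

    ``hydroxylations`` may sit on P or K (optionally M); ``deamidations`` on
    N or Q. Only counts are tracked, never positions.
    """

    hydroxylations: int = 0
    deamidations: int = 0

    def __post_init__(self) -> None:
        if self.hydroxylations < 0 or self.deamidations < 0:
            raise ValueError("modification counts must be non-negative")

    def validate_against(self, sequence: str, allow_met_oxidation: bool = False) -> None:
        cap_k = _hydroxylation_capacity(sequence, allow_met_oxidation)
        if self.hydroxylations > cap_k:
            raise ValueError(
                f"{self.hydroxylations} hydroxylations exceed the {cap_k} "
                f"available P/K sites of {sequence!r}"
            )
        cap_d = _deamidation_capacity(sequence)
        if self.deamidations > cap_d:
            raise ValueError(
                f"{self.deamidations} deamidations exceed the {cap_d} "
                f"available N/Q sites of {sequence!r}"
            )

    @property
    def mass_shift(self) -> float:
        return HYDROXYLATION * self.hydroxylations + DEAMIDATION * self.deamidations


@dataclass(frozen=True)
class PeptideVariant:
    """A peptide sequence with a modification state and its computed masses."""

    sequence: str
    modifications: ModificationSpec = field(default_factory=ModificationSpec)

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        self.modifications.validate_against(self.sequence)

    @property
    def neutral_mass(self) -> float:
        return (
            sum(_RESIDUE_MASSES[aa] for aa in self.sequence)
            + WATER
            + self.modifications.mass_shift
        )

    @property
    def mhplus(self) -> float:
        return self.neutral_mass + PROTON


def monoisotopic_mhplus(
    sequence: str,
    hydroxylations: int = 0,
    deamidations: int = 0,
    *,
    allow_met_oxidation: bool = False,
) -> float:
    """Singly protonated monoisotopic mass ([M+H]+, Da) of a modified peptide."""
    _check_sequence(sequence)
    spec = ModificationSpec(hydroxylations, deamidations)
    spec.validate_against(sequence, allow_met_oxidation)
    return (
        sum(_RESIDUE_MASSES[aa] for aa in sequence)
        + WATER
        + PROTON
        + spec.mass_shift
    )


def infer_hydroxylations(
    sequence: str, nominal: float, tolerance: float = 1.0
) -> int | None:
    """Smallest hydroxylation count whose [M+H]+ matches a nominal marker mass.

    ZooMS tables print integer marker masses and peptide sequences but not the
    hydroxylation count linking them; this recovers it by exhaustive search
    over ``k = 0..(#P + #K)``. Returns ``None`` when no count lands within
    ``tolerance`` (default 1.0 Da, wide enough for the mixed
    truncation/rounding of integer mass labels).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    _check_sequence(sequence)
    for k in range(_hydroxylation_capacity(sequence) + 1):
        if abs(monoisotopic_mhplus(sequence, k) - nominal) <= tolerance:
            return k
    return None


def digest(
    sequence: str,
    missed_cleavages: int = 0,
    *,
    no_cut_before_proline: bool = True,
) -> list[tuple[str, int]]:
    """Tryptic digest: peptides with their 1-based start positions.

    Cuts after every K or R; with ``no_cut_before_proline`` (the default,
    matching trypsin's behaviour and the monotreme missed-cleavage case) a
    K/R followed by P is not cut. Peptides spanning up to ``missed_cleavages``
    internal cut sites are included, ordered by start position then length.
    """
    _check_sequence(sequence)
    if not 0 <= missed_cleavages <= 3:
        raise ValueError("missed_cleavages must be between 0 and 3")
    # Fully cleaved fragments as (start, end) 0-based half-open spans.
    fragments: list[tuple[int, int]] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR":
            if no_cut_before_proline and i + 1 < len(sequence) and sequence[i + 1] == "P":
                continue
            fragments.append((start, i + 1))
            start = i + 1
    if start < len(sequence):
        fragments.append((start, len(sequence)))
    out: list[tuple[str, int]] = []
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            lo, hi = fragments[i][0], fragments[j][1]
            out.append((sequence[lo:hi], lo + 1))
    out.sort(key=lambda p: (p[1], len(p[0])))
    return out


def extract_locus_peptide(
    chain: str, start: int, end: int, *, no_cut_before_proline: bool = True
) -> tuple[str, bool]:
    """Extract a 1-based inclusive span and say whether it is a tryptic product.

    A valid tryptic product starts at the chain start or right after a cut
    site, and ends at the chain end or at a cut site (K/R not followed by P).
    """
    _check_sequence(chain)
    if not (1 <= start <= end <= len(chain)):
        raise ValueError(
            f"span {start}-{end} out of range for chain of length {len(chain)}"
        )
    peptide = chain[start - 1 : end]

    def is_cut_site(i: int) -> bool:  # cut after 1-based position i?
        if chain[i - 1] not in "KR":
            return False
        if no_cut_before_proline and i < len(chain) and chain[i] == "P":
            return False
        return True

    starts_ok = start == 1 or is_cut_site(start - 1)
    ends_ok = end == len(chain) or is_cut_site(end)
    return peptide, starts_ok and ends_ok


def read_chains(path) -> dict[str, str]:
    """Read protein chains from FASTA; keys are the first word of each header."""
    chains: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        _check_sequence(seq)
        chains[record.id] = seq
    return chains
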