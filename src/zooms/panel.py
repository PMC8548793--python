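"""The taxon × marker-locus reference panel.

The bundled panel covers 24 Australian marsupial and monotreme taxa at 11
collagen type I marker loci (the classic letter-named markers P1, A, B, C,
P2, D, E, F, G plus COL1A2 10–42, also known by its tryptic name 2T3, and
COL1A2 889–906). Three loci (A, F, G) are conventionally reported as an
oxidation pair: a base mass and a +16 partner carrying one extra
hydroxylation of the same peptide.

Cell semantics carried from the source tables:

* ``maldi_visible`` — the marker is seen in MALDI-TOF fingerprints;
* ``msms_only`` — confirmed in LC-MS/MS data but not visible in MALDI
  spectra (such alleles may support an identification but are never emitted
  by the simulator);
* ``unreported`` — no allele recorded; treated as a wildcard that never
  discriminates (absence of evidence, not evidence of absence);
* ``diagnostic`` — bold in the source, kept as metadata only.

Marker masses are integer nominal labels; where the peptide sequence is
known the exact monoisotopic [M+H]+ is recomputed with the inferred
hydroxylation count and used for matching and simulation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .chem import HYDROXYLATION, infer_hydroxylations, monoisotopic_mhplus

__all__ = [
    "VISIBILITIES",
    "MarkerLocus",
    "AlleleMember",
    "LocusAlleles",
    "TaxonProfile",
    "Panel",
    "ValidationReport",
    "load_panel",
    "save_panel",
    "bundled_panel",
    "validate_panel",
    "equivalence_classes",
]

VISIBILITIES = ("maldi_visible", "msms_only", "unreported")

REQUIRED_COLUMNS = [
    "taxon",
    "lineage",
    "chain",
    "span",
    "marker_name",
    "nominal_mz",
    "sequence",
    "visibility",
    "diagnostic",
    "pair_partner_mz",
]

#: Agreement window between a nominal integer label and the computed
#: monoisotopic mass (the labels mix truncation and rounding).
NOMINAL_TOLERANCE = 1.0
#: Expected base/+16 partner offset and its allowed slack, Da.
PAIR_OFFSET = 15.99
PAIR_SLACK = 0.02


@dataclass(frozen=True)
class MarkerLocus:
    """One marker locus: a tryptic span on a collagen chain."""

    name: str
    chain: str
    span: tuple[int, int]
    paired: bool = False

    def __post_init__(self) -> None:
        if self.span[0] > self.span[1]:
            raise ValueError(f"locus {self.name}: span start exceeds end")


@dataclass(frozen=True)
class AlleleMember:
    """One reported mass of a taxon at a locus (base or +16 partner)."""

    nominal: int
    role: str  # "base" | "prime"
    visibility: str
    diagnostic: bool = False
    sequence: str | None = None
    hydroxylations: int | None = None
    mono_mz: float | None = None
    sequence_consistent: bool = True

    @property
    def mass(self) -> float:
        """Best available mass: monoisotopic when the sequence is known."""
        return self.mono_mz if self.mono_mz is not None else float(self.nominal)


@dataclass(frozen=True)
class LocusAlleles:
    """A taxon's allele set at one locus."""

    locus: str
    base: AlleleMember | None = None
    prime: AlleleMember | None = None
    alt_masses: tuple[float, ...] = ()
    alt_nominals: tuple[int, ...] = ()

    @property
    def members(self) -> tuple[AlleleMember, ...]:
        return tuple(m for m in (self.base, self.prime) if m is not None)

    @property
    def reported(self) -> bool:
        return bool(self.members)

    def mass_set(self) -> tuple[float, ...]:
        """All masses this taxon can legitimately show at the locus."""
        return tuple(m.mass for m in self.members) + self.alt_masses

    def visible_members(self, include_msms: bool = False) -> tuple[AlleleMember, ...]:
        allowed = {"maldi_visible"} | ({"msms_only"} if include_msms else set())
        return tuple(m for m in self.members if m.visibility in allowed)


@dataclass(frozen=True)
class TaxonProfile:
    species: str
    genus: str
    family: str
    order: str
    alleles: dict[str, LocusAlleles] = field(default_factory=dict)

    @property
    def lineage(self) -> tuple[str, str, str, str]:
        return (self.species, self.genus, self.family, self.order)


@dataclass
class Panel:
    loci: dict[str, MarkerLocus]
    profiles: dict[str, TaxonProfile]
    table: pd.DataFrame  # normalized row table, preserves unknown columns

    @property
    def taxa(self) -> list[str]:
        return list(self.profiles)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self.loci == other.loci and self.profiles == other.profiles

    def collisions(self) -> dict[int, list[tuple[str, str]]]:
        """Nominal masses attached to more than one (locus, role).

        A mass that labels different peptides — at two different loci, or as
        the base allele of one taxon and the +16 partner (or an alternate
        oxidation state) of another — cannot be read off a spectrum alone.
        """
        seen: dict[int, set[tuple[str, str]]] = {}
        for profile in self.profiles.values():
            for la in profile.alleles.values():
                for member in la.members:
                    seen.setdefault(member.nominal, set()).add((la.locus, member.role))
                for nom in la.alt_nominals:
                    seen.setdefault(nom, set()).add((la.locus, "alt"))
        return {
            nominal: sorted(roles)
            for nominal, roles in sorted(seen.items())
            if len(roles) > 1
        }

    def cross_locus_collision_nominals(self) -> set[int]:
        return {
            nominal
            for nominal, roles in self.collisions().items()
            if len({locus for locus, _ in roles}) > 1
        }


def _parse_span(text: str, lineno: int | None = None) -> tuple[int, int]:
    where = f" (line {lineno})" if lineno is not None else ""
    try:
        start, end = text.split("-")
        return int(start), int(end)
    except ValueError:
        raise ValueError(f"malformed span {text!r}{where}") from None


def _build_member(row, role: str) -> AlleleMember:
    nominal = int(row["nominal_mz"])
    sequence = row["sequence"] or None
    k = None
    mono = None
    consistent = True
    if sequence:
        k = infer_hydroxylations(sequence, nominal, NOMINAL_TOLERANCE)
        if k is None:
            # keep the nearest ladder rung; validate_panel reports the miss
            capacity = sum(1 for aa in sequence if aa in "PK")
            k = min(
                range(capacity + 1),
                key=lambda kk: abs(monoisotopic_mhplus(sequence, kk) - nominal),
            )
            consistent = False
        mono = monoisotopic_mhplus(sequence, k)
    return AlleleMember(
        nominal=nominal,
        role=role,
        visibility=row["visibility"],
        diagnostic=str(row["diagnostic"]) in ("1", "True", "true"),
        sequence=sequence,
        hydroxylations=k,
        mono_mz=mono,
        sequence_consistent=consistent,
    )


def load_panel(path) -> Panel:
    """Load a panel from its TSV representation."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty:
        raise ValueError(f"panel file {path} contains no rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} is missing required columns: {missing}")
    return _panel_from_table(df)


def _panel_from_table(df: pd.DataFrame) -> Panel:
    loci: dict[str, MarkerLocus] = {}
    paired_names = {
        name.rstrip("'") for name in df["marker_name"] if name.endswith("'")
    }
    staged: dict[str, dict[str, dict]] = {}
    lineages: dict[str, tuple[str, str, str]] = {}

    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        marker = row["marker_name"]
        if not marker:
            raise ValueError(f"empty marker_name (line {lineno})")
        locus_name = marker.rstrip("'")
        role = "prime" if marker.endswith("'") else "base"
        span = _parse_span(row["span"], lineno)
        locus = MarkerLocus(locus_name, row["chain"], span, locus_name in paired_names)
        if locus_name in loci and loci[locus_name] != locus:
            raise ValueError(
                f"conflicting definitions for locus {locus_name} (line {lineno})"
            )
        loci.setdefault(locus_name, locus)

        taxon = row["taxon"]
        parts = row["lineage"].split(";")
        if len(parts) != 3:
            raise ValueError(
                f"lineage must be 'genus;family;order' (line {lineno}): {row['lineage']!r}"
            )
        lineages.setdefault(taxon, tuple(parts))

        visibility = row["visibility"]
        if visibility not in VISIBILITIES:
            raise ValueError(f"unknown visibility {visibility!r} (line {lineno})")
        if visibility == "unreported":
            if row["nominal_mz"]:
                raise ValueError(
                    f"unreported allele must not carry a mass (line {lineno})"
                )
            staged.setdefault(taxon, {}).setdefault(locus_name, {})
            continue
        if not row["nominal_mz"]:
            raise ValueError(f"reported allele lacks nominal_mz (line {lineno})")

        member = _build_member(row, role)
        slot = staged.setdefault(taxon, {}).setdefault(locus_name, {})
        if role in slot:
            raise ValueError(
                f"duplicate {role} allele for {taxon} at {locus_name} (line {lineno})"
            )
        slot[role] = member
        alt = row.get("alt_mz", "")
        if alt:
            slot.setdefault("alt", []).append(int(alt))

    profiles: dict[str, TaxonProfile] = {}
    for taxon, locus_map in staged.items():
        genus, family, order = lineages[taxon]
        alleles: dict[str, LocusAlleles] = {}
        for locus_name, slot in locus_map.items():
            base = slot.get("base")
            prime = slot.get("prime")
            alt_nominals = tuple(slot.get("alt", []))
            alt_masses = []
            for nom in alt_nominals:
                anchor = base or prime
                # alternates differ from the anchor by whole oxidation steps
                steps = round((nom - anchor.nominal) / 16)
                alt_masses.append(anchor.mass + steps * HYDROXYLATION)
            alleles[locus_name] = LocusAlleles(
                locus=locus_name,
                base=base,
                prime=prime,
                alt_masses=tuple(alt_masses),
                alt_nominals=alt_nominals,
            )
        profiles[taxon] = TaxonProfile(taxon, genus, family, order, alleles)

    return Panel(loci=loci, profiles=profiles, table=df.copy())


def save_panel(panel: Panel, path) -> None:
    """Write the panel back to TSV (round-trip stable, unknown columns kept)."""
    panel.table.to_csv(path, sep="\t", index=False)


def bundled_panel() -> Panel:
    """The built-in 24-taxon marsupial/monotreme reference panel."""
    ref = importlib.resources.files("zooms.data").joinpath("panel.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_panel(path)


@dataclass
class ValidationReport:
    """Report-only outcome of panel self-checks."""

    allele_checks: pd.DataFrame
    pair_violations: list[str]
    collisions: dict[int, list[tuple[str, str]]]

    @property
    def inconsistent_alleles(self) -> pd.DataFrame:
        return self.allele_checks[~self.allele_checks["consistent"]]

    @property
    def n_inconsistent(self) -> int:
        return int((~self.allele_checks["consistent"]).sum())

    def summary(self) -> str:
        lines = [
            f"alleles with sequences checked: {len(self.allele_checks)}",
            f"sequence/mass inconsistencies:  {self.n_inconsistent}",
            f"pair-offset violations:         {len(self.pair_violations)}",
            f"ambiguous (colliding) masses:   {sorted(self.collisions)}",
        ]
        for _, row in self.inconsistent_alleles.iterrows():
            lines.append(
                f"  FLAG {row['taxon']} {row['marker']} {row['nominal']}: "
                f"best k={row['hydroxylations']} gives {row['mono_mz']:.4f} "
                f"(off by {row['deviation']:+.4f} Da)"
            )
        lines.extend(f"  PAIR {v}" for v in self.pair_violations)
        return "\n".join(lines)


def validate_panel(panel: Panel) -> ValidationReport:
    """Check sequence/mass agreement, pair offsets, and list mass collisions."""
    rows = []
    pair_violations: list[str] = []
    for taxon, profile in panel.profiles.items():
        for la in profile.alleles.values():
            for member in la.members:
                if member.sequence is None:
                    continue
                marker = la.locus + ("'" if member.role == "prime" else "")
                rows.append(
                    {
                        "taxon": taxon,
                        "marker": marker,
                        "nominal": member.nominal,
                        "sequence": member.sequence,
                        "hydroxylations": member.hydroxylations,
                        "mono_mz": member.mono_mz,
                        "deviation": member.mono_mz - member.nominal,
                        "consistent": member.sequence_consistent,
                    }
                )
            if la.base is not None and la.prime is not None:
                offset = la.prime.mass - la.base.mass
                if abs(offset - PAIR_OFFSET) > PAIR_SLACK:
                    pair_violations.append(
                        f"{taxon} {la.locus}/{la.locus}': offset {offset:.4f} Da"
                    )
    return ValidationReport(
        allele_checks=pd.DataFrame(rows),
        pair_violations=pair_violations,
        collisions=panel.collisions(),
    )


def equivalence_classes(panel: Panel, visibility_mode: str = "maldi_visible_only") -> list[list[str]]:
    """Partition taxa indistinguishable under the matching rules.

    Two taxa fall in one class when the idealized (noise-free, full-detection)
    spectrum of each is consistent with the other under the classifier's
    consistency rules — unreported loci are wildcards and absence never
    discriminates. Classes are the connected components of that mutual
    relation, deterministically ordered.
    """
    if visibility_mode not in ("maldi_visible_only", "all_reported"):
        raise ValueError(f"unknown visibility_mode {visibility_mode!r}")
    from .classify import taxon_consistent_with_masses

    include_msms = visibility_mode == "all_reported"
    taxa = sorted(panel.profiles)
    spectra = {
        t: [
            m.mass
            for la in panel.profiles[t].alleles.values()
            for m in la.visible_members(include_msms)
        ]
        for t in taxa
    }
    adjacent = {t: set() for t in taxa}
    for i, t in enumerate(taxa):
        for u in taxa[i + 1 :]:
            if taxon_consistent_with_masses(
                panel, u, spectra[t]
            ) and taxon_consistent_with_masses(panel, t, spectra[u]):
                adjacent[t].add(u)
                adjacent[u].add(t)
    classes: list[list[str]] = []
    unseen = set(taxa)
    for t in taxa:
        if t not in unseen:
            continue
        component = []
        stack = [t]
        unseen.discard(t)
        while stack:
            cur = stack.pop()
            component.append(cur)
            for nxt in sorted(adjacent[cur]):
                if nxt in unseen:
                    unseen.discard(nxt)
                    stack.append(nxt)
        classes.append(sorted(component))
    return sorted(classes)
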