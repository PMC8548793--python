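"""Match observed peaks against the marker panel and classify samples.

The classifier implements absence-tolerant consistency: a taxon remains a
candidate as long as no observed marker peak contradicts it. Missing markers
never exclude (collagen preservation, not biology, decides which peaks
survive in archaeological samples), and loci where a taxon has no recorded
allele are wildcards.

Key ambiguity rules carried from the marker tables:

* At an oxidation-paired locus (A, F, G) a taxon's admissible masses are
  {base, base+16}; a lone observed pair member only excludes taxa whose pair
  contains neither interpretation. The F/F' overlap between the banded hare
  wallaby (2881/2897) and the other macropods (2897/2913) therefore only
  resolves when both peaks of the pair are seen.
* A mass registered at more than one locus (2975 labels both the G' partner
  of the wombat/koala group and the COL1A2 10–42 marker of most taxa) only
  anchors when corroborated — by its own pair partner or by at least one
  unambiguous marker peak elsewhere in the spectrum.
* The D-locus masses 2161/2177 are oxidation states of near-identical
  peptides and never mutually exclude (encoded as alternate masses in the
  panel).

A sample lacking the near-universal P1 marker (1162 in marsupials, also many
birds and reptiles; 1120 in the echidna) but showing several other
collagen-range markers is flagged tentative_fish_or_bird; P1 alone is
collagen without identification; too few peaks is a failed spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem import HYDROXYLATION
from .panel import Panel
from .spectra import PeakList

__all__ = [
    "MatchParams",
    "AlleleMatch",
    "MatchResult",
    "LocusObservation",
    "Classification",
    "match_peaks",
    "classify",
    "classify_peaklist",
    "report",
    "taxon_consistent_with_masses",
]

#: The locus whose presence separates collagen-bearing vertebrate classes.
P1_LOCUS = "P1"


@dataclass(frozen=True)
class MatchParams:
    """Tunable matching/classification parameters.

    ``tolerance`` is the absolute m/z window (Da) for sequence-backed marker
    masses; nominal-only masses get a window of at least 1.0 Da.
    ``min_loci`` is the minimum number of matched non-P1 loci required to
    call an identification. ``pair_window_factor`` scales the tolerance used
    to recognize a +16 oxidation partner. ``collision_corroboration``
    controls whether cross-locus ambiguous masses need corroboration before
    they anchor.
    """

    tolerance: float = 0.3
    min_loci: int = 2
    pair_window_factor: float = 2.0
    collision_corroboration: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.min_loci < 1:
            raise ValueError("min_loci must be at least 1")


@dataclass(frozen=True)
class AlleleMatch:
    taxon: str
    locus: str
    role: str
    allele_mass: float
    deviation: float
    visibility: str


@dataclass(frozen=True)
class MatchResult:
    mz: float
    intensity: float
    matches: tuple[AlleleMatch, ...]
    loci: frozenset[str]
    collision: bool


@dataclass(frozen=True)
class LocusObservation:
    locus: str
    observed_mz: tuple[float, ...]
    pair_status: str  # "unpaired_locus" | "single" | "complete_pair"


@dataclass
class Classification:
    sample_id: str
    status: str
    candidates: tuple[str, ...]
    resolved_rank: str | None
    resolved_label: str | None
    evidence: pd.DataFrame
    warnings: tuple[str, ...]
    params: MatchParams


def _allele_entries(panel: Panel):
    entries = []
    for taxon, profile in panel.profiles.items():
        for la in profile.alleles.values():
            for member in la.members:
                entries.append(
                    (
                        taxon,
                        la.locus,
                        member.role,
                        member.mass,
                        member.visibility,
                        member.sequence is not None,
                    )
                )
            for mass in la.alt_masses:
                entries.append((taxon, la.locus, "alt", mass, "maldi_visible", True))
    return entries


def match_peaks(
    peaklist: PeakList, panel: Panel, params: MatchParams = MatchParams()
) -> tuple[list[MatchResult], list[LocusObservation]]:
    """Annotate every peak with the panel alleles it could represent."""
    entries = _allele_entries(panel)
    results: list[MatchResult] = []
    for peak in peaklist:
        matches = []
        for taxon, locus, role, mass, visibility, has_seq in entries:
            window = params.tolerance if has_seq else max(params.tolerance, 1.0)
            dev = peak.mz - mass
            if abs(dev) <= window:
                matches.append(AlleleMatch(taxon, locus, role, mass, dev, visibility))
        loci = frozenset(m.locus for m in matches)
        results.append(
            MatchResult(
                mz=peak.mz,
                intensity=peak.intensity,
                matches=tuple(matches),
                loci=loci,
                collision=len(loci) > 1,
            )
        )

    observations: list[LocusObservation] = []
    for locus_name, locus in panel.loci.items():
        observed = tuple(r.mz for r in results if locus_name in r.loci)
        if not observed:
            continue
        if not locus.paired:
            status = "unpaired_locus"
        else:
            window = params.pair_window_factor * params.tolerance
            status = "single"
            for i, a in enumerate(observed):
                for b in observed[i + 1 :]:
                    if abs(abs(b - a) - HYDROXYLATION) <= window:
                        status = "complete_pair"
        observations.append(LocusObservation(locus_name, observed, status))
    return results, observations


def _anchored(results: list[MatchResult], params: MatchParams) -> list[MatchResult]:
    """Marker peaks allowed to drive exclusion.

    Unambiguous (single-locus) marker peaks always anchor. A cross-locus
    ambiguous mass anchors only when corroborated: either its +16 pair
    partner is present at one of its paired loci, or the spectrum holds at
    least one unambiguous marker peak.
    """
    marker = [r for r in results if r.matches]
    if not params.collision_corroboration:
        return marker
    plain = [r for r in marker if not r.collision]
    anchored = list(plain)
    window = params.pair_window_factor * params.tolerance
    for r in marker:
        if not r.collision:
            continue
        if plain:
            anchored.append(r)
            continue
        partner = any(
            q is not r
            and abs(abs(q.mz - r.mz) - HYDROXYLATION) <= window
            and (q.loci & r.loci)
            for q in marker
        )
        if partner:
            anchored.append(r)
    return anchored


def _consistent(panel: Panel, taxon: str, result: MatchResult, tolerance: float) -> bool:
    """Is the taxon compatible with this (anchored) marker peak?

    Compatible when, at any locus the peak could represent, the taxon either
    records no allele (wildcard) or records a mass matching the peak.
    """
    profile = panel.profiles[taxon]
    for locus in result.loci:
        la = profile.alleles.get(locus)
        if la is None or not la.reported:
            return True
        window = tolerance if all(
            m.sequence is not None for m in la.members
        ) else max(tolerance, 1.0)
        if any(abs(result.mz - mass) <= window for mass in la.mass_set()):
            return True
    return False


def _candidates(
    panel: Panel, anchored: list[MatchResult], params: MatchParams
) -> list[str]:
    return sorted(
        taxon
        for taxon in panel.profiles
        if all(_consistent(panel, taxon, r, params.tolerance) for r in anchored)
    )


def taxon_consistent_with_masses(
    panel: Panel,
    taxon: str,
    masses: list[float],
    params: MatchParams = MatchParams(),
) -> bool:
    """Convenience wrapper: consistency of a taxon with a bare mass list."""
    from .spectra import Peak

    peaklist = PeakList("query", [Peak(m, 1.0) for m in masses])
    results, _ = match_peaks(peaklist, panel, params)
    anchored = _anchored(results, params)
    return all(_consistent(panel, taxon, r, params.tolerance) for r in anchored)


def _resolve_label(panel: Panel, candidates: list[str]) -> tuple[str, str]:
    profiles = [panel.profiles[c] for c in candidates]
    if len(profiles) == 1:
        return "species", profiles[0].species
    for rank, attr in (("genus", "genus"), ("family", "family"), ("order", "order")):
        values = {getattr(p, attr) for p in profiles}
        if len(values) == 1:
            return rank, values.pop()
    return "class", "Mammalia"


def _evidence_table(
    panel: Panel, anchored: list[MatchResult], params: MatchParams
) -> pd.DataFrame:
    rows = []
    for r in sorted(anchored, key=lambda r: r.mz):
        supporting = sorted(
            t for t in panel.profiles if _consistent(panel, t, r, params.tolerance)
        )
        conflicting = sorted(set(panel.profiles) - set(supporting))
        rows.append(
            {
                "mz": round(r.mz, 4),
                "loci": "/".join(sorted(r.loci)),
                "collision": r.collision,
                "supporting": ";".join(supporting),
                "conflicting": ";".join(conflicting),
            }
        )
    return pd.DataFrame(rows, columns=["mz", "loci", "collision", "supporting", "conflicting"])


def _msms_separability_note(panel: Panel, candidates: list[str]) -> str | None:
    """Note when remaining candidates differ only at LC-MS/MS-only alleles."""
    if len(candidates) < 2:
        return None
    loci_notes = set()
    for locus in panel.loci:
        visible_sets = set()
        full_sets = set()
        for c in candidates:
            la = panel.profiles[c].alleles.get(locus)
            if la is None or not la.reported:
                continue
            visible_sets.add(tuple(sorted(m.nominal for m in la.visible_members())))
            full_sets.add(tuple(sorted(m.nominal for m in la.members)))
        if len(visible_sets) <= 1 and len(full_sets) > 1:
            loci_notes.add(locus)
    if loci_notes:
        return (
            "candidates differ only in LC-MS/MS-visible alleles at loci: "
            + ", ".join(sorted(loci_notes))
        )
    return None


def classify(
    results: list[MatchResult],
    observations: list[LocusObservation],
    panel: Panel,
    params: MatchParams = MatchParams(),
    sample_id: str = "sample",
) -> Classification:
    """Turn annotated peaks into a taxonomic call with an evidence trail."""
    anchored = _anchored(results, params)
    has_p1 = any(P1_LOCUS in r.loci for r in results if r.matches)
    other_loci = {
        locus for r in anchored for locus in r.loci if locus != P1_LOCUS
    }
    warnings: list[str] = []

    if not has_p1:
        if len(other_loci) >= params.min_loci:
            status = "tentative_fish_or_bird"
            warnings.append(
                "collagen-like marker series without the P1 marker; "
                "outside the reference panel's scope"
            )
        else:
            status = "failed"
        return Classification(
            sample_id=sample_id,
            status=status,
            candidates=(),
            resolved_rank=None,
            resolved_label=None,
            evidence=_evidence_table(panel, anchored, params),
            warnings=tuple(warnings),
            params=params,
        )

    if len(other_loci) < params.min_loci:
        return Classification(
            sample_id=sample_id,
            status="collagen_unidentifiable",
            candidates=(),
            resolved_rank=None,
            resolved_label=None,
            evidence=_evidence_table(panel, anchored, params),
            warnings=("collagen present (P1) but too few other markers",),
            params=params,
        )

    candidates = _candidates(panel, anchored, params)
    if not candidates:
        return Classification(
            sample_id=sample_id,
            status="collagen_unidentifiable",
            candidates=(),
            resolved_rank=None,
            resolved_label=None,
            evidence=_evidence_table(panel, anchored, params),
            warnings=("marker peaks jointly consistent with no panel taxon",),
            params=params,
        )

    rank, label = _resolve_label(panel, candidates)
    if len(other_loci) == params.min_loci:
        warnings.append(
            "identification rests on the minimum number of marker loci; "
            "note the P1 1162 marker is shared with many birds and reptiles"
        )
    note = _msms_separability_note(panel, candidates)
    if note:
        warnings.append(note)
    return Classification(
        sample_id=sample_id,
        status="identified",
        candidates=tuple(candidates),
        resolved_rank=rank,
        resolved_label=label,
        evidence=_evidence_table(panel, anchored, params),
        warnings=tuple(warnings),
        params=params,
    )


def classify_peaklist(
    peaklist: PeakList, panel: Panel, params: MatchParams = MatchParams()
) -> Classification:
    results, observations = match_peaks(peaklist, panel, params)
    return classify(results, observations, panel, params, sample_id=peaklist.sample_id)


def report(classifications: list[Classification]) -> tuple[pd.DataFrame, str]:
    """Assemblage summary: NISP per resolved label plus outcome tallies."""
    if not classifications:
        raise ValueError("no classifications to report")
    identified = [c for c in classifications if c.status == "identified"]
    counts: dict[tuple[str, str], int] = {}
    for c in identified:
        key = (c.resolved_label, c.resolved_rank)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"zooms_id": label, "rank": rank, "nisp": n}
        for (label, rank), n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0][0]))
    ]
    table = pd.DataFrame(rows, columns=["zooms_id", "rank", "nisp"])

    tallies = {
        status: sum(1 for c in classifications if c.status == status)
        for status in (
            "identified",
            "collagen_unidentifiable",
            "tentative_fish_or_bird",
            "failed",
        )
    }
    lines = ["ZooMS identifications", "---------------------"]
    for row in rows:
        lines.append(f"{row['zooms_id']:30s} ({row['rank']:7s}) NISP {row['nisp']}")
    lines.append("")
    lines.append(f"samples analysed:          {len(classifications)}")
    lines.append(f"identified:                {tallies['identified']}")
    lines.append(f"collagen, unidentifiable:  {tallies['collagen_unidentifiable']}")
    lines.append(f"tentative fish/bird:       {tallies['tentative_fish_or_bird']}")
    lines.append(f"failed:                    {tallies['failed']}")
    return table, "\n".join(lines)
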