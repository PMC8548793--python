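"""Sequence-level candidate-biomarker discovery.

Given homologous, pre-aligned (gap-free) collagen chain sequences for two or
more taxa, find tryptic loci whose peptide masses discriminate taxa. Each
taxon's chain is digested independently with the trypsin rule (no cut
before proline), fragments are aligned by shared start column, and a locus
is reported when at least two taxa differ in base peptide mass by at least
``min_gap``. A substitution that creates or destroys a cut site shifts the
tryptic span of the affected taxon; such loci are reported with a
span-shift flag rather than discarded (the monotreme E-marker case, where
a proline after a lysine suppresses the cut and extends the peptide by
four residues).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem import digest, monoisotopic_mhplus, read_chains

__all__ = [
    "AlignedChainSet",
    "CandidateMarker",
    "discover_markers",
    "project_panel",
]

#: Cap on reported hydroxylation ladder rungs, to avoid combinatorial noise.
LADDER_CAP = 6


@dataclass(frozen=True)
class AlignedChainSet:
    """Equal-length homologous chain sequences for one collagen chain."""

    chain_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need at least two taxa")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"chain {self.chain_id}: sequences have unequal lengths {sorted(lengths)}"
            )

    @classmethod
    def from_fasta(cls, path, chain_id: str) -> "AlignedChainSet":
        return cls(chain_id, read_chains(path))


@dataclass(frozen=True)
class CandidateMarker:
    """A discriminating tryptic locus across taxa."""

    chain_id: str
    start: int  # 1-based alignment column where the tryptic peptide begins
    peptides: dict[str, str]  # taxon -> peptide
    spans: dict[str, tuple[int, int]]  # taxon -> 1-based inclusive span
    ladders: dict[str, tuple[float, ...]]  # taxon -> [M+H]+ for k=0..cap
    gaps: tuple[tuple[str, str, float], ...]  # (taxon_a, taxon_b, mass gap)
    span_shifted: bool

    @property
    def max_gap(self) -> float:
        return max(g for _, _, g in self.gaps)


def _ladder(peptide: str) -> tuple[float, ...]:
    cap = min(sum(1 for aa in peptide if aa in "PK"), LADDER_CAP)
    return tuple(monoisotopic_mhplus(peptide, k) for k in range(cap + 1))


def discover_markers(
    chains: AlignedChainSet, missed_cleavages: int = 0, min_gap: float = 2.0
) -> list[CandidateMarker]:
    """Find tryptic loci whose base peptide masses separate taxa by >= min_gap.

    ``min_gap`` defaults to 2.0 Da, comfortably above the deamidation
    (+0.98) shift and away from the ±16 oxidation ambiguity.
    """
    if not 0 <= missed_cleavages <= 1:
        raise ValueError("missed_cleavages must be 0 or 1")
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")

    taxa = sorted(chains.sequences)
    # Fully cleaved product per start column (the shortest product there).
    per_taxon: dict[str, dict[int, str]] = {}
    for taxon in taxa:
        products: dict[int, str] = {}
        for peptide, start in digest(chains.sequences[taxon], missed_cleavages):
            if start not in products or len(peptide) < len(products[start]):
                products[start] = peptide
        per_taxon[taxon] = products

    shared_starts = sorted(
        set.intersection(*(set(per_taxon[t]) for t in taxa))
    )
    candidates: list[CandidateMarker] = []
    for start in shared_starts:
        peptides = {t: per_taxon[t][start] for t in taxa}
        masses = {t: monoisotopic_mhplus(p) for t, p in peptides.items()}
        gaps = tuple(
            (a, b, abs(masses[a] - masses[b]))
            for i, a in enumerate(taxa)
            for b in taxa[i + 1 :]
        )
        if not any(g >= min_gap for _, _, g in gaps):
            continue
        candidates.append(
            CandidateMarker(
                chain_id=chains.chain_id,
                start=start,
                peptides=peptides,
                spans={t: (start, start + len(p) - 1) for t, p in peptides.items()},
                ladders={t: _ladder(p) for t, p in peptides.items()},
                gaps=gaps,
                span_shifted=len({len(p) for p in peptides.values()}) > 1,
            )
        )
    return candidates


def project_panel(
    candidates: list[CandidateMarker],
    taxa: dict[str, str] | list[str] | None = None,
    hydroxylations: int | dict[int, int] = 0,
) -> pd.DataFrame:
    """Emit discovered alleles as a panel-format table for merging.

    ``taxa`` restricts/annotates the taxa: a dict maps taxon name to a
    'genus;family;order' lineage string, a list keeps placeholder lineages.
    ``hydroxylations`` selects the reported oxidation state per candidate
    (keyed by start column) or globally; nominal masses are the rounded
    [M+H]+ at that state.
    """
    if not candidates:
        raise ValueError("no candidate markers to project")
    starts = [c.start for c in candidates]
    dup = {s for s in starts if starts.count(s) > 1}
    if dup:
        raise ValueError(f"conflicting duplicate loci at start columns {sorted(dup)}")

    if taxa is None:
        lineage_of = {t: "unknown;unknown;unknown" for c in candidates for t in c.peptides}
    elif isinstance(taxa, dict):
        lineage_of = dict(taxa)
    else:
        lineage_of = {t: "unknown;unknown;unknown" for t in taxa}

    rows = []
    for cand in sorted(candidates, key=lambda c: c.start):
        k = (
            hydroxylations.get(cand.start, 0)
            if isinstance(hydroxylations, dict)
            else hydroxylations
        )
        for taxon in sorted(cand.peptides):
            if taxon not in lineage_of:
                continue
            peptide = cand.peptides[taxon]
            span = cand.spans[taxon]
            kk = min(k, len(cand.ladders[taxon]) - 1)
            mz = cand.ladders[taxon][kk]
            rows.append(
                {
                    "taxon": taxon,
                    "lineage": lineage_of[taxon],
                    "chain": cand.chain_id,
                    "span": f"{span[0]}-{span[1]}",
                    "marker_name": f"{cand.chain_id}_{cand.start}",
                    "nominal_mz": str(int(round(mz))),
                    "sequence": peptide,
                    "visibility": "maldi_visible",
                    "diagnostic": "0",
                    "pair_partner_mz": "",
                    "alt_mz": "",
                }
            )
    return pd.DataFrame(rows)
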