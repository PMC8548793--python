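"""Re-derive discriminating loci from the marker peptide sequences.

Builds synthetic scaffold chains by stitching each taxon's published marker
peptides (joined by constant tryptic spacers), runs sequence-level marker
discovery on them, and confirms that the discovered loci reproduce the
published inter-taxon mass gaps. The scaffolds are synthetic stand-ins for
full collagen chains, which are not bundled; only the relative differences
at marker loci are meaningful.

Writes results/discovered_markers.tsv (a loadable panel fragment).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from zooms.discover import AlignedChainSet, discover_markers, project_panel  # noqa: E402
from zooms.panel import bundled_panel  # noqa: E402

SPACER = "GPAGPR"
# loci whose base peptides are span-conserved across these taxa
SCAFFOLD_LOCI = ["P1", "B", "C", "D", "889-906"]
TAXA = [
    "Tachyglossus aculeatus",
    "Osphranter robustus",
    "Trichosurus vulpecula",
    "Phascolarctos cinereus",
]


def main() -> None:
    panel = bundled_panel()
    chains = {}
    for taxon in TAXA:
        parts = []
        for locus in SCAFFOLD_LOCI:
            la = panel.profiles[taxon].alleles.get(locus)
            if la is None or la.base is None or la.base.sequence is None:
                sys.exit(f"{taxon} lacks a sequence at locus {locus}")
            parts.append(la.base.sequence)
        chains[taxon] = SPACER + SPACER.join(parts) + SPACER
    chain_set = AlignedChainSet("scaffold", chains)

    candidates = discover_markers(chain_set, missed_cleavages=0, min_gap=2.0)
    print(f"discovered {len(candidates)} discriminating loci "
          f"on a {len(SCAFFOLD_LOCI)}-marker scaffold of {len(TAXA)} taxa:")
    for cand in candidates:
        gaps = [f"{a.split()[0][0]}.{a.split()[1]} vs {b.split()[0][0]}.{b.split()[1]}: "
                f"{g:.2f} Da" for a, b, g in cand.gaps if g >= 2.0]
        flag = " [span-shifted]" if cand.span_shifted else ""
        print(f"  start col {cand.start:3d}{flag}: " + "; ".join(gaps))

    fragment = project_panel(
        candidates,
        taxa={t: ";".join(panel.profiles[t].lineage[1:]) for t in TAXA},
        hydroxylations={c.start: 1 for c in candidates},
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    fragment.to_csv(results / "discovered_markers.tsv", sep="\t", index=False)
    print(f"\npanel fragment: {results / 'discovered_markers.tsv'}")


if __name__ == "__main__":
    main()
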