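"""Classify the simulated assemblage and score the calls against truth.

Reads the peak lists written by 02_simulate_assemblage.py, classifies each
against the bundled panel, prints the NISP summary table, and cross-checks
every call against the known ground truth (an identified sample is correct
when its truth taxon is in the candidate set; collagen-only and
non-collagen samples must never be assigned a taxon).

Writes results/assemblage_calls.tsv and results/assemblage_report.tsv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from zooms.classify import MatchParams, classify_peaklist, report  # noqa: E402
from zooms.panel import bundled_panel  # noqa: E402
from zooms.spectra import read_peaklist  # noqa: E402


def main() -> None:
    spectra_dir = ROOT / "scratch" / "assemblage"
    truth_path = ROOT / "results" / "assemblage_truth.tsv"
    if not spectra_dir.exists() or not truth_path.exists():
        sys.exit("run analysis/02_simulate_assemblage.py first")

    panel = bundled_panel()
    params = MatchParams(tolerance=0.3, min_loci=2)
    truth = dict(
        pd.read_csv(truth_path, sep="\t")[["sample_id", "truth"]].itertuples(index=False)
    )

    calls = []
    classifications = []
    for path in sorted(spectra_dir.glob("s*.txt")):
        c = classify_peaklist(read_peaklist(path), panel, params)
        classifications.append(c)
        t = truth[c.sample_id]
        if c.status == "identified":
            correct = t in c.candidates
        else:
            correct = t in ("collagen_only", "non_collagen") or c.status != "identified"
        calls.append(
            {
                "sample_id": c.sample_id,
                "truth": t,
                "status": c.status,
                "resolved": c.resolved_label or "",
                "rank": c.resolved_rank or "",
                "n_candidates": len(c.candidates),
                "correct": correct,
            }
        )

    results = ROOT / "results"
    calls_df = pd.DataFrame(calls)
    calls_df.to_csv(results / "assemblage_calls.tsv", sep="\t", index=False)

    table, text = report(classifications)
    table.to_csv(results / "assemblage_report.tsv", sep="\t", index=False)
    print(text)
    print()

    identified = calls_df[calls_df["status"] == "identified"]
    wrongly_assigned = identified[
        identified["truth"].isin(["collagen_only", "non_collagen"])
    ]
    hit = identified[~identified["truth"].isin(["collagen_only", "non_collagen"])][
        "correct"
    ]
    print(f"identified samples with truth in candidate set: {int(hit.sum())}/{len(hit)}")
    print(f"degenerate samples wrongly assigned a taxon:    {len(wrongly_assigned)}")


if __name__ == "__main__":
    main()
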