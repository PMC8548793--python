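"""Peak matching and taxonomic classification rules."""

import numpy as np
import pytest

from zooms.classify import (
    MatchParams,
    classify_peaklist,
    match_peaks,
    report,
    taxon_consistent_with_masses,
)
from zooms.simulate import SimulationParams, simulate_spectrum
from zooms.spectra import Peak, PeakList

from conftest import noise_free_spectrum


def oracle_candidates(panel, mz_values, tol=0.3):
    """Brute-force restatement of the consistency rules, used as an oracle.

    For every taxon, test its full profile against the observed peaks:
    a peak may represent any locus where any taxon has a matching mass;
    unambiguous peaks anchor, cross-locus ambiguous ones only when
    corroborated; a taxon survives when every anchored peak fits some
    interpretation (wildcard loci always fit).
    """
    table = {
        taxon: {
            locus: list(la.mass_set())
            for locus, la in profile.alleles.items()
            if la.reported
        }
        for taxon, profile in panel.profiles.items()
    }
    peak_loci = []
    for mz in mz_values:
        loci = {
            locus
            for masses_by_locus in table.values()
            for locus, masses in masses_by_locus.items()
            if any(abs(mz - m) <= tol for m in masses)
        }
        if loci:
            peak_loci.append((mz, loci))
    unambiguous = [pl for pl in peak_loci if len(pl[1]) == 1]
    anchored = list(unambiguous)
    for mz, loci in peak_loci:
        if len(loci) == 1:
            continue
        if unambiguous or any(
            q != mz and (ql & loci) and abs(abs(mz - q) - 15.99491) <= 2 * tol
            for q, ql in peak_loci
        ):
            anchored.append((mz, loci))
    out = []
    for taxon in panel.profiles:
        fits = all(
            any(
                locus not in table[taxon]
                or any(abs(mz - m) <= tol for m in table[taxon][locus])
                for locus in loci
            )
            for mz, loci in anchored
        )
        if fits:
            out.append(taxon)
    return sorted(out)


class TestMatchPeaks:
    def test_p1_peak_matches_all_marsupials(self, panel):
        pl = PeakList("s", [Peak(1162.60, 100.0)])
        results, obs = match_peaks(pl, panel)
        (r,) = results
        assert r.loci == frozenset({"P1"})
        assert not r.collision
        assert len({m.taxon for m in r.matches}) == 23  # every marsupial

    def test_2975_flagged_at_two_loci(self, panel):
        pl = PeakList("s", [Peak(2975.4, 10.0)])
        results, _ = match_peaks(pl, panel)
        (r,) = results
        assert r.collision
        assert r.loci == frozenset({"G", "2T3"})

    def test_empty_peaklist(self, panel):
        results, obs = match_peaks(PeakList("s", []), panel)
        assert results == [] and obs == []

    def test_pair_status(self, panel):
        pl = PeakList("s", [Peak(2897.44, 10.0), Peak(2913.43, 5.0)])
        _, obs = match_peaks(pl, panel)
        f_obs = next(o for o in obs if o.locus == "F")
        assert f_obs.pair_status == "complete_pair"
        _, obs = match_peaks(PeakList("s", [Peak(2897.44, 10.0)]), panel)
        assert next(o for o in obs if o.locus == "F").pair_status == "single"

    def test_match_count_monotone_in_tolerance(self, panel):
        pl = noise_free_spectrum(panel, "Vombatus ursinus")
        counts = []
        for tol in (0.05, 0.1, 0.3, 0.6, 1.0):
            results, _ = match_peaks(pl, panel, MatchParams(tolerance=tol))
            counts.append(sum(len(r.matches) for r in results))
        assert counts == sorted(counts)


class TestStatusRules:
    def test_p1_only_is_collagen_unidentifiable(self, panel):
        pl = PeakList("s", [Peak(1162.60, 100.0)])
        c = classify_peaklist(pl, panel)
        assert c.status == "collagen_unidentifiable"
        assert c.candidates == ()

    def test_marker_series_without_p1_is_tentative_fish_or_bird(self, panel):
        pl = PeakList("s", [Peak(1453.74, 10.0), Peak(2145.13, 8.0), Peak(2897.44, 5.0)])
        c = classify_peaklist(pl, panel)
        assert c.status == "tentative_fish_or_bird"

    def test_sparse_or_unmatched_spectra_fail(self, panel):
        assert classify_peaklist(PeakList("s", []), panel).status == "failed"
        pl = PeakList("s", [Peak(900.0, 5.0), Peak(1750.8, 2.0)])
        assert classify_peaklist(pl, panel).status == "failed"

    def test_min_loci_warning_on_thin_evidence(self, panel):
        pl = PeakList("s", [Peak(1162.60, 50.0), Peak(1453.74, 10.0), Peak(2145.13, 8.0)])
        c = classify_peaklist(pl, panel)
        assert c.status == "identified"
        assert any("birds and reptiles" in w for w in c.warnings)


class TestConsistencyRules:
    def test_d_locus_oxidation_states_never_mutually_exclude(self, panel):
        taxon = "Pseudocheirus peregrinus"  # D reported at 2161
        masses = [
            m.mass
            for la in panel.profiles[taxon].alleles.values()
            for m in la.visible_members()
        ]
        shifted = [m + 15.99491 if abs(m - 2161.12) < 0.3 else m for m in masses]
        assert taxon_consistent_with_masses(panel, taxon, shifted)

    def test_lone_pair_member_respects_overlap(self, panel):
        # a lone 2897 sits in both the L. fasciatus (2881/2897) and the
        # other-macropod (2897/2913) F pairs, so it separates neither...
        assert taxon_consistent_with_masses(panel, "Lagostrophus fasciatus", [2897.44])
        assert taxon_consistent_with_masses(panel, "Osphranter robustus", [2897.44])
        # ...but the complete observed pair does
        pair = [2897.44, 2913.43]
        assert not taxon_consistent_with_masses(panel, "Lagostrophus fasciatus", pair)
        assert taxon_consistent_with_masses(panel, "Osphranter robustus", pair)

    def test_uncorroborated_2975_does_not_exclude(self, panel):
        # alone, the two-locus 2975 peak anchors nothing
        assert taxon_consistent_with_masses(panel, "Macropus giganteus", [2975.35])
        # corroborated by an unambiguous marker, it excludes Macropus
        assert not taxon_consistent_with_masses(
            panel, "Macropus giganteus", [2975.35, 1453.74]
        )

    def test_unreported_locus_is_wildcard(self, panel):
        # P. tapoatafa reports no A-locus allele; A-pair peaks cannot exclude it
        assert taxon_consistent_with_masses(
            panel, "Phascogale tapoatafa", [1150.63, 1166.63]
        )


class TestOracleEquivalence:
    def test_candidates_match_brute_force(self, panel):
        params = MatchParams()
        rng = np.random.default_rng(17)
        for taxon in panel.profiles:
            for seed in range(5):
                sim = SimulationParams(
                    target=taxon, mass_sd=0.05, detection=0.7,
                    noise_peaks=3, seed=int(rng.integers(2**31)),
                )
                pl = simulate_spectrum(panel, sim)
                c = classify_peaklist(pl, panel, params)
                expected = oracle_candidates(panel, [p.mz for p in pl])
                if c.status == "identified":
                    assert list(c.candidates) == expected
                else:
                    observed = [
                        t for t in panel.profiles
                        if taxon_consistent_with_masses(panel, t, [p.mz for p in pl])
                    ]
                    assert sorted(observed) == expected

    def test_candidate_set_monotone_under_peak_removal(self, panel):
        rng = np.random.default_rng(23)
        pl = simulate_spectrum(
            panel,
            SimulationParams(target="Sarcophilus harrisii", mass_sd=0.05,
                             detection=1.0, noise_peaks=4, seed=99),
        )
        full = set(classify_peaklist(pl, panel).candidates) or {
            t for t in panel.profiles
            if taxon_consistent_with_masses(panel, t, [p.mz for p in pl])
        }
        for _ in range(20):
            keep = [p for p in pl if rng.uniform() < 0.6]
            kept = {
                t for t in panel.profiles
                if taxon_consistent_with_masses(panel, t, [p.mz for p in keep])
            }
            assert full <= kept


class TestResolutionAndReport:
    def test_resolved_rank_walks_up_lineage(self, panel):
        c = classify_peaklist(noise_free_spectrum(panel, "Macropus giganteus"), panel)
        assert (c.resolved_rank, c.resolved_label) == ("genus", "Macropus")
        c = classify_peaklist(noise_free_spectrum(panel, "Notamacropus eugenii"), panel)
        assert (c.resolved_rank, c.resolved_label) == ("family", "Macropodidae")
        c = classify_peaklist(noise_free_spectrum(panel, "Perameles nasuta"), panel)
        assert (c.resolved_rank, c.resolved_label) == ("species", "Perameles nasuta")

    def test_report_nisp_counts(self, panel):
        classifications = (
            [classify_peaklist(noise_free_spectrum(panel, "Osphranter robustus", s), panel)
             for s in range(36)]
            + [classify_peaklist(noise_free_spectrum(panel, "Isoodon macrourus", s), panel)
               for s in range(3)]
            + [classify_peaklist(noise_free_spectrum(panel, "Trichosurus vulpecula", 1), panel)]
        )
        table, text = report(classifications)
        counts = dict(zip(table["zooms_id"], table["nisp"]))
        assert counts == {
            "Macropodidae": 36,
            "Isoodon macrourus": 3,
            "Trichosurus vulpecula": 1,
        }
        assert "NISP 36" in text

    def test_report_all_failed(self, panel):
        classifications = [
            classify_peaklist(PeakList(f"s{i}", []), panel) for i in range(4)
        ]
        table, text = report(classifications)
        assert table.empty
        assert "failed:                    4" in text

    def test_report_requires_input(self):
        with pytest.raises(ValueError):
            report([])

    def test_evidence_table_lists_loci(self, panel):
        c = classify_peaklist(noise_free_spectrum(panel, "Tachyglossus aculeatus"), panel)
        assert "P1" in set(c.evidence["loci"])
        assert (c.evidence["supporting"].str.len() > 0).all()
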