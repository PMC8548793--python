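"""Peptide mass arithmetic, tryptic digestion, and modification inference."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from zooms.chem import (
    HYDROXYLATION,
    PROTON,
    WATER,
    ModificationSpec,
    PeptideVariant,
    digest,
    extract_locus_peptide,
    infer_hydroxylations,
    monoisotopic_mhplus,
)

AA = "GASPVTCLINDQKEMHFRYW"
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


class TestMonoisotopicMass:
    def test_single_glycine(self):
        # hand sum: 57.02146 + 18.010565 + 1.007276
        assert monoisotopic_mhplus("G") == pytest.approx(76.039301, abs=1e-3)

    @given(sequences)
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_pyteomics(self, seq):
        expected = pyteomics_mass.calculate_mass(sequence=seq, ion_type="M", charge=1)
        assert monoisotopic_mhplus(seq) == pytest.approx(expected, abs=2e-3)

    @given(sequences, sequences)
    @settings(max_examples=200, derandomize=True)
    def test_additivity_of_condensation(self, a, b):
        # peptide-bond formation releases one water
        combined = PeptideVariant(a + b).neutral_mass
        assert combined == pytest.approx(
            PeptideVariant(a).neutral_mass + PeptideVariant(b).neutral_mass - WATER,
            abs=1e-6,
        )

    def test_oxidation_ladder_step(self):
        seq = "GVQGPPGPQGPR"
        for k in range(seq.count("P")):
            step = monoisotopic_mhplus(seq, k + 1) - monoisotopic_mhplus(seq, k)
            assert step == pytest.approx(HYDROXYLATION, abs=1e-9)

    def test_marsupial_p1_marker(self):
        # the hydroxylated P1 peptide sits at the 1162 marker
        assert monoisotopic_mhplus("GVQGPPGPQGPR", 1) == pytest.approx(1162, abs=1.0)

    def test_deamidation_shift(self):
        shift = monoisotopic_mhplus("GNQG", 0, 2) - monoisotopic_mhplus("GNQG")
        assert shift == pytest.approx(2 * 0.98402, abs=1e-9)

    @pytest.mark.parametrize(
        "seq, k, d, err",
        [
            ("", 0, 0, "non-empty"),
            ("GXZ", 0, 0, "non-canonical"),
            ("GAG", 1, 0, "exceed"),
            ("GPG", 0, 1, "exceed"),
        ],
    )
    def test_rejections(self, seq, k, d, err):
        with pytest.raises(ValueError, match=err):
            monoisotopic_mhplus(seq, k, d)

    def test_error_names_offending_symbol_and_position(self):
        with pytest.raises(ValueError, match=r"'B' at position 3"):
            monoisotopic_mhplus("GABG")

    def test_met_oxidation_opt_in(self):
        with pytest.raises(ValueError):
            monoisotopic_mhplus("GMG", 1)
        delta = monoisotopic_mhplus("GMG", 1, allow_met_oxidation=True) - monoisotopic_mhplus("GMG")
        assert delta == pytest.approx(HYDROXYLATION, abs=1e-9)


class TestInferHydroxylations:
    @pytest.mark.parametrize(
        "seq, nominal, expected",
        [
            ("GVQGPAGPQGPR", 1120, 0),  # echidna P1, unmodified
            ("GVQGPPGPQGPR", 1162, 1),  # marsupial P1, one hydroxyproline
            ("GPNGEPGSTGPTGPPGLR", 1680, 2),
            ("GVQGPPGPQGPR", 5000, None),  # unreachable mass
        ],
    )
    def test_known_counts(self, seq, nominal, expected):
        assert infer_hydroxylations(seq, nominal) == expected

    @given(sequences, st.integers(min_value=0, max_value=12))
    @settings(max_examples=200, derandomize=True)
    def test_matches_exhaustive_enumeration(self, seq, k_true):
        capacity = sum(1 for aa in seq if aa in "PK")
        k_true = min(k_true, capacity)
        nominal = monoisotopic_mhplus(seq, k_true)
        # independent enumeration of every ladder rung
        solutions = [
            k
            for k in range(capacity + 1)
            if abs(
                sum(pyteomics_mass.std_aa_mass[aa] for aa in seq)
                + WATER + PROTON + k * HYDROXYLATION - nominal
            ) <= 1.0
        ]
        assert infer_hydroxylations(seq, nominal) == (min(solutions) if solutions else None)

    def test_requires_positive_tolerance(self):
        with pytest.raises(ValueError):
            infer_hydroxylations("GPG", 300.0, tolerance=0.0)


def oracle_digest(sequence, missed_cleavages, no_cut_before_proline=True):
    """Independent position-scan digest: enumerate every substring and keep
    those bounded by cut sites with at most the allowed internal sites."""

    def cut_after(i):  # 0-based index i: cut between i and i+1?
        if sequence[i] not in "KR":
            return False
        if no_cut_before_proline and i + 1 < len(sequence) and sequence[i + 1] == "P":
            return False
        return True

    n = len(sequence)
    out = []
    for lo in range(n):
        if lo != 0 and not cut_after(lo - 1):
            continue
        for hi in range(lo + 1, n + 1):
            if hi != n and not cut_after(hi - 1):
                continue
            internal = sum(1 for i in range(lo, hi - 1) if cut_after(i))
            if internal <= missed_cleavages:
                out.append((sequence[lo:hi], lo + 1))
    return sorted(out, key=lambda p: (p[1], len(p[0])))


class TestDigest:
    @pytest.mark.parametrize(
        "seq, mc, expected",
        [
            ("AAKGG", 0, [("AAK", 1), ("GG", 4)]),
            ("GGKPGR", 0, [("GGKPGR", 1)]),  # K before P is not a cut site
            ("AAKRGG", 1, [("AAK", 1), ("AAKR", 1), ("R", 4), ("RGG", 4), ("GG", 5)]),
        ],
    )
    def test_examples(self, seq, mc, expected):
        assert digest(seq, mc) == expected

    @given(sequences, st.integers(min_value=0, max_value=3), st.booleans())
    @settings(max_examples=1200, derandomize=True)
    def test_equals_position_scan_oracle(self, seq, mc, kp_rule):
        assert digest(seq, mc, no_cut_before_proline=kp_rule) == oracle_digest(
            seq, mc, no_cut_before_proline=kp_rule
        )

    @given(sequences)
    @settings(max_examples=300, derandomize=True)
    def test_full_cleavage_reconstructs_input(self, seq):
        assert "".join(p for p, _ in digest(seq, 0)) == seq

    @given(sequences, st.integers(min_value=0, max_value=3))
    @settings(max_examples=300, derandomize=True)
    def test_internal_cut_sites_bounded(self, seq, mc):
        for peptide, start in digest(seq, mc):
            internal = sum(
                1
                for i, aa in enumerate(peptide[:-1])
                if aa in "KR" and peptide[i + 1] != "P"
            )
            assert internal <= mc


class TestExtractLocusPeptide:
    CHAIN = "GARGVQGPPGPQGPRGGK"  # marker peptide at 4..15, flanked by R/R

    def test_valid_tryptic_span(self):
        peptide, valid = extract_locus_peptide(self.CHAIN, 4, 15)
        assert peptide == "GVQGPPGPQGPR"
        assert valid

    def test_mid_fragment_span_flagged(self):
        peptide, valid = extract_locus_peptide(self.CHAIN, 4, 10)
        assert peptide == "GVQGPPG"
        assert not valid

    def test_span_errors(self):
        with pytest.raises(ValueError):
            extract_locus_peptide(self.CHAIN, 10, 4)
        with pytest.raises(ValueError):
            extract_locus_peptide(self.CHAIN, 0, 5)


class TestModificationSpec:
    def test_capacity_check(self):
        spec = ModificationSpec(hydroxylations=3)
        with pytest.raises(ValueError):
            spec.validate_against("GPG")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ModificationSpec(hydroxylations=-1)
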