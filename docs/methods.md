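# Methods

## Peptide mass model

Marker masses are singly protonated monoisotopic masses computed from
standard residue masses (5-decimal monoisotopic values; water 18.010565,
proton 1.007276). Post-translational modifications are modelled as counts,
not positions: hydroxylation (+15.99491, siteable on P and K; optionally M,
off by default since no bundled marker needs it) and deamidation
(+0.98402, siteable on N and Q), each bounded by the number of available
sites. Positional isomers are mass-identical, and MALDI fingerprints carry
no site information, so nothing is lost.

Published marker tables print integer mass labels that mix truncation
(1162.596 → "1162") and rounding (1679.798 → "1680"); agreement between a
computed mass and a printed label is therefore judged at ±1.0 Da, and the
hydroxylation count linking a printed sequence to its printed mass is
recovered by exhaustive search over k = 0..(#P+#K)
(`infer_hydroxylations`), which is exact by construction.

Trypsin specificity is C-terminal K/R with no cut before proline
(configurable off). The no-cut-before-P rule is load-bearing: it produces
the monotreme E-marker peptide, which carries a K followed by P and is
therefore four residues longer than its marsupial counterpart.

## The bundled panel

The panel covers 24 taxa (23 marsupials, 1 monotreme) at 11 loci; three
loci (A, F, G) are oxidation pairs reported as base/+16 mass pairs.
Per-allele metadata: visibility (`maldi_visible`; `msms_only` for alleles
confirmed only in LC-MS/MS data — these support but are never simulated or
required; `unreported` for absent cells, treated as wildcards), a
`diagnostic` flag (bold in the source tables, metadata only — it never
changes matching), and a +16 partner mass where reported. Where the
peptide sequence is known (every reported allele), the matching mass is
the recomputed monoisotopic value, not the integer label.

Special cases encoded in the panel data:

* D locus, 2161/2177: two near-identical peptides observed with both two
  and three oxidations; either mass can belong to either allele, so each
  carries the other as an alternate mass and they never mutually exclude.
  The A→S substitution separating them weighs 15.99492 Da — identical to
  an oxidation — which is why the ambiguity is irreducible.
* The common wombat's D allele is stored at 2119 (the two-oxidation state,
  the one most visible for that species) with 2135 allowed as an alternate.
* The 2121 D mass is carried by two different sequences; they are exactly
  mass-identical (at k=3 vs k=2), so the sequence-to-taxon assignment
  (thylacine vs echidna) cannot affect classification.
* Known source inconsistency: the echidna G/G′ entry prints 2999/3015,
  but its printed sequence computes to 3000.48/3016.48 at best (k=3/4) —
  1.48 Da off, beyond the ±1.0 Da window. No hydroxylation/deamidation
  combination closes the gap. The entry is transcribed as printed and
  `validate_panel` flags exactly this allele; the corresponding acceptance
  test is left failing rather than silently "fixing" published data.
  Classification is unaffected (both simulation and matching use the same
  computed mass, and the echidna is pinned by P1/C/E regardless).

A mass collision registry lists every nominal mass attached to more than
one (locus, role): 2975 (G′ of the wombat/koala group vs COL1A2 10–42 of
most taxa — the one cross-locus case), 2945 and 2959 (G of one taxon vs
G′ of another), 2897 (F/F′) and 2161/2177.

## Matching and classification

Default mass tolerance is 0.3 Da (external-calibration MALDI-TOF scale;
the source work does not state the tolerance its markers were read at).
A peak matches an allele when within tolerance of its computed mass
(within 1.0 Da of the nominal label for sequence-less alleles in external
panels).

A taxon is a candidate iff every *anchored* peak fits it at some locus the
peak could represent — where "fits" means the taxon is unreported there
(wildcard) or its mass set contains the peak. At paired loci the mass set
is {base, base+16}: a lone pair member excludes only taxa whose pair
contains neither interpretation, which reproduces the published F/F′
caveat (a lone 2897 never separates the banded hare wallaby, whose pair is
2881/2897, from the other macropods at 2897/2913; the complete observed
pair does). Cross-locus ambiguous peaks (2975) anchor only when
corroborated by their own +16 partner or by at least one unambiguous
marker peak. Exclusion is only ever driven by observed conflicting peaks,
never by absence — dropout dominates degraded samples.

Status rules: no P1-type peak (1162/1120) with at least `min_loci` (=2)
other matched loci → `tentative_fish_or_bird`; P1 with fewer than
`min_loci` other loci → `collagen_unidentifiable`; too few matches →
`failed`; otherwise `identified`, with the candidate set reported at the
lowest common lineage rank (species → genus → family → order → class,
over a hard-coded minimal taxonomy of the 24 taxa). Candidates are
reported alphabetically; every output is deterministic. Identifications
resting on exactly `min_loci` loci carry a warning that P1 1162 is shared
with many birds and reptiles; multi-candidate calls note when candidates
differ only at LC-MS/MS-visible alleles.

One deliberate consequence of these rules: the red kangaroo's F′ partner
is MS/MS-only, so its own noise-free spectrum shows a lone F peak and
cannot exclude the banded hare wallaby — its candidate set is strictly
larger than its mutual-indistinguishability class. This asymmetry is real
(less informative spectra exclude less), affects only that taxon, and is
asserted as such in the tests.

## Synthetic spectra

The generator emulates what the classifier must survive, with known truth:

* each locus with a MALDI-visible allele is detected with probability
  `detection` (presets: good 0.95, degraded 0.6, poor 0.25); dropout is
  independent Bernoulli per locus — real taphonomic correlation structure
  is unknown and not modelled;
* emitted peaks sit at the allele's computed monoisotopic mass plus a
  constant calibration offset plus Gaussian error (`mass_sd`, default
  0.05 Da);
* when both pair members are visible the +16 partner takes an
  `oxidation_split` share (default 0.4) of the log-normal peak intensity;
* `noise_peaks` uniform noise peaks over 800–3200 Da (the marker mass
  range), log-normally weaker than marker peaks — the simplest adversarial
  stand-in, since no noise model is published;
* `collagen_only` samples emit exactly one P1-region peak; `non_collagen`
  samples emit only noise;
* all randomness flows from one integer seed through named child streams;
  the per-locus draw schedule is fixed, so lowering `detection` removes
  peaks without moving any surviving peak, and assemblage sample seeds are
  spawned deterministically from the master seed.

What passing simulation-based tests does **not** show about real data:
isotope envelopes, adducts, detector saturation, baseline effects,
correlated preservation, and off-panel collagen (real fish/bird bone) are
not modelled; the `tentative_fish_or_bird` category is exercised only by
on-panel spectra that lost their P1 peak.

## Discovery

`discover_markers` is a deliberately simplified, sequence-level form of
candidate-biomarker identification: it takes pre-aligned, gap-free
homologous chains (collagen chains are near-equal length; building
alignments is out of scope), digests each taxon independently, aligns
fragments by shared start column, and reports loci where base peptide
masses differ by ≥ `min_gap` (default 2.0 Da, clear of deamidation and
oxidation confusions). Substitutions that create or destroy cut sites are
reported as span-shifted loci rather than dropped. Hydroxylation ladders
are reported for k = 0..min(#P+#K, 6) to bound combinatorial noise.
Database searching, error-tolerant variant search and FDR machinery are
out of scope. The analysis driver runs discovery on synthetic scaffold
chains stitched from the published marker peptides; only relative
differences at marker loci are meaningful there.

## Problem sizes

Test and driver workloads are sized for a single CPU: the oracle
equivalence check runs 24 taxa × 20 seeds, the robustness check 24 taxa ×
100 seeds (plus 100 P1-only samples), the digest property 1000 random
sequences against an independent position-scan oracle, and the assemblage
driver 131 samples. The full suite runs in well under a minute.
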