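# Methods

## Information model

A metabolite's ¹H-detected NMR spectra carry a countable set of
identification features. `micekit` counts seven: the number of ¹H chemical
shifts, the number of multiplicities, the number of 2-/3-bond H,H coupling
constants, a 0/1 second-order flag, and the numbers of COSY, HSQC and HMBC
cross-peaks. Each counted feature is one *bit* of metabolite
identification information. Bits accumulate over four evidence levels —
1D ¹H alone; plus COSY; plus HSQC; plus HMBC — and are normalised to

* **MIE** — bits per heavy atom (any non-hydrogen atom),
* **MICE** — bits per carbon atom,
* **MIHF** — observed bits divided by theoretically available bits.

MIE parallels ligand efficiency in drug discovery (binding energy per
heavy atom); carbon is the alternative denominator because carbons carry
nearly all non-exchangeable protons. MICE/MIE = N_heavy/N_C holds exactly
by construction and is asserted over the whole cohort in the tests.

## Counting rules (theoretical)

1. **Exchangeability.** Only non-exchanging protons count. The structural
   rule: O-H and S-H always exchange; N-H exchanges unless the nitrogen is
   an amide nitrogen (single-bonded to a carbonyl carbon) — amide N-H is
   slow to exchange on the NMR timescale in aqueous biofluids and counts.
   Guanidine, amine, imidazole and indole N-H are treated as exchangeable.
   Per-atom overrides are honoured for curated corrections.
2. **Shifts and multiplicities.** One shift per proton equivalence class;
   one multiplicity per resonance, however complex the multiplet (a
   "triplet of septets" is one multiplicity bit). A molecule with no
   non-exchanging protons gets zero counts and an NMR-invisible flag.
3. **Couplings.** One bit per unordered pair of *distinct* non-exchanging
   proton classes connected by a 2-bond (geminal) or 3-bond (vicinal)
   path; paths may traverse any heavy atom (amide H-N-C-H couplings
   count). Couplings within a class and ≥ 4-bond couplings never count.
4. **COSY.** One theoretical cross-peak per counted coupling; the identity
   n_cosy = n_couplings is enforced structurally. Long-range COSY peaks
   are evidence, not bits.
5. **HSQC.** One bit per (proton class, carbon orbit) pair, where carbon
   orbits are constitutional symmetry classes: diastereotopic CH₂ protons
   give two peaks on one carbon, symmetry-equivalent carbons give one peak
   (succinate: one HSQC bit for four protons on two carbons). The count
   reflects the number of peaks visible in a spectrum.
6. **HMBC.** One bit per (carbon orbit, proton class) pair linked by a 2-
   or 3-bond C→H path. Cross-peaks between pseudo-equivalent groups are
   real (the methyls of trimethylamine) and count once per orbit pair;
   pairs whose only relationship is the 1-bond HSQC pairing do not count.
7. **Second-order flag.** Set when a class contains protons that are
   chemically equivalent but magnetically inequivalent *by topology*: two
   members sit at unequal coupling distance (2-3 bonds vs more) from some
   proton outside the class — the AA′BB′ pattern of mono- and
   para-substituted benzenes. Second-order behaviour caused by accidental
   shift proximity (e.g. X-CH₂-CH₂-Y systems whose inequivalence is purely
   a J-difference, or strongly-coupled AB pairs) is out of scope for a
   shift-free counter.
8. **Anomers.** For sugars observed as an anomeric equilibrium the feature
   counts are summed over both anomers, but the MICE/MIE denominators
   always come from a single form (fucose: 12 shifts over two anomers,
   6 carbons).

## Proton equivalence (topicity)

Two hydrogens share a resonance when they are homotopic or enantiotopic;
diastereotopic hydrogens are split. The decision procedure is the
substitution test: replace each hydrogen by a test label and compare
labelled structures — equivalent iff identical or enantiomeric. Because
labelling one CH₂ proton can configure *several* new stereocentres at once
(citric acid configures the substituted carbon *and* the central carbon),
the labelled stereoisomer is not derivable from the connection table
alone. The test therefore runs on one embedded 3D conformer (ETKDG, fixed
seed): the label is applied in place, configurations are read back from
the coordinates, and the enantiomer comparison inverts every tetrahedral
tag (reflection preserves cis/trans). Tetrahedral configuration is
conformation-independent, so any successful embedding gives the same
partition. Constitutional symmetry classes (canonical ranks) prune the
pairwise tests; a brute-force all-pairs oracle with its own embedding and
label re-implementation checks the partition on every cohort molecule of
≤ 14 heavy atoms in the test suite.

Stereocentre counting (feature 7, the chiral/non-chiral partition) uses
tetrahedral *carbon* centres only, assigned or unassigned; anomeric
carbons count, double-bond stereo and stereogenic S/N do not.

## The cohort fixture

75 urinary metabolites curated from the published common/IUPAC names into
SMILES (10 compound classes; 24 chiral / 51 non-chiral; 1–13 carbons;
nominal mass 31–284 Da, mean 126.7 ± 46.6). d-Xylose, l-fucose and
d-glucose carry both anomeric forms. Isovaleric acid is modeled as
3-methylbutanoic acid (the common name is authoritative over a
printed-table inconsistency, and it is the reading consistent with the
cohort's chiral count). Allantoin ships a curated override profile
(1 shift, 1 multiplicity, 1 HSQC, 3 HMBC, nothing else): its four amide-
type N-H would be counted by the structural rule, but the compound shows a
single singlet and a theoretical MIE below 0.5, so the curated count is
authoritative for the shipped set. The fixture file is checksummed;
`load_fixture` refuses a modified table.

Cohort aggregates computed by this counter agree closely with the
published manual counts (theoretical totals 692/855/1102/1855 vs
688/849/1099/1824 across the four levels; identical minima and 1D
maximum). Residual differences trace to manual judgments the published
rules do not pin down — which amide/urea N-H were counted, which AA′BB′
systems were flagged — and are surfaced by `soft_report` as an
informational per-metabolite diff rather than asserted.

## Observed data and scoring

Observed feature sets are schema-validated JSON: shifts with assignment
labels, multiplicity labels, couplings in Hz, COSY/HSQC/HMBC peak lists,
and evidence items (long-range COSY, long-range or heteronuclear
couplings, literature notes). Tallying deduplicates peak lists, counts a
multiplicity bit only when a label was actually read, and never counts
evidence items as bits. `validate_vs_theory` warns when any observed count
exceeds the theoretical one.

Reference matching pairs values by assignment label under the published
tolerances (±0.03 ppm ¹H, ±0.5 ppm ¹³C, ±0.2 Hz J); boundary values pass,
with a relative epsilon so printed-precision equality survives binary
floating point. A nearest-value mode exists for unassigned peak lists and
is documented as a heuristic. Coverage is the fraction of named molecular
fragments (sets of assignment labels; default: the whole molecule) touched
by at least one observed bit.

The confidence call, made at the 1D+COSY+HSQC level, is confident iff the
match passed AND coverage is complete AND (MICE ≥ 1 OR MIE > 0.5 OR ≥ 1
HSQC/HMBC peak OR diagnostic evidence present). The OR-combination
reproduces every published adjudication of the thirteen low-score
metabolites (three putative: methylsuccinic acid for lack of any backup
data, N-propionylglycine likewise, l-carnitine for missing carboxylate
coverage); thresholds are configurable because the published "and/or"
phrasing leaves the exact combination open.

Reported values round half away from zero to one decimal (0.75 → 0.8,
0.375 → 0.4); raw values are kept internally.

## Retention simulator

`RetentionModel` retains each theoretical bit independently with a
per-family probability: shift/multiplicity 0.68, coupling/COSY 0.58, HSQC
0.52, HMBC 0.11 — the cohort-wide observed/theoretical ratios of the
study (the steep HMBC drop reflects the difficulty of acquiring HMBC on
low-abundance metabolites). A multiplicity bit survives exactly when its
resonance's shift bit does: a multiplet cannot be read off an unobserved
signal, and the family probability is defined as the marginal retention.
Draws are seeded per (seed, metabolite id) and byte-reproducible. The
simulator treats bits independently — it does not model chemical-shift
crowding, which in real spectra correlates losses within a region; a
crowding extension is a documented non-goal. Simulated ppm/Hz values are
placeholders; only counts and assignment structure are meaningful. With
default probabilities the simulated cohort totals stay within ±10% (in
practice ±7%) of the study's observed totals over 20 seeds.

## Statistics

Group comparisons are two-tailed unpaired t-tests; both Welch
(unequal-variance, the reported default) and Student conventions are
computed because the study's spreadsheet provenance leaves the variant
ambiguous. Both agree that chiral metabolites carry significantly more
information per carbon than non-chiral ones at the 1D+COSY+HSQC level
(p < 0.05); only the direction and the 0.05 threshold are asserted. Two
zero-variance groups with equal means return p = 1 by convention.
Cohort aggregation sorts values first so statistics are bit-identical
under input permutation; the sample SD of a single value is reported as 0.

## Problem sizes and determinism

Everything is exact counting on graphs; the full cohort profiles in about
a second. The test suite runs the 75-molecule topicity oracle, 20-seed
simulation totals and 40-seed MIHF convergence checks in a few seconds
total. The only randomness anywhere is the seeded retention simulator and
the fixed-seed conformer embedding; identical inputs, seed and
configuration give byte-identical outputs (reports embed the tool
version, a configuration hash and the fixture checksum).

## Known limitations

* Second-order detection is topological only; conformation- or
  shift-proximity-driven second-order effects are not flagged.
* Theoretical HMBC counts enumerate every 2-/3-bond orbit pair; manual
  counts in the literature are sometimes more conservative, which is the
  largest contributor to the +1.7% cohort total difference at the HMBC
  level.
* Exchangeability is structural; borderline cases (lactam and urea N-H in
  fast exchange) may need per-metabolite overrides.
* The simulator's independence assumption understates the variance that
  spectral crowding induces in real studies.
* Reference self-consistency checking is limited to duplicate-assignment
  detection; database misannotations must be caught by the analyst.
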