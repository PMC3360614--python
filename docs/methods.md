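# Methods

This note documents the models, parameters and design choices behind
`mirest`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what the tests
do and do not demonstrate.

## Homology scan

ESTs are single-pass cDNA reads, so the scan is deliberately simple:
pure Hamming comparison of every reference-length window on both strands,
no indels, no seed-and-extend heuristics.  The mismatch bound defaults to
5 *inclusive* (`max_mm = 5`); it is a config knob because the two natural
readings of "about five mismatches" (≤ 5 vs < 5) differ by one.  `N`
bases (draft-quality calls) never match anything.  Both strands are
scanned because 5'-single-pass clones can be reversed relative to the
transcript; the strand is reported.  Within one reference and strand,
overlapping hit runs collapse to the local-minimum-mismatch hit, with the
leftmost-in-scan-orientation tie-break applied in strand-local
coordinates — this is what makes the hit set exactly mirror-symmetric
under reverse complement, a property the test suite checks.  Hits of
different references are deduplicated by (EST, coordinates, strand).

Window extraction places the mature region at three positions (5' arm,
center, 3' arm) inside a 100 nt window, because a genuine mature miRNA
sits in one arm of its hairpin and the flanking-region description
("approximately 100 bp") does not fix the placement.  Downstream folding
keeps whichever placement folds best, so the multiplicity costs compute
time, not specificity.

## Hairpin thermodynamics

Pre-miRNA validation only asks whether a window forms one classical
stem-loop, so the structure space is restricted to *single hairpins*: a
nested chain of pairs closed by one terminal loop of ≥ 3 nt — no
multiloops, no pseudoknots.  This restriction is what makes an exact
brute-force oracle feasible: `enumerate_structures` scores every chain in
the same space with the same terms, and the test suite requires exact
agreement with the dynamic program on hundreds of random short sequences.

The energy model is a nearest-neighbor table at 37 °C stored as package
data (`data/nn_params.yaml`): Watson–Crick stack free energies from the
standard published set, G·U wobble stacks from the published wobble
extension, hairpin/bulge/internal-loop initiation by length with
Jacobson–Stockmayer extrapolation beyond the tables, and a capped
asymmetry penalty for internal loops.  Deliberate simplifications, all
stated rather than silent: no terminal-mismatch or dangling-end bonuses,
no stack across single-nucleotide bulges, no AU/GU helix-end penalties,
no temperature dependence.  These shift absolute ΔG by a few tenths of a
kcal/mol relative to full-featured folders; a sanity test checks that our
restricted-space minimum never drops meaningfully below an unrestricted
folder's minimum on the same sequence.  The interior-loop span between
consecutive stem pairs is capped at 30 nt (the folding field's standard
cap).

### Filter criteria

A folded candidate passes when all of the following hold, and every
failed criterion is recorded by name (so relaxing any threshold provably
never shrinks the passing set — a tested property):

| criterion | default | meaning |
|---|---|---|
| `free_energy` | ΔG ≤ −20 kcal/mol | hairpin stability threshold |
| `stem_loop` | ≥ 14 stem pairs | a real helix, not a hairpin fragment |
| `mature_in_arm` | ≤ 4 nt outside the arm | mature must not straddle the loop |
| `mature_paired` | ≥ 60 % of mature bases paired | Drosha/Dicer-like duplex geometry |
| `gc_content` | 0.20–0.80 | composition band of genuine precursors |
| `ch_ratio` | ≥ 0.8 | core energy / total energy |

`core_mfe` and `ch_ratio` have no standard published definition, so this
package defines them explicitly: the core is the stem-loop from the
outermost pair that flanks the mature arm inward, its energy is the sum
of the corresponding decomposition terms, and `ch_ratio = core_mfe / ΔG`.
A ratio near 1 means the hairpin's stability comes from the mature-bearing
stem itself rather than from fortuitous flanking pairs.  `min_stem = 14`
is chosen so a typical 22 nt mature can reach 60 % pairing inside the
stem; both are configurable.  When a window has no stem at all, only
`free_energy` and `stem_loop` are reported — the arm, pairing and ratio
criteria are not evaluable without a stem.

Among passing windows of one hit, the lowest-ΔG precursor is selected
(ties: smaller window start).  Clusters require the same strand because
polycistronic pri-miRNAs are single transcripts; overlapping accepted
matures (family siblings matching one locus) are merged into one locus
first, so cluster spacers are always non-negative.

## Families and identity

A family key is the numeric core of the name (letters and copy suffixes
collapse; species prefixes are ignored).  "let" names keep a `let-`
marker in the key so let-7 can never merge with miR-7 — the packaged
catalogue contains no let entries, so this affects only external inputs.
Pairwise identity is ungapped sliding of the shorter sequence over the
longer with overhangs allowed (minimum overlap one base), reported as
best matches / shorter length.  It is intentionally *not* a gapped
aligner: published homologue-similarity figures depend on a historical
reference set and are not reproduced here.

## Expression profiling

Relative expression is log10(miRNA/U6 snRNA) per sample, clamped to
[−3, 3] for display (a zero band clamps to −3).  Fold classes follow the
published bins — high > 2×, moderate 0.1–1×, very low < 0.01× — and the
two gaps those bins leave, (0.01, 0.1) and (1, 2], get an explicit
`intermediate` label rather than a silent assignment.  The per-miRNA
class is computed from the row maximum over samples by default (a single
pooled-RNA column behaves identically); the reference column is
configurable because the original description does not say which column
the headline class calls used.  Row clustering is average linkage on
1 − Pearson correlation of the clamped profiles, emulating the classic
Cluster/TreeView defaults; rows are pre-sorted by name, making the leaf
order permutation-invariant and fully deterministic.  A constant row has
undefined correlation and is placed at distance 1 from everything, with a
warning.  The test suite validates merge heights against an independent
O(n³) average-linkage implementation.

## Target prediction

**Class I** is defined here as a canonical animal seed site: the UTR
contains the exact Watson–Crick reverse complement of mature positions
2–8 (G·U is not accepted in the seed), and the duplex of the *full*
miRNA against the surrounding UTR window must be below −20 kcal/mol.
This is a documented stand-in for external seed-site programs run with
default parameters; it is reproducible from first principles, which those
programs are not.

**Class II** hybridizes the 3'-region fragment — 1-based positions 12
through x−2 of an x nt mature, read literally from the printed rule — and
keeps genes whose best duplex is below −20 kcal/mol.  The duplex search
is a local intermolecular DP over the whole UTR with per-side unpaired
gaps capped at 10 nt; because the fragment is short, any duplex the DP
can form spans at most fragment length + gap cap nucleotides of the UTR,
which makes the whole-UTR DP equivalent to sliding a fragment+10 window
at single-nucleotide steps and keeping each gene's best window — the
windowed description, implemented without the quadratic cost.  Counting
is per gene (best site only).  Whether the original analysis hybridized
the fragment alone or the full miRNA anchored at the fragment is
ambiguous; fragment-only is the default (`class2_mode = "fragment"`),
full-miRNA via config.

A consequence worth stating: with realistic nearest-neighbor energies, a
short AU-rich fragment physically cannot reach −20 kcal/mol (a 4 nt
fragment has at most 3 stacks), so Class II calls concentrate on long,
GC-rich matures.  The tests exercise recovery with sli-miR-3242, whose
13 nt GC-rich fragment does cross the threshold.

The duplex energy is symmetric under strand exchange, ΔG(a,b) = ΔG(b,a):
rotating the duplex 180° swaps the strands without changing any stack
motif, and the packaged stack table carries exactly that rotational
symmetry.  It is *not* symmetric under reversing both sequences — that
operation reflects the duplex and maps each stack onto a chemically
different motif — and no direction-dependent nearest-neighbor table can
make it so.  The property test asserts the exchange symmetry.

**Initiation.** The duplex initiation penalty is a single constant in the
parameter table (+4.09 kcal/mol, the standard bimolecular initiation);
with it, a lone base pair is never net-stabilizing.

## Synthetic data

The generators define the study conditions for all full-pipeline tests:

* **Precursor constructs** are mature arm + random loop (8–12 nt) +
  reverse complement of the mature carrying 2–4 planted G·U wobbles
  (mismatches where no wobble is possible) + random flanks to ~100 nt.
  Every construct is self-checked: the unmutated form must pass the
  default filters, regenerating up to a bounded number of attempts.
  Requested mutations are applied to the mature copy afterwards, so a
  6-mutation plant escapes the 5-mismatch scan by construction.
* **EST datasets** embed one construct per selected reference in random
  background ESTs of 300–900 nt at 0.42 GC (typical lepidopteran
  transcript composition; the value only affects decoy difficulty), plus
  pure-background decoys.  The acceptance-level condition is 20 planted
  precursors among 200 decoys.
* **UTR sets** are random 200–1500 nt sequences with non-overlapping
  planted reverse-complement sites (full mature for Class I, fragment
  for Class II).
* **Intensity tables** realize intended fold classes with representative
  ratios (5, 0.5, 0.005, 1.5) times a constant 1000-unit control, under
  mean-one lognormal noise of chosen CV.

All generators are pure functions of (parameters, seed); determinism is
byte-exact and tested.  Recovery scoring counts a planted precursor as
found when an accepted window overlaps it by ≥ 50 % of the planted length
(window placement is heuristic, exact coordinates would be brittle), and
a decoy as falsely accepted when any accepted candidate lies on it.

**What passing these tests shows — and does not.**  The synthetic
background is i.i.d. random sequence: it contains no repeats, no
poly-A tails, no vector contamination, no sequencing-error structure and
no genuinely transcribed non-miRNA hairpins, all of which inflate false
positives on real ESTs.  Planted precursors are built to pass the
filters, so sensitivity on them measures the pipeline's internal
consistency (scan → window → fold → filter), not discovery power on
diverged real precursors.  The observed ~2 % decoy false-accept rate is
a floor, not an estimate for real libraries.

## Problem sizes and determinism

The test suite folds hundreds of windows and runs ten full synthetic
datasets (20 planted / 200 decoys each); the acceptance script runs three
datasets derived from its `--seed` — sizes chosen so a complete
verification runs in about a minute on one CPU while still pooling enough
planted precursors (60) for stable recovery estimates.  Every stage is
deterministic given config and seed; subcommands log a hash of their
configuration.

## Known limitations and open points

* The historical discovery counts of the original EST study (1,132 ESTs →
  90 homologous → 58 validated) depend on unpublished libraries and a
  historical reference release; they are not reproducible and are not
  claimed.  The packaged catalogue and target-count tables are the
  in-study data this package does reproduce (58 records → 46 families;
  211 targets = 189 Class I + 22 Class II).
* The source tables carry two internal oddities, preserved as printed:
  one mature name appears twice with different sequences (both rows are
  kept), and the study's own summary elsewhere cites 128 target genes
  against the table's 211 (only the table arithmetic is reproduced).
* The folding model is an MFE model: no partition function, no ensemble
  diversity, no suboptimal structures.
* Gapped homology (indels) is out of scope by design; a diverged miRNA
  with an indel relative to every reference will be missed.
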