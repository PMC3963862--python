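# Methods

its1kit reimplements, as one coherent library, the sequence-structure
analysis pipeline used to establish the three-helix common core of the
anaerobic-fungal ITS1: HMM-based delineation of the spacer, energy
minimization with a motif-guided helix-wise rescue, core classification,
12-letter sequence-structure alignment, distance-based treeing with
(Profile-)Neighbor-Joining, and compensatory base change (CBC) analysis.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## ITS1 delineation by profile HMMs

The ITS1 spacer is bounded by the highly conserved 3' terminus of the 18S
rRNA gene and 5' terminus of the 5.8S rRNA gene.  Each terminus is
modelled by an ungapped-core profile HMM built from a small alignment:
columns with more than 50% gaps become insert columns; match emissions and
the seven transition probabilities (M→M/I/D, I→I/M, D→D/M) are estimated
with a pseudocount (default 0.1 — the training alignments have tens of
rows and need smoothing).  Scanning is local Viterbi in log2-odds space
with uniform entry/exit over match states (Plan7-style); multiple hits are
extracted greedily best-first with non-overlap, ties resolving to the
leftmost start.

E-values come from seeded Monte-Carlo calibration: the best-hit scores of
i.i.d. background decoys (default 1000 decoys of 100 nt) are fitted by a
Gumbel distribution via maximum likelihood, and
`E = n_targets * exp(-lambda * (score - mu))`, clipped to `[0, n_targets]`.
Absolute E-values therefore depend on the decoy ensemble, but the rank
order of hits does not.  The working annotation mode uses 10-nt terminal
models at E ≤ 0.1 (many database records barely reach into the rRNA
genes); 25-nt models at E ≤ 0.001 are retained for comparison.  The ITS1
span is `[hit18S.end, hit58S.start)` — both matched termini excluded, all
API coordinates 0-based half-open.  When several hits tie, the 18S hit
closest to the spacer (rightmost) and the 5.8S hit closest to it
(leftmost) are taken, since the biological motifs border the spacer.

## Folding model

Secondary structures are predicted by Zuker-style dynamic programming
under a reduced nearest-neighbour model declared in `its1kit.energy`
(kcal/mol, fixed 37 °C set):

- a symmetric 6×6 pair-on-pair stacking table over {AU, UA, GC, CG, GU,
  UG} (GC/CG stacks strongest at −2.9…−3.4, AU/UA intermediate, GU wobble
  weakest);
- tabulated hairpin (≥ 3 unpaired), bulge and internal-loop initiation
  penalties with Jacobson–Stockmayer `1.75·RT·ln(l/l0)` extrapolation, plus
  a linear internal-loop asymmetry term (0.6/nt, capped at 3.0);
- an affine multiloop penalty (closure 3.4, 0.4 per branch, 0.1 per
  unpaired base);
- interior loops capped at 30 unpaired bases (the standard restriction);
- letters outside ACGU never pair.

Dangles, terminal mismatches, coaxial stacking and special hairpin
bonuses are deliberately omitted: the pipeline's contract is "energy
minimal under the declared model", and the declared model is kept small
enough that exhaustive enumeration of all nested structures of short
sequences is a practical independent oracle (the test suite and the
acceptance script verify DP = enumeration on hundreds of random
sequences).  The same loop decomposition is used by the folder and by the
standalone structure evaluator, `energy_of_structure`.

Traceback is deterministic with a fixed preference order — stacked pair,
then interior loop, then multiloop, then hairpin, and in the exterior loop
pairing with the leftmost opening — which realizes a "prefer stacked
pairs" policy locally.  Identical input always produces an identical
dot-bracket; the global lexicographic minimization of the dot-bracket
among co-optimal structures is not attempted.

## Helix decomposition and the common core

A folded structure is decomposed into its exterior-anchored domains: each
outermost pair and everything nested inside is one helix domain, in
5'→3' order, with the unpaired runs between them.  Helix "length" is the
full domain span in nucleotides (outermost base to its partner,
inclusive), matching how the observed core ranges are stated.  A domain
containing a multiloop (a Y-shaped helix) still counts as one domain but
carries a flag, so both readings of ambiguous shapes stay available.

The common-core classifier requires exactly three domains with helix I
span 12–35 nt, helix II 115–201 nt, helix III 8–23 nt, and inter-helix
runs 15–28 and 10–29 nt.  Violations are reported by name, and relaxing
any range is monotone (can only turn non-core into core).

## Helix-wise (divide-and-conquer) folding

Two conserved motifs open and close helix II.  When direct folding fails
the core classifier, the sequence is cut at `motifI.start` and
`motifII.end` (the default of three cut conventions; the alternatives
`motif_midpoints` and `motif_end_start` are selectable), each of the three
domains is folded independently, and the dot-brackets are concatenated.
No pair can cross a cut, the total energy is the sum of domain energies,
and the concatenated structure is re-classified.  The pipeline verdict is
`direct`, `helixwise`, or `failed` with the fewer-violations structure
attached.  Motif hits require E ≤ 0.001.

The cut convention is the single most consequential interpretation in the
package: motif I is taken to begin helix II and motif II to end it, which
in a stem-loop forces the two motifs to be reverse complements of one
another on the closing stem.  The synthetic generator enforces exactly
that relationship.

## 12-letter alignment

Each folded position is encoded as nucleotide × structural state
(unpaired `.`, paired-left `(`, paired-right `)`), twelve symbols in the
fixed order A., A(, A), C., …, U).  The default 12×12 score matrix is the
additive construction `nuc_term + struct_term` with match 2, mismatch −1,
structure agreement +1, disagreement −1; an arbitrary matrix file can be
loaded instead (the original 4SALE matrix values are not public).  Gaps
are affine: a gap of length g costs `gap_open + g·gap_extend`
(−6, −1 by default), terminal gaps priced like internal ones (a
free-end-gaps switch exists).  Pairwise alignment is Needleman–Wunsch/
Gotoh; progressive alignment builds an NJ guide tree on distances
`1 − score/mean(self-scores)` (ties by record id) and merges profiles
with sum-of-pairs column scoring using the pairwise gap costs.

## Distances and trees

Distances between aligned rows are maximum-likelihood under a general
time reversible model on the 12 states: stationary frequencies are
pseudocount-smoothed observed frequencies, exchangeabilities come from the
symmetrized pairwise substitution counts, and Q is scaled to one expected
substitution per unit time.  The per-pair ML distance maximizes
`Σ_sites log(π_a P(a→b|t))` by bounded scalar optimization
(`t ∈ [1e-8, 10]`, tolerance 1e-10) with `P = exp(Qt)` via a single
eigendecomposition.  Gapped columns are pairwise-deleted — ITS1 alignments
are gap-rich and complete deletion would discard most columns.  Distances
saturate at 10.  The equal-rates special case has the closed form
`jc12(p) = −(11/12)·ln(1 − (12/11)p)`, and the ML distance reproduces it
to 1e-6 under the uniform model (verified in the tests and acceptance
script).

Trees are Saitou–Nei Neighbor Joining with the standard Q-criterion; ties
break on the smallest active index pair; negative branch lengths are
clamped to zero with the deficit moved to the sister edge.  Bootstrap
support is column resampling with per-replicate distance+NJ, reported as
the percentage of replicates containing each original bipartition, with
the figure-style classes open (50–90) and closed (> 90) available as edge
annotations.

Profile Neighbor Joining iterates: NJ + bootstrap; rooted clades (child
subtrees of the current tree) whose bipartition support meets the
threshold (default 70, a ProfDistS-era convention) and which contain at
least two profiles are condensed — maximal disjoint clades first — into
position-wise 12-state frequency profiles (weighted means of their
members).  Distances involving profiles use expected pair counts
`C = Σ_sites f1 ⊗ f2` in the same ML machinery.  Iteration stops when no
new profile forms or `max_iter` is reached, and the final tree expands
profiles back to their stored subtrees, so the leaf set is always
conserved.  Because condensation operates on rooted clades, a supported
bipartition whose "clade side" straddles the root trifurcation is not
condensed in that iteration; it typically becomes condensable after the
next round.  Iteration counts are therefore implementation-specific and
are not comparable across programs.

## CBC counting

For two rows of one alignment, each with its own structure over its own
ungapped positions, a column pair is a *shared pair* when both records
base-pair their residues at exactly those columns (through the gap-aware
position maps) and both pairings are canonical (AU/UA/GC/CG/GU/UG; pairs
involving N or other letters are excluded).  A full CBC changes both
partners, a hemi-CBC exactly one — including the G-only GU↔GC exchange,
which this package counts as hemi.  Counts can be restricted to a
half-open column window; a pair belongs to the window of its 5' column,
so windowed counts over any partition of the columns sum exactly to the
global counts.  Helix-specific windows can be supplied explicitly (the
truncated-alignment workflow) or projected from one record's helix
decomposition through its gap map.

## Synthetic data generator

The generator emulates the study conditions so that every stage is
testable without downloads: a three-helix architecture with spans drawn
uniformly from the core ranges, unpaired central-ring regions, the motif I
consensus opening helix II and its reverse complement closing it, optional
10-nt 18S/5.8S flanks, and an overall AT content targeting the observed
0.79.  The flank and motif consensi shipped with the package are fixed
synthetic stand-ins (the study's real sequences are not distributed here);
they are config-replaceable with real alignments.

Element compositions are drawn by quota (exact base counts per element,
then shuffled), which keeps the realized overall AT fraction within a few
per cent of target on every record.  The AT mass is distributed unevenly,
mirroring the observed element-wise pattern — unpaired regions very
AT-rich and strongly A-biased (A and A cannot pair, which keeps the
central ring unpaired in the MFE fold), stems of the short helices
GC-reinforced (AT ≈ 0.45), the long helix II stem AT-rich (≈ 0.87 outside
the motifs).  Three feasibility choices deviate from a literal reading of
the observed tables, all forced by the reduced energy model:

- helix I and III spans are sampled from [14, 35] and [14, 23] rather
  than down to the classifier's lower bounds 12 and 8 — an isolated
  hairpin of span < ~14 has at most 1–3 stacks and is not MFE-stable, so
  such records could never be recovered;
- short stem-loops use a minimal 4–5 nt loop (keeping ≥ 5 stem pairs) and
  take no GU wobble; wobble pairs (configurable fraction, default 0.08)
  are planted only in the long helix II stem;
- helix III stems are sampled at AT ≈ 0.45 although the observed value is
  ≈ 1.0 — a pure-AU stem of span ≤ 23 is unfoldable without the context
  terms (dangles, terminal mismatches) this model omits.  The overall AT
  target is maintained by making the unpaired regions correspondingly
  AT-richer.

Consequently, passing tests demonstrate that the pipeline recovers the
planted architecture under the declared thermodynamics; they do not
demonstrate performance on real anaerobic-fungal sequences, whose folding
landscape (and UNAFold's full parameter set) is richer.  The generator
also provides `mutate_with_cbcs` (exactly k planted full CBCs on
ground-truth pairs, structure untouched) and `simulate_clade` (evolving a
root record along a random tree under the 12-state model restricted per
site to the four states compatible with the root's structural state, so
all leaves share the root structure).

## Numerical and degenerate-input choices

- Fold DP uses float64 throughout; traceback re-derives choices with an
  absolute tolerance of 1e-6 and the preference order above.
- The Viterbi and fold kernels are numba-compiled; results are identical
  to the pure-Python formulations they implement.
- `jc12` and the ML distance saturate at 10 rather than diverging.
- Empty batches, missing motifs, unannotatable records and too-short
  sequences are encoded as statuses (`missing_18S`, `unannotated`,
  `failed`, …), not exceptions; malformed inputs (length mismatches,
  unbalanced dot-brackets, duplicate ids, asymmetric matrices) raise
  errors naming the offender.
- Problem sizes in the tests and the acceptance script (200-record
  sweeps, 300 folding-oracle sequences, 100 additive matrices, bootstrap
  with tens of replicates on ≤ 12 taxa) are chosen to exercise every code
  path at desk scale with seeded reproducibility.

## Known limitations

- The energy parameters are not UNAFold 3.8.1's, so absolute MFE values
  and helix-count histograms on real data will differ from published
  ones; the pipeline logic (annotation → fold → rescue → classify) is
  faithful.
- E-values are calibration-dependent; only their ordering is comparable
  across runs with different decoy seeds.
- Pseudoknots, suboptimal ensembles, partition-function pair
  probabilities and temperature scanning are out of scope.
- The 12×12 score matrix is a declared default, not the 4SALE original.
- PNJ iteration counts are not comparable to ProfDistS output (different
  condensation details and profile distance formula).
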