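# Methods

## Model

The classifier rests on a single structural regularity: β-barrel outer
membrane proteins contain 8–24 antiparallel membrane-spanning strands
with short connecting loops, so their 3-state secondary-structure
strings compress to long alternations of E elements and short coils.
Globular all-β proteins carry fewer, shorter strands with longer coils;
α-helical proteins (globular or membrane) carry few or no strands.
Comparing *element arrangements* rather than residues makes the
similarity measure insensitive to sequence divergence while remaining
sensitive to strand count, element order and element lengths.

### Element alignment

Elements are maximal runs of one state; an element is never split
during alignment (splitting has been argued not to improve element
alignments, and keeping elements atomic keeps the score interpretable).
The pairing score is

    S(a, b) = w(type_a, type_b) * min(L_a, L_b)

with symmetric weights `w` on unordered type pairs. The default scheme
is the identity scheme — `w(X,X) = 1`, all cross-type weights 0 — the
most conservative choice consistent with the score's bound
`S <= min(L_a, L_b)`. Users following scoring variants that grant coil
partial credit against helix/strand can raise `w(C,H)` / `w(C,E)` via a
config file; weights must stay in [0, 1] so that the normalized score
keeps its [0, 1] range.

The alignment is a global Needleman–Wunsch-style recurrence over
elements,

    F(i,j) = max(F(i-1,j) - g, F(i,j-1) - g, F(i-1,j-1) + S(i,j)),

with gap cost `g = 0` by default, in which case skipping an element is
free and the optimum is the maximum-weight monotone (crossing-free)
matching of elements. With `g = 0` each DP row reduces to a running
maximum and is vectorised; the general `g > 0` path is a plain loop.
Correctness of both paths is pinned against an exhaustive enumeration
over all monotone matchings in the tests.

Normalization divides the total score by the **mean residue length**
`(L_A + L_B) / 2` of the two proteins — residue units, not element
counts, because the total score itself is in residue units. The
resulting `SSEA_Score` lies in [0, 1], equals 1 exactly on
self-alignment, and is symmetric.

Traceback ties break deterministically: diagonal first, then advancing
in the first sequence, then the second. The total score is
tie-independent; only the reported element pairs depend on the order.

### Classification

Against a library with labels OMP / non-OMP,

    Pred_Score = max_{OMP entries} SSEA_Score - max_{non-OMP entries} SSEA_Score,

and the call is OMP iff `Pred_Score` strictly exceeds the threshold
(default 0). Equality at the threshold is a non-OMP call. Arg-max ties
break by library order so output files are reproducible. Both maxima
must exist, hence a library needs at least one entry of each class.
`calibrate` replaces the default cut with the smallest observed
leave-one-out non-OMP score at which the empirical false-positive rate
drops to the requested level — appropriate when a fixed confidence
level (e.g. 99%) matters more than maximal sensitivity.

## Evaluation protocol

Leave-one-out: each library entry in turn is held out and classified
against the remainder. To prevent homology leakage from inflating the
estimate, the remainder is first filtered against the held-out protein;
an entry survives only if it passes **every** enabled stage:

- `identity` — global Needleman–Wunsch identity strictly below
  `identity_max` (default 0.25). Alignment uses BLOSUM62 with affine
  gaps (open 11 / extend 1, the common BLAST-like convention); identity
  is identical columns over alignment length *including gap columns*.
  The 25% cut is sensitive to these conventions, so all of them are
  exposed as parameters.
- `search_evalue` / `profile_evalue` — e-value strictly above
  `evalue_min` (default 0.01), supplied by pluggable hooks because the
  search tools (BLAST, PSI-BLAST with sequence profiles) are external
  programs. A file-based adapter consumes outfmt-6-style TSV. "No hit"
  passes; a hook failure retains the entry with a logged warning
  (fail-open), so a broken search backend cannot silently shrink the
  library and masquerade as stringency. When a requested hook is absent
  the stage is skipped with a prominent log line, reproducing the
  identity-filter-only variant of the protocol.

A held-out protein whose filtered library lost an entire class cannot
be scored; it is recorded with `pred_score = -1` (the floor of the
score range), called non-OMP, and flagged `unpredictable` in the
per-protein report. This is a deliberate, conservative convention —
it depresses sensitivity rather than silently dropping cases — and is a
package choice, not a published one.

Aggregate measures: accuracy, sensitivity, specificity and the Matthews
correlation coefficient from the confusion counts (MCC is the primary
measure for the imbalanced two-class problem; a zero MCC denominator is
defined as 0, the standard convention). The ROC curve sweeps the
threshold α over all distinct observed scores with the same strict
`>` rule as the classifier, so items tied at a threshold change
prediction together; AUC is the trapezoidal area of the rate-scaled
curve and equals the midpoint-tie rank-sum statistic, which the tests
verify independently.

## Synthetic data generator

The generator emulates the topological contrast the method exploits,
not real proteins. Each class is a `TopologyProfile`: terminal coil,
then N core elements separated by coil linkers, all lengths uniform on
per-class ranges:

| class | core | N | core len | linker | label |
|---|---|---|---|---|---|
| omp_barrel | E | 8–24 | 6–14 | 2–6 | OMP |
| all_alpha | H | 4–10 | 10–25 | 3–8 | non-OMP |
| all_beta_globular | E | 4–10 | 3–8 | 5–14 | non-OMP |
| alpha_beta | E/H alternating | 6–12 | 4–12 | 3–8 | non-OMP |
| helical_membrane | H | 6–12 | 15–25 | 2–8 | non-OMP |

The barrel strand-count range is the defining fact of the fold; the
remaining ranges are the package's own fixture choices: membrane-spanning
strands are drawn longer (6–14) than globular-β strands (3–8, with
longer coils), mirroring the real contrast in the discriminative
direction. Uniform lengths are the simplest distribution preserving the
contrast; nothing empirical is claimed for them. Optional per-residue
noise flips a state to a uniformly random other state with probability
`noise` (default 0.02), a crude stand-in for secondary-structure
prediction error. A seed fully determines all output.

Synthetic amino-acid sequences (uniform over the 20 residues, length
matched to the SSE string) are attached so the identity filter can run;
`mutate_sequence` produces seeded point-mutated copies at controlled
identity for boundary tests. These sequences carry no composition
signal whatsoever.

**What passing synthetic tests shows — and does not.** Perfect label
recovery on the noise-free default library (40 barrels, 60 decoys
across the four decoy classes, fixed seed) demonstrates that the
pipeline is wired correctly and that the score separates the intended
topological contrast. It does not demonstrate performance on real
proteins, where secondary-structure prediction errors are correlated
(not i.i.d. flips), strand-length distributions overlap far more, and
homologs blur class boundaries; the published large-scale benchmarks
require external datasets and PSIPRED/PSI-BLAST runs and are outside
this package's tests.

## Numerical choices and degenerate inputs

- Empty secondary-structure strings are rejected at construction
  (normalization would divide by zero downstream).
- `.ss2` parsing takes the state column as authoritative even where it
  disagrees with the probability argmax — the column is the predictor's
  own call.
- DSSP 8→3 reduction maps H,G,I→H; E,B→E; everything else→C. The
  strand-friendly `B→E` choice (conventions differ) suits barrels,
  where isolated bridge residues belong with strands.
- Scores are kept at full floating precision internally; CLI output
  rounds to 3 decimals for display only.
- Traceback equality tests use a small floating tolerance
  (`np.isclose`) to keep pair recovery stable under float addition
  order; totals themselves come straight from the DP table.
- Problem sizes in the test suite (libraries of ~100 entries, strings
  of a few hundred residues, 500–1000 randomized alignment cases) were
  chosen to exercise every code path at desk scale while keeping the
  suite quick to run routinely.

## Known limitations

- A query whose barrel topology is unlike every library OMP will be
  missed — the method is a nearest-neighbour scheme and inherits its
  library's coverage.
- Element alignment discards all amino-acid information; proteins with
  barrel-like predicted topology but non-OMP identity (some all-β
  globular folds) can only be separated by strand count/length
  statistics, not composition.
- The e-value filter stages depend on user-supplied search output; the
  package neither bundles nor reimplements the search tools.
- The default cross-type weights (0) are conservative; no claim is made
  that they are optimal, and the scheme is exposed for exactly that
  reason.
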