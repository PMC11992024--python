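# Methods

## Transcript co-localization score

**Model.** Input is a detected-transcript table from an imaging-based
spatial platform: one row per decoded transcript with gene, planar position
(µm, one global stitched frame per section) and the segmented cell the
transcript falls in. For an ordered pair (source gene A, partner gene B) a
source transcript is *close* to B if at least one B transcript lies at
Euclidean distance strictly below the radius *r* and belongs to a different
cell. The score is

    score(A, B) = 2 · close_count(A, B) / (n_A + n_B)

where `close_count` counts source transcripts with ≥1 close partner (each
source transcript at most once, regardless of how many partners are near).
These counting semantics — source-side uniqueness — are the only reading
under which the unique-interaction rule yields an asymmetric matrix; a
both-directions sum would be symmetric. `score(A, B)` weights A's
participation by the pooled pair abundance; for an equal-count, fully
paired configuration it is exactly 1.

**Parameters.**

| parameter | default | meaning |
|---|---|---|
| `radius` | 30 µm | strict (<) close threshold; a 30 µm disc covers a handful (~5–10) of cells, so the score probes cell-neighbourhood scale |
| `same_cell_exclusion` | on | drop partner transcripts sharing the source's cell: the score is about tissue neighbourhoods, not intracellular co-expression |
| `unassigned_policy` | `singleton` | unassigned transcripts act as their own one-transcript cell (the exclusion is keyed on *sharing* a cell identity); `drop` removes them |
| `include_diagonal` | on | (A, A) entries computed with self-pairing forbidden; flagged in matrix metadata because diagonal semantics differ from off-diagonal pairs |

**Numerical choices.** Scores are NA exactly when `n_A + n_B = 0`. Scores
can exceed 1 when `n_source ≫ n_partner` (every source transcript close,
denominator dominated by the source); they are reported unclamped with a
warning. The matrix is computed with a single fixed-radius k-d tree over
all transcripts (`scipy.spatial.cKDTree.query_pairs`), re-filtering
candidate pairs to the strict inequality because the tree reports ≤ r;
exactness against the all-pairs brute force is asserted in tests on random
instances. Distances are 2-D: sections are thin (~10 µm) relative to the
30 µm radius, and any z column is ignored. Matrix TSVs serialize floats
with 17 significant digits so write→read round-trips are bit-exact.

**Differential matrices.** `differential_matrix(case, control)` is the
elementwise difference with NA propagation; the sign convention
(positive = closer in the case condition) is stored in the output metadata.
Panels and scoring parameters must match exactly. Multiple sections per
condition are combined by pooling interaction and transcript counts before
normalization (default) or by averaging per-section score matrices.

## Synthetic spatial data

`gen_transcripts` emulates the statistical structure the scorer assumes:
per-gene uniform point patterns on a square field, a square cell mosaic
(pitch 20 µm — deterministic and testable, unlike a Voronoi mosaic; a 30 µm
disc covers ≈7 such cells), and planted co-localization for chosen pairs: a
`coupled_fraction` of the second gene's transcripts is re-placed at a
Gaussian offset (`sigma`) from randomly chosen transcripts of the first,
with out-of-field draws rejected and re-drawn so per-gene counts stay
exact. It does not model imaging optics, decoding errors, blank-barcode
misassignment, or segmentation errors — so passing recovery tests
demonstrates the pipeline's statistical behaviour, not robustness to those
artefacts.

**Recovery study conditions.** Planted-signal recovery interacts strongly
with the same-cell exclusion: at σ = 2 µm under a 20 µm mosaic only ~14% of
coupled partners land in a different cell than their anchor, so ~86% of the
planted structure is (correctly) invisible to the score. Recovery therefore
requires a low baseline close-probability. The recovery experiments use a
3 mm field at 200 transcripts per gene (~22 transcripts/gene/mm², a
realistic abundance for a mid-expressed gene in a 500-plex panel), where
the planted differential entry exceeds the 95th percentile of null entries
in 20/20 seeds while null entries stay centred at zero. At 10× higher
density (1 mm field, same counts) the planted signal is not reliably
separable from the baseline — a genuine property of the score, worth
knowing before designing a panel.

## Clonotype classes and sharing

Clonotype identity is the CDR3β amino-acid sequence (paired-chain keys out
of scope). Classes partition positive clone sizes: unique = 1, small = 2–5,
large = 6–30, hyperexpanded ≥ 31. Cells without a recovered TCR are simply
absent from the table and therefore excluded from all denominators. Since
repertoire figures variously count cells or clonotypes per class, both
tallies are emitted. The synthetic generator draws clone sizes from a
geometric law (power-law alternative; neither is a biological claim) and
re-uses a configurable fraction of tumor clonotype keys among liver clones;
the estimated sharing fraction recovers the configured one within binomial
error.

## Neoantigen selection and construct assembly

The consensus filter keeps missense variants, keyed on
(chrom, pos, ref, alt) (1-based, as in VCF), called in ≥3 of exactly 4
datasets after removing variants flagged in the matched germline reference.
Predictor output is consumed as tables — the external epitope predictors
are not re-implemented — and merged with expression; duplicate
(peptide, allele) candidates keep the lower (stronger) predicted affinity,
a tie-break this package defines since combination rules for disagreeing
predictors are genuinely open. Ranking applies hard filters
(affinity ≤ 500 nM, TPM strictly > 0, agretopicity ≥ 1, foreignness ≥ 0 by
default; all configurable) followed by a stable sort: ascending affinity,
then descending TPM, descending foreignness, lexicographic peptide.
The four criteria come with no published weights or thresholds, so the
filter-then-sort policy and its defaults are this package's design; the
500 nM cut-off is the conventional weak-binder bound for MHC-I.

Construct assembly concatenates the selected peptides with a linker
(default `GGSGG`; configurable) optionally downstream of a CD74 leader.
The objective is maximin: each junction is scored by its strongest
(lowest-nM) junction-spanning 8–11-mer — windows not fully contained in
either flanking peptide, linker residues included — and the ordering
maximizes the weakest junction. Up to 6 peptides the optimum is found by
exhaustive search over orders (junction scores are cached per ordered pair,
so 6! evaluations are trivial); beyond that a greedy heuristic starts from
the weakest-binding ordered pair and extends the chain at either end.
Greedy alone cannot guarantee optimality even for 3 peptides, which is why
the small-n path is exact. A deterministic hash-based mock junction scorer
is bundled for tests; real use plugs in an MHC-I predictor.

## Quantifications

* Vector copy number: `2 · c_HIV / c_normalizer` (the normalizer amplicon
  targets a two-copy locus). Undefined at zero normalizer concentration.
* Tumor volume: `x² · y / 2` with x the larger caliper diameter; swapped
  diameters are rejected rather than silently reordered.
* IIT signature: per-sample score = Σ over panel genes of
  log2(expression + offset), offset 1 by default for zero handling (the
  upstream normalization of the expression input is deliberately not
  assumed). Samples strictly above the 50th percentile of scores are
  "high", the rest "low" — median ties go low. Note the operative
  definition is the *sum*; sum and mean differ by the constant factor
  |panel| and give identical strata. With offset 0 on positive expression
  the strata are exactly invariant under any global monotone rescaling
  (every score shifts by the same constant); with a nonzero pseudocount the
  invariance is approximate — sums of shifted logarithms can swap sample
  ranks near the median under extreme rescaling. The shipped panel file
  carries the six signature members named in the study text; the full
  22-gene list is distributed as supplementary material of the originating
  study and should replace the file for real analyses. Survival fitting
  itself (Kaplan–Meier, Cox) is delegated to standard packages;
  `export_strata` emits the joined (sample, score, stratum, time, event)
  table they consume.

## Problem sizes in the test suite

Tests run the full 500-gene × 100-transcripts matrix once (~50k transcripts,
a few seconds via the k-d tree path), 100 random oracle-equivalence
instances of up to 2,000 transcripts, and 20-seed recovery experiments on
12-gene panels — sizes chosen so the whole suite exercises every code path
at full fidelity while remaining quick on a laptop.

## Known limitations

* The scorer assumes one consistent global coordinate frame per section;
  per-FOV coordinate systems must be stitched upstream.
* Diagonal entries mix within-gene dispersion with abundance; compare them
  only with matching parameters.
* The differential matrix carries no significance estimate; planted-signal
  tests use replicate seeds instead of permutation p-values.
* Reproducing any specific published peptide list requires the original
  sequencing data and predictor versions; this package implements the
  selection logic, not the predictors.
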