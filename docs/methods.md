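# Methods

## Conservation scoring

Pairwise conservation is computed from optimal global (Needleman–Wunsch)
alignments with affine gap penalties, via biopython's `PairwiseAligner`.
Defaults: BLOSUM62, gap open −10, gap extend −0.5 (a run of k gaps costs
open + (k−1)·extend; terminal gaps are penalized like internal ones). For
near-identical ortholog panels the optimum is insensitive to these values;
they matter, and are configurable, only for divergent pairs such as the
652-residue fish ortholog versus the 635-residue mammalian protein.

Conventions, fixed once and used everywhere:

* **Identity** = identical columns / *all* alignment columns (gap columns
  included in the denominator). This makes the arithmetic of mismatch
  counts direct: 2 mismatches in a gapless 635-column alignment give
  633/635 = 99.69%.
* **Similarity** = columns whose BLOSUM62 score is positive (identical
  columns count as similar; gap columns as neither). "Similarity" has no
  universal definition; alignment viewers differ, so numbers from other
  tools can differ on divergent pairs even when identity agrees.
* Percentages are rounded half-up, 2 decimals by default.
* Tie-breaking between equally optimal alignments is the aligner's first
  traceback (diagonal preferred, then gap-in-query, then gap-in-reference),
  so output is deterministic.

Insertions relative to the reference are anchored to the preceding
reference position in the difference list. Conservative vs
non-conservative substitution calls use a fixed physicochemical class
table — aliphatic {G,A,V,L,I,P} with branched-chain subset {V,L,I},
aromatic {F,Y,W}, hydroxyl {S,T}, sulfur {C,M}, acidic {D,E}, amide {N,Q},
basic {K,R,H} — with "same class" meaning shared membership in at least one
class. The multiple-alignment view of a panel is reference-anchored
stacking of pairwise alignments; progressive MSA is deliberately out of
scope.

## Phylogeny

Distances are p-distances on percent identity, `d = 1 − identity/100`,
with an optional Poisson correction `−ln(1−p)` (off by default: the panels
of interest sit above 98% identity, where the correction is below the
rounding noise). Trees come from a hand-written Saitou–Nei neighbor
joining: NJ is exact on additive matrices, and writing it ourselves fixes
the tie-break (lexicographically smallest pair of canonical node labels at
equal Q), which library implementations do not expose, so identical inputs
always give identical Newick output. Negative branch lengths — possible on
non-additive input — are clamped to zero with a logged warning. Tests
cross-check topology against scikit-bio's NJ and path lengths against
dendropy's re-parse of the emitted Newick.

## Topology model

The transporter is modeled as an ordered tiling of 1..635 by 25 named
regions: N_TERM, TM1..TM12 with alternating loops (EL1..EL6 extracellular
after odd helices, IL1..IL5 intracellular after even ones, forced by the
cytosolic N-terminus), C_TERM. All coordinates are 1-based inclusive;
boundary residues belong to the region that declares them. The tiling is
input data (TSV: name, start, end), validated on load for coverage, order
and non-overlap.

The packaged default tiling is **synthetic**: the real helix boundaries are
not published alongside the analyses this package reproduces. It uses
~21-residue helices in the style of UniProt TRANSMEM annotation, a long
EL2 (the SLC6 family's large second extracellular loop), and is arranged so
that residue 38 lies in the N-terminus, residues 305–415 cover TM6–TM8, and
residue 491 lies in a helix. Conclusions that depend on exact boundary
placement (a variant near a region edge) should be re-run against a
user-supplied topology file; outputs echo which topology was used.

## Variant interpretation

HGVS p.-notation is parsed with a regex grammar covering missense,
nonsense (`Ter`/`*`), single and range deletions, duplications, and
frameshifts, in one- or three-letter codes. Unparseable rows in a variant
table are rejected with machine-readable reason codes and counted, not
fatal — real database exports contain descriptions outside any grammar.
Finer clinical labels collapse to three bins (benign/likely benign,
pathogenic/likely pathogenic, unknown).

Annotation semantics: non-truncating variants affect the regions their
interval intersects; nonsense and frameshift variants affect everything
from their start to the C-terminus (protein-level consequence only — a
frameshift's novel read-through sequence is not modeled). Each variant's
primary region is its start position's region; multi-region events count
once under that class, with the full region list retained. Two variants at
the same residue are distinct alleles and counted separately. Tally
percentages are rounded to whole percent.

Hotspots: a window (default 111 residues) slides one residue at a time;
windows holding at least `min_count` missense variants qualify, and
overlapping qualifying windows merge into maximal runs reported with their
union span and a recount. The default `min_count` is ceil(2 × the mean
window count) — twice the protein-wide average density — chosen because the
qualitative observation being formalized ("a cluster between roughly
residues 305 and 415") comes with no printed rule; both knobs are exposed.
On the packaged catalog the merged span (280–418) is wider than the
described cluster because merging unions every qualifying window position.

Tolerance scores bin as: [0, 0.5) highly intolerant, [0.5, 0.7) moderately
intolerant, [0.7, 1.0] intermediate, (1.0, ∞) tolerant. The printed ranges
share endpoints; shared points go to the upper bin except 1.0, which stays
intermediate because "tolerant" is stated strictly as >1.0.

## Uptake statistics

Group summaries use the sample SD (n−1). Percent of WT is
`100·mean/WT_mean`; the WT group is 100 by construction. Welch's one-way
ANOVA is implemented from its definition (formula in the README); tests
verify it against pingouin to 6 significant figures and the k = 2 identity
F = t² against scipy's Welch t test. Each group needs n ≥ 2 and nonzero
variance (a zero-variance group makes the weights infinite; callers are
told to jitter or exclude). Technical duplicates are assumed averaged into
one biological replicate before entry — the convention is recorded in the
output header because source data rarely state it.

Per-variant comparisons against WT use Welch two-sample tests without
multiplicity correction by default (matching how per-variant p-values are
conventionally reported in this assay literature); a Holm option exists.
Severity: severe = significant and ≥88% reduction, moderate = significant
below that, unimpaired otherwise, at α = 0.05. The 88% default reflects
the observed split between profoundly impaired and partially active
variants in the motivating data; it is a configurable reporting convention,
not a clinical threshold.

## Synthetic data

The generators exist so every pipeline stage can be exercised and
statistically validated offline.

* **Ortholog panels** (635 residues, 8 species by default): per-residue
  substitution rates by region — termini 0.02, loops 0.01, TM1–TM10 0
  (invariant core), TM11–TM12 0.004 — with 80% of substitutions staying in
  the reference residue's amino-acid class. These defaults emulate the
  observed conservation gradient: divergence in the termini and loops,
  none in the core helices, rare changes confined to the last two.
  The reference sequence is uniform over the 20 amino acids (composition
  affects none of the implemented statistics). Species are drawn
  independently from the reference — no phylogenetically correlated
  process — which suffices for identity/tally recovery but makes the
  resulting trees star-like, a stated simplification. Configurations
  implying >50% expected divergence are rejected.
* **Variant catalogs**: positions sampled by region-class weights (optional
  hotspot interval with an enrichment multiplier), classifications drawn
  per region class (defaults: terminus 0, loop 0.64, TM 0.70 pathogenic).
* **The curated 43-variant catalog** is a deterministic synthetic stand-in
  for a public-database extraction, constructed to have the regional
  composition of interest: 8 terminus (all benign), 25 loop (16
  pathogenic), 10 TM (7 pathogenic, two alleles sharing Cys491), with 17
  variants clustered in residues 305–415.
* **Uptake tables**: truncated-normal (non-negative) replicates per
  genotype around `wt_mean · target/100`, constant coefficient of
  variation `wt_sd/wt_mean` (assay noise scales with signal; with the
  default CV of 12% the truncation bias is negligible). Default targets:
  eight severe variants at 8% of WT, one moderate at 71%, n = 6
  replicates.

All generators use one `numpy` Generator seeded explicitly; identical
configs and seeds give byte-identical output files.

## Validation strategy and problem sizes

Every nontrivial algorithm is checked against an independent oracle:
alignment scores against exhaustive enumeration of all global alignments
(200 random pairs, length ≤ 8); NJ against path lengths on the generating
tree for 100 random additive matrices (4–8 taxa) and against scikit-bio's
topology; Welch ANOVA against pingouin and the t² identity, plus type-I
calibration (rejection rate at α = 0.05 within [0.04, 0.06] over 5,000
null simulations of 3 groups × 6 replicates); hotspot calls against direct
recounts; generator parameters against pipeline-recovered estimates at
n = 10,000 variants and n = 200 replicates. These sizes keep the whole
suite under ~15 s while leaving binomial tolerances tight.

## Known limitations

* Replicate-level uptake measurements behind published percent-reduction
  figures are generally unavailable, so specific printed p-values cannot be
  reproduced; the package covers that territory as threshold behavior of
  the severity classifier instead.
* The similarity convention (positive substitution score) may not match
  other tools' conventions on divergent pairs.
* The default topology's boundaries are approximate (see above).
* No coding-DNA (c.) or splice interpretation; intronic events must be
  supplied as their protein-level consequence.
* No progressive MSA, likelihood phylogenetics, topology prediction or 3-D
  structure handling.
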