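"""Global pairwise protein alignment and conservation scoring.

Percent identity and similarity between transporter orthologs are computed
from optimal Needleman-Wunsch global alignments with affine gap penalties
(BLOSUM62, open -10, extend -0.5 by default).  For the near-identical
mammalian panels this package targets, the optimum is insensitive to these
parameters; they are configurable for divergent pairs such as zebrafish.

Conventions (fixed, documented here once):

* identity denominator = all alignment columns, gap columns included, so a
  gapless 635-column alignment with 2 mismatches gives 633/635 = 99.69%;
* a column is "similar" when both residues are present and their
  substitution-matrix score is positive (identical columns count as both);
* percentages round half-up to the requested number of decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinSequence

GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for global alignment.

    A gap run of length k costs ``gap_open + (k - 1) * gap_extend``
    (both negative, terminal gaps penalized like internal ones).
    """

    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError(
                f"require gap_open <= gap_extend < 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix_name)


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped rows plus the optimal score."""

    ref_id: str
    qry_id: str
    ref_row: str
    qry_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.qry_row):
            raise ValueError("alignment rows differ in length")
        if any(a == GAP and b == GAP for a, b in zip(self.ref_row, self.qry_row)):
            raise ValueError("gap-gap column in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.ref_row)

    def columns(self):
        return zip(self.ref_row, self.qry_row)


class DiffKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


class ClassChange(str, Enum):
    SAME_CLASS = "same_class"
    CLASS_CHANGE = "class_change"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ResidueDifference:
    ref_position: int  # for insertions: the preceding reference position
    ref_aa: str
    qry_aa: str
    kind: DiffKind
    class_change: ClassChange


@dataclass(frozen=True)
class IdentitySimilarityResult:
    identity_pct: float
    similarity_pct: float
    n_columns: int
    n_identical: int
    n_similar: int
    n_gapped_columns: int


# Amino-acid classes used to call conservative vs non-conservative changes
# (physicochemical grouping; V/L/I additionally form the branched-chain
# subset of the aliphatics).  Two residues are "same class" when they share
# membership in at least one class.
AA_CLASSES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("GAVLIP"),
    "branched_chain": frozenset("VLI"),
    "aromatic": frozenset("FYW"),
    "hydroxyl": frozenset("ST"),
    "sulfur": frozenset("CM"),
    "acidic": frozenset("DE"),
    "amide": frozenset("NQ"),
    "basic": frozenset("KRH"),
}

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def classify_aa_change(ref_aa: str, qry_aa: str) -> ClassChange:
    """Conservative (same physicochemical class) or not."""
    for aa in (ref_aa, qry_aa):
        if aa not in _STANDARD_AA:
            raise ValueError(f"not a standard amino acid: {aa!r}")
    for members in AA_CLASSES.values():
        if ref_aa in members and qry_aa in members:
            return ClassChange.SAME_CLASS
    return ClassChange.CLASS_CHANGE


def align_pair(
    ref: ProteinSequence,
    qry: ProteinSequence,
    params: AlignmentParams | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of ``qry`` against ``ref``.

    Ties between equally optimal alignments are broken deterministically
    (first traceback, diagonal preferred over a gap in the query over a gap
    in the reference).
    """
    params = params or AlignmentParams()
    if not ref.residues or not qry.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.matrix()
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    aln = aligner.align(ref.residues, qry.residues)[0]
    ref_row, qry_row = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ref.id, qry.id, ref_row, qry_row, float(aln.score))


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def identity_similarity(
    aln: PairwiseAlignment,
    params: AlignmentParams | None = None,
    rounding_decimals: int = 2,
) -> IdentitySimilarityResult:
    """Percent identity/similarity over all alignment columns."""
    params = params or AlignmentParams()
    matrix = params.matrix()
    n_identical = n_similar = n_gapped = 0
    for a, b in aln.columns():
        if a == GAP or b == GAP:
            n_gapped += 1
            continue
        if a == b:
            n_identical += 1
        if matrix[a, b] > 0:
            n_similar += 1
    n = aln.n_columns
    return IdentitySimilarityResult(
        identity_pct=_round_half_up(100.0 * n_identical / n, rounding_decimals),
        similarity_pct=_round_half_up(100.0 * n_similar / n, rounding_decimals),
        n_columns=n,
        n_identical=n_identical,
        n_similar=n_similar,
        n_gapped_columns=n_gapped,
    )


def enumerate_differences(aln: PairwiseAlignment) -> list[ResidueDifference]:
    """One record per non-identical column, in reference coordinates.

    Insertions (gap in the reference row) are anchored to the preceding
    reference position (0 if at the very start).
    """
    diffs: list[ResidueDifference] = []
    ref_pos = 0
    for a, b in aln.columns():
        if a != GAP:
            ref_pos += 1
        if a == b:
            continue
        if a == GAP:
            diffs.append(
                ResidueDifference(ref_pos, GAP, b, DiffKind.INSERTION,
                                  ClassChange.NOT_APPLICABLE)
            )
        elif b == GAP:
            diffs.append(
                ResidueDifference(ref_pos, a, GAP, DiffKind.DELETION,
                                  ClassChange.NOT_APPLICABLE)
            )
        else:
            try:
                cc = classify_aa_change(a, b)
            except ValueError:
                cc = ClassChange.NOT_APPLICABLE
            diffs.append(ResidueDifference(ref_pos, a, b, DiffKind.SUBSTITUTION, cc))
    return diffs


@dataclass
class ConservationReport:
    """Per-species identity/similarity plus difference lists for a panel."""

    reference_id: str
    alignments: dict[str, PairwiseAlignment] = field(default_factory=dict)
    stats: dict[str, IdentitySimilarityResult] = field(default_factory=dict)
    differences: dict[str, list[ResidueDifference]] = field(default_factory=dict)


def conservation_scan(panel, params: AlignmentParams | None = None) -> ConservationReport:
    """Align every non-reference species to the reference and score it."""
    params = params or AlignmentParams()
    report = ConservationReport(panel.reference_id)
    ref = panel.reference
    for qry in panel.queries:
        aln = align_pair(ref, qry, params)
        report.alignments[qry.id] = aln
        report.stats[qry.id] = identity_similarity(aln, params)
        report.differences[qry.id] = enumerate_differences(aln)
    return report
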