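"""Protein-level variant interpretation against the transporter topology.

Parses HGVS p.-notation (missense, nonsense, deletion, duplication,
frameshift; one- or three-letter codes), annotates each variant with the
topology regions it affects — truncating variants lose everything from
their start position to the C-terminus — tallies benign/pathogenic counts
per region class, detects missense hotspots with a sliding window, and bins
per-residue missense-tolerance scores on the four-category scale
(<0.5 highly intolerant; 0.5–0.7 moderately intolerant; 0.7–1.0
intermediate; >1.0 tolerant).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum

from .io_formats import Classification, VariantTableRow
from .topology import Region, RegionClass, TopologyModel, region_class

# ---------------------------------------------------------------------------
# HGVS p.-notation parsing

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1 = set(AA3_TO_1.values())


class VariantKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    FRAMESHIFT = "frameshift"


class HgvsParseError(ValueError):
    """Unparseable or unsupported HGVS p. string."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class VariantDescriptor:
    kind: VariantKind
    start: int
    end: int
    ref_aa: str
    alt_aa: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")
        if self.kind is VariantKind.MISSENSE and self.ref_aa == self.alt_aa:
            raise ValueError("missense with identical ref and alt")

    @property
    def truncating(self) -> bool:
        return self.kind in (VariantKind.NONSENSE, VariantKind.FRAMESHIFT)


_AA_TOKEN = r"(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|[ACDEFGHIKLMNPQRSTVWY])"
_POS = rf"({_AA_TOKEN})(\d+)"

_RE_FS = re.compile(rf"^{_POS}(?:{_AA_TOKEN})?fs(?:\*\d+|Ter\d+)?$")
_RE_NONSENSE = re.compile(rf"^{_POS}(?:Ter|\*)$")
_RE_DEL_DUP = re.compile(rf"^{_POS}(?:_{_POS})?(del|dup)$")
_RE_MISSENSE = re.compile(rf"^{_POS}({_AA_TOKEN})$")


def _aa1(token: str) -> str:
    return AA3_TO_1.get(token, token)


def parse_hgvs_p(text: str) -> VariantDescriptor:
    """Parse an HGVS protein-level variant description.

    Supported forms (one- or three-letter amino-acid codes): missense
    ``p.Pro544Leu``; nonsense ``p.Trp107Ter`` / ``p.W107*``; deletion
    ``p.Gly132del`` and ranges ``p.Val398_Pro401del``; duplication
    ``p.Met235dup`` and ranges; frameshift ``p.Asn336Lysfs*11`` /
    ``p.N336fs``.  Optional enclosing parentheses are accepted.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsParseError("empty", "empty HGVS string")
    s = text.strip()
    if not s.startswith("p."):
        raise HgvsParseError("no_p_prefix", f"{text!r}: missing 'p.' prefix")
    body = s[2:]
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]

    m = _RE_FS.match(body)
    if m:
        pos = int(m.group(2))
        return VariantDescriptor(VariantKind.FRAMESHIFT, pos, pos, _aa1(m.group(1)))
    m = _RE_NONSENSE.match(body)
    if m:
        pos = int(m.group(2))
        return VariantDescriptor(VariantKind.NONSENSE, pos, pos, _aa1(m.group(1)), "*")
    m = _RE_DEL_DUP.match(body)
    if m:
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        if end < start:
            raise HgvsParseError("bad_range", f"{text!r}: range end before start")
        kind = VariantKind.DELETION if m.group(5) == "del" else VariantKind.DUPLICATION
        ref = _aa1(m.group(1)) if end == start else _aa1(m.group(1)) + _aa1(m.group(3))
        return VariantDescriptor(kind, start, end, ref)
    m = _RE_MISSENSE.match(body)
    if m:
        ref, alt = _aa1(m.group(1)), _aa1(m.group(3))
        if ref == alt:
            raise HgvsParseError("synonymous", f"{text!r}: ref and alt identical")
        pos = int(m.group(2))
        return VariantDescriptor(VariantKind.MISSENSE, pos, pos, ref, alt)
    raise HgvsParseError("unsupported", f"unsupported HGVS p. notation: {text!r}")


# ---------------------------------------------------------------------------
# Region annotation

@dataclass(frozen=True)
class AnnotatedVariant:
    descriptor: VariantDescriptor
    classification: Classification
    affected_regions: tuple[str, ...]
    primary_region_class: RegionClass
    hgvs_p: str = ""


def annotate_variant(
    descriptor: VariantDescriptor,
    classification: Classification,
    model: TopologyModel,
    hgvs_p: str = "",
) -> AnnotatedVariant:
    """Attach the affected topology regions to a variant.

    Truncating variants (nonsense, frameshift) affect every region from
    their start through the C-terminus; others affect the regions their
    interval intersects.  The primary region class comes from the start
    position.
    """
    if descriptor.end > model.protein_length:
        raise ValueError(
            f"variant interval [{descriptor.start}, {descriptor.end}] beyond "
            f"protein length {model.protein_length}"
        )
    end = model.protein_length if descriptor.truncating else descriptor.end
    regions = model.regions_in_interval(descriptor.start, end)
    return AnnotatedVariant(
        descriptor=descriptor,
        classification=classification,
        affected_regions=tuple(r.name for r in regions),
        primary_region_class=region_class(model.region_of(descriptor.start)),
        hgvs_p=hgvs_p,
    )


def annotate_table(rows: list[VariantTableRow], model: TopologyModel) -> list[AnnotatedVariant]:
    return [
        annotate_variant(parse_hgvs_p(r.hgvs_p), r.classification, model, r.hgvs_p)
        for r in rows
    ]


# ---------------------------------------------------------------------------
# Regional pathogenicity tallies

@dataclass(frozen=True)
class ClassTally:
    benign: int
    pathogenic: int
    unknown: int

    @property
    def total(self) -> int:
        # unknowns are tallied separately from the benign/pathogenic split
        return self.benign + self.pathogenic

    @property
    def pathogenic_pct(self) -> float | None:
        """Whole-percent pathogenic fraction; None when no classified variants."""
        if self.total == 0:
            return None
        return round(100.0 * self.pathogenic / self.total)

    @property
    def benign_pct(self) -> float | None:
        if self.total == 0:
            return None
        return round(100.0 * self.benign / self.total)


@dataclass
class RegionTally:
    by_class: dict[RegionClass, ClassTally]
    n_variants: int


def tally_by_region_class(
    variants: list[AnnotatedVariant], missense_only: bool = False
) -> RegionTally:
    """Benign/pathogenic counts and whole-percent fractions per region class
    (terminus / loop / tm), each variant counted once under its primary
    region."""
    counts = {rc: {"benign": 0, "pathogenic": 0, "unknown": 0} for rc in RegionClass}
    n = 0
    for v in variants:
        if missense_only and v.descriptor.kind is not VariantKind.MISSENSE:
            continue
        n += 1
        bucket = counts[v.primary_region_class]
        if v.classification is Classification.BENIGN:
            bucket["benign"] += 1
        elif v.classification is Classification.PATHOGENIC:
            bucket["pathogenic"] += 1
        else:
            bucket["unknown"] += 1
    return RegionTally(
        by_class={rc: ClassTally(**c) for rc, c in counts.items()},
        n_variants=n,
    )


# ---------------------------------------------------------------------------
# Hotspot detection

@dataclass(frozen=True)
class HotspotWindow:
    start: int
    end: int
    variant_count: int

    @property
    def density(self) -> float:
        return self.variant_count / (self.end - self.start + 1)


def detect_hotspots(
    variants: list[AnnotatedVariant],
    protein_length: int,
    window_size: int = 111,
    min_count: int | None = None,
) -> list[HotspotWindow]:
    """Sliding-window missense hotspot calls.

    A window of ``window_size`` residues slides one residue at a time over
    the protein; windows holding at least ``min_count`` missense variants
    (by start position) qualify, and overlapping/adjacent qualifying
    windows are merged into maximal runs reported with their union span and
    a recount over that span.  When ``min_count`` is None it defaults to
    ``ceil(2 * mean window count)`` — twice the protein-wide average — so
    only genuinely enriched stretches qualify.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    positions = sorted(
        v.descriptor.start
        for v in variants
        if v.descriptor.kind is VariantKind.MISSENSE
    )
    if not positions:
        return []
    window_size = min(window_size, protein_length)
    starts = range(1, protein_length - window_size + 2)

    def count_in(lo: int, hi: int) -> int:
        import bisect

        return bisect.bisect_right(positions, hi) - bisect.bisect_left(positions, lo)

    window_counts = [count_in(s, s + window_size - 1) for s in starts]
    if min_count is None:
        mean = sum(window_counts) / len(window_counts)
        min_count = max(1, math.ceil(2.0 * mean))

    hotspots: list[HotspotWindow] = []
    run_start: int | None = None
    prev_end = 0
    for s, c in zip(starts, window_counts):
        if c >= min_count:
            if run_start is None or s > prev_end + 1:
                if run_start is not None:
                    hotspots.append(
                        HotspotWindow(run_start, prev_end, count_in(run_start, prev_end))
                    )
                run_start = s
            prev_end = s + window_size - 1
    if run_start is not None:
        hotspots.append(HotspotWindow(run_start, prev_end, count_in(run_start, prev_end)))
    return hotspots


# ---------------------------------------------------------------------------
# Missense-tolerance binning

class ToleranceCategory(str, Enum):
    HIGHLY_INTOLERANT = "highly_intolerant"
    MODERATELY_INTOLERANT = "moderately_intolerant"
    INTERMEDIATE_TOLERANCE = "intermediate_tolerance"
    TOLERANT = "tolerant"


#: Half-open score bins partitioning [0, inf).  The printed ranges share
#: endpoints ("0.5-0.7", "0.7-1.0"); the shared points 0.5 and 0.7 go to the
#: upper bin, while 1.0 stays intermediate because "tolerant" is strictly
#: ">1.0".
TOLERANCE_BINS: tuple[tuple[ToleranceCategory, float, float], ...] = (
    (ToleranceCategory.HIGHLY_INTOLERANT, 0.0, 0.5),
    (ToleranceCategory.MODERATELY_INTOLERANT, 0.5, 0.7),
    (ToleranceCategory.INTERMEDIATE_TOLERANCE, 0.7, 1.0),
    (ToleranceCategory.TOLERANT, 1.0, math.inf),
)


def bin_tolerance(score: float) -> ToleranceCategory:
    """Map a per-residue missense-tolerance score to its category."""
    if score < 0:
        raise ValueError(f"tolerance score must be >= 0, got {score}")
    if score < 0.5:
        return ToleranceCategory.HIGHLY_INTOLERANT
    if score < 0.7:
        return ToleranceCategory.MODERATELY_INTOLERANT
    if score <= 1.0:
        return ToleranceCategory.INTERMEDIATE_TOLERANCE
    return ToleranceCategory.TOLERANT
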