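"""Linear membrane topology of a 12-TM transporter.

The creatine transporter CRT1 (SLC6A8, 635 residues, LeuT fold) threads the
membrane twelve times; both termini are cytosolic, so the loops alternate
extracellular (EL1..EL6, after odd-numbered helices) and intracellular
(IL1..IL5, after even-numbered helices).  A :class:`TopologyModel` is an
ordered tiling of ``1..protein_length`` by named regions; all coordinates are
1-based and inclusive throughout the package (HGVS convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable


class RegionClass(str, Enum):
    TERMINUS = "terminus"
    LOOP = "loop"
    TM = "tm"


class Side(str, Enum):
    CYTOPLASMIC = "cytoplasmic"
    MEMBRANE = "membrane"
    EXTRACELLULAR = "extracellular"


#: The only region names a model may use, in their mandatory order for a
#: 12-TM transporter with cytosolic termini.
CANONICAL_REGION_ORDER: tuple[str, ...] = (
    "N_TERM",
    "TM1", "EL1", "TM2", "IL1", "TM3", "EL2", "TM4", "IL2", "TM5", "EL3",
    "TM6", "IL3", "TM7", "EL4", "TM8", "IL4", "TM9", "EL5", "TM10", "IL5",
    "TM11", "EL6", "TM12",
    "C_TERM",
)


def side_of(name: str) -> Side:
    """Membrane side implied by a region name (termini/IL cytosolic, EL
    extracellular, TM in the membrane)."""
    if name in ("N_TERM", "C_TERM") or name.startswith("IL"):
        return Side.CYTOPLASMIC
    if name.startswith("EL"):
        return Side.EXTRACELLULAR
    if name.startswith("TM"):
        return Side.MEMBRANE
    raise ValueError(f"unknown region name: {name!r}")


@dataclass(frozen=True)
class Region:
    """A contiguous residue interval [start, end] (1-based, inclusive)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in CANONICAL_REGION_ORDER:
            raise ValueError(f"unknown region name: {self.name!r}")
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"region {self.name}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def side(self) -> Side:
        return side_of(self.name)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def region_class(region: Region | str) -> RegionClass:
    """Coarse class of a region: terminus, loop or tm."""
    name = region.name if isinstance(region, Region) else region
    if name in ("N_TERM", "C_TERM"):
        return RegionClass.TERMINUS
    if name.startswith(("EL", "IL")):
        return RegionClass.LOOP
    if name.startswith("TM"):
        return RegionClass.TM
    raise ValueError(f"unknown region name: {name!r}")


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str


@dataclass
class TopologyModel:
    """Ordered region tiling of a protein of ``protein_length`` residues."""

    protein_length: int
    regions: list[Region] = field(default_factory=list)

    def validate(self) -> list[ValidationIssue]:
        return validate_topology(self)

    def region_of(self, position: int) -> Region:
        """The unique region containing ``position`` (1-based)."""
        if not 1 <= position <= self.protein_length:
            raise ValueError(
                f"position {position} outside protein 1..{self.protein_length}"
            )
        for region in self.regions:
            if region.start <= position <= region.end:
                return region
        raise ValueError(f"no region covers position {position}; model invalid")

    def regions_in_interval(self, start: int, end: int) -> list[Region]:
        """All regions intersecting [start, end], in N→C order."""
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
        if start < 1 or end > self.protein_length:
            raise ValueError(
                f"interval [{start}, {end}] outside protein 1..{self.protein_length}"
            )
        return [r for r in self.regions if r.start <= end and r.end >= start]


def validate_topology(model: TopologyModel) -> list[ValidationIssue]:
    """Check the tiling and alternation invariants.

    Returns a (possibly empty) list of issues; an empty list means valid.
    Checks: positive length; region names in canonical order with no
    omissions; regions tile 1..protein_length without gaps or overlaps.
    """
    issues: list[ValidationIssue] = []
    if model.protein_length < 1:
        issues.append(ValidationIssue("bad_length", "protein_length must be >= 1"))
        return issues
    names = [r.name for r in model.regions]
    if names != list(CANONICAL_REGION_ORDER):
        missing = [n for n in CANONICAL_REGION_ORDER if n not in names]
        if missing:
            issues.append(
                ValidationIssue(
                    "missing_region", "missing region(s): " + ", ".join(missing)
                )
            )
        extra = [n for n in names if n not in CANONICAL_REGION_ORDER]
        if extra:
            issues.append(
                ValidationIssue("unknown_region", "unknown region(s): " + ", ".join(extra))
            )
        if not missing and not extra:
            issues.append(
                ValidationIssue(
                    "bad_order",
                    "regions out of canonical N_TERM..TM12..C_TERM order",
                )
            )
    pos = 1
    for region in model.regions:
        if region.start > pos:
            issues.append(
                ValidationIssue(
                    "gap",
                    f"gap before {region.name}: residues {pos}..{region.start - 1} uncovered",
                )
            )
        elif region.start < pos:
            issues.append(
                ValidationIssue(
                    "overlap",
                    f"{region.name} overlaps the preceding region at residue {region.start}",
                )
            )
        pos = max(pos, region.end + 1)
    if model.regions and model.regions[-1].end != model.protein_length:
        issues.append(
            ValidationIssue(
                "coverage",
                f"tiling ends at {model.regions[-1].end}, protein length is "
                f"{model.protein_length}",
            )
        )
    return issues


def build_topology(protein_length: int, boundaries: Iterable[tuple[str, int, int]]) -> TopologyModel:
    """Build and validate a model from (name, start, end) triples."""
    model = TopologyModel(protein_length, [Region(n, s, e) for n, s, e in boundaries])
    issues = validate_topology(model)
    if issues:
        raise ValueError(
            "invalid topology: " + "; ".join(i.message for i in issues)
        )
    return model


# Synthetic default topology for the 635-residue human transporter.  The
# true helix boundaries are not published with the analyses this package
# reproduces, so this tiling is a constructed stand-in in the style of
# UniProt TRANSMEM annotation: ~21-residue helices, a large EL2 (the SLC6
# family's long second extracellular loop), position 38 in the N-terminus,
# and TM6-TM8 falling inside residues 305-415.
_DEFAULT_BOUNDARIES: tuple[tuple[str, int, int], ...] = (
    ("N_TERM", 1, 55),
    ("TM1", 56, 76), ("EL1", 77, 87), ("TM2", 88, 108), ("IL1", 109, 119),
    ("TM3", 120, 140), ("EL2", 141, 220), ("TM4", 221, 241), ("IL2", 242, 252),
    ("TM5", 253, 273), ("EL3", 274, 310), ("TM6", 311, 331), ("IL3", 332, 345),
    ("TM7", 346, 366), ("EL4", 367, 400), ("TM8", 401, 421), ("IL4", 422, 432),
    ("TM9", 433, 453), ("EL5", 454, 475), ("TM10", 476, 496), ("IL5", 497, 507),
    ("TM11", 508, 528), ("EL6", 529, 570), ("TM12", 571, 591),
    ("C_TERM", 592, 635),
)


def default_topology() -> TopologyModel:
    """The packaged synthetic 635-residue, 25-region topology (see module
    comment above `_DEFAULT_BOUNDARIES`)."""
    return build_topology(635, _DEFAULT_BOUNDARIES)
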