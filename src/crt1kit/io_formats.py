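"""Readers and writers for every external format the pipeline touches.

FASTA ortholog panels (via biopython), tab-separated variant tables in HGVS
p.-notation, topology definition TSVs, per-residue missense-tolerance TSVs
and replicate uptake CSVs.  Malformed variant rows are rejected (not fatal)
and surfaced in a rejection report; everything else validates hard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .topology import TopologyModel, build_topology

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class ValidationError(ValueError):
    """An input file violated a hard contract."""


class Classification(str, Enum):
    BENIGN = "benign_likely_benign"
    PATHOGENIC = "pathogenic_likely_pathogenic"
    UNKNOWN = "unknown"


#: LOVD-style labels collapsed onto the three working bins.
_CLASSIFICATION_ALIASES = {
    "benign": Classification.BENIGN,
    "likely benign": Classification.BENIGN,
    "likely_benign": Classification.BENIGN,
    "benign/likely benign": Classification.BENIGN,
    "benign_likely_benign": Classification.BENIGN,
    "pathogenic": Classification.PATHOGENIC,
    "likely pathogenic": Classification.PATHOGENIC,
    "likely_pathogenic": Classification.PATHOGENIC,
    "pathogenic/likely pathogenic": Classification.PATHOGENIC,
    "pathogenic_likely_pathogenic": Classification.PATHOGENIC,
    "vus": Classification.UNKNOWN,
    "uncertain": Classification.UNKNOWN,
    "unknown": Classification.UNKNOWN,
}


def parse_classification(label: str) -> Classification:
    try:
        return _CLASSIFICATION_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValidationError(f"unrecognized clinical classification: {label!r}")


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence (one-letter codes, upper case)."""

    id: str
    residues: str
    species_label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains illegal residue characters: "
                + "".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OrthologPanel:
    """Ordered species panel; the first sequence is the reference unless a
    different ``reference_id`` is set."""

    sequences: list[ProteinSequence]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValidationError("panel is empty")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError("duplicate sequence ids: " + ", ".join(dupes))
        if self.reference_id is None:
            self.reference_id = ids[0]
        elif self.reference_id not in ids:
            raise ValidationError(
                f"reference id {self.reference_id!r} not in panel"
            )

    @property
    def reference(self) -> ProteinSequence:
        return next(s for s in self.sequences if s.id == self.reference_id)

    @property
    def queries(self) -> list[ProteinSequence]:
        return [s for s in self.sequences if s.id != self.reference_id]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class VariantTableRow:
    hgvs_p: str
    classification: Classification
    source_label: str = ""


@dataclass(frozen=True)
class ToleranceRow:
    position: int
    score: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"tolerance position {self.position} < 1")
        if self.score < 0:
            raise ValidationError(
                f"tolerance score {self.score} at position {self.position} is negative"
            )


@dataclass(frozen=True)
class UptakeRow:
    genotype_label: str
    replicate_id: str
    creatine_amount: float

    def __post_init__(self) -> None:
        if self.creatine_amount < 0:
            raise ValidationError(
                f"negative creatine amount for {self.genotype_label}/{self.replicate_id}"
            )


@dataclass(frozen=True)
class Rejection:
    """One excluded input row with a machine-readable reason code."""

    row: str
    code: str
    message: str


@dataclass
class VariantTable:
    rows: list[VariantTableRow]
    rejections: list[Rejection] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, reference_id: str | None = None) -> OrthologPanel:
    """Read an ortholog panel, preserving record order.

    The first record is the reference unless ``reference_id`` names another.
    Residues are upper-cased; illegal characters, duplicate ids and empty
    files raise :class:`ValidationError` naming the offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    seqs = []
    for rec in records:
        residues = str(rec.seq).upper()
        species = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            seqs.append(ProteinSequence(rec.id, residues, species))
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {rec.id!r}: {exc}") from exc
    return OrthologPanel(seqs, reference_id)


def write_fasta(panel: OrthologPanel, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.species_label)
        for s in panel.sequences
    ]
    SeqIO.write(records, str(path), "fasta")
    del width  # biopython wraps at 60; kept for signature stability


# ---------------------------------------------------------------------------
# Variant table (TSV)

VARIANT_COLUMNS = ("hgvs_p", "classification")


def read_variant_table(path: str | Path) -> VariantTable:
    """Read an LOVD-style variant TSV with ``hgvs_p`` and ``classification``
    columns (optional ``source_label``).

    Rows whose HGVS string does not parse, or whose classification is
    unrecognized, are rejected with a reason code instead of aborting.
    """
    from .variant_analysis import HgvsParseError, parse_hgvs_p

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"expected header with {', '.join(VARIANT_COLUMNS)}"
        )
    rows: list[VariantTableRow] = []
    rejections: list[Rejection] = []
    for _, r in df.iterrows():
        raw = "\t".join(str(v) for v in r.tolist())
        try:
            parse_hgvs_p(r["hgvs_p"])
            cls = parse_classification(r["classification"])
        except HgvsParseError as exc:
            rejections.append(Rejection(raw, exc.code, str(exc)))
            continue
        except ValidationError as exc:
            rejections.append(Rejection(raw, "bad_classification", str(exc)))
            continue
        rows.append(
            VariantTableRow(r["hgvs_p"].strip(), cls, r.get("source_label", ""))
        )
    if rejections:
        logger.info(
            "%s: rejected %d of %d variant rows", path, len(rejections), len(df)
        )
    return VariantTable(rows, rejections)


def write_variant_table(rows: list[VariantTableRow], path: str | Path) -> None:
    pd.DataFrame(
        {
            "hgvs_p": [r.hgvs_p for r in rows],
            "classification": [r.classification.value for r in rows],
            "source_label": [r.source_label for r in rows],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Topology (TSV: name, start, end)

def read_topology(path: str | Path) -> TopologyModel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("name", "start", "end"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing topology column {col!r}")
    try:
        return build_topology(
            int(df["end"].max()),
            [(str(r["name"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()],
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_topology(model: TopologyModel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [r.name for r in model.regions],
            "start": [r.start for r in model.regions],
            "end": [r.end for r in model.regions],
            "side": [r.side.value for r in model.regions],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tolerance scores (TSV: position, score)

def read_tolerance(path: str | Path, protein_length: int | None = None) -> list[ToleranceRow]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("position", "score"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing tolerance column {col!r}")
    rows = []
    for _, r in df.iterrows():
        row = ToleranceRow(int(r["position"]), float(r["score"]))
        if protein_length is not None and row.position > protein_length:
            raise ValidationError(
                f"{path}: tolerance position {row.position} beyond protein length "
                f"{protein_length}"
            )
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Uptake replicates (CSV: genotype, replicate, value)

UPTAKE_COLUMNS = ("genotype", "replicate", "value")


def read_uptake(path: str | Path) -> list[UptakeRow]:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing uptake column(s) {', '.join(missing)}"
        )
    rows = []
    seen: set[tuple[str, str]] = set()
    for _, r in df.iterrows():
        key = (str(r["genotype"]), str(r["replicate"]))
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate (genotype, replicate) pair {key}"
            )
        seen.add(key)
        rows.append(UptakeRow(key[0], key[1], float(r["value"])))
    return rows


def write_uptake(rows: list[UptakeRow], path: str | Path) -> None:
    pd.DataFrame(
        {
            "genotype": [r.genotype_label for r in rows],
            "replicate": [r.replicate_id for r in rows],
            "value": [r.creatine_amount for r in rows],
        }
    ).to_csv(path, index=False)
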