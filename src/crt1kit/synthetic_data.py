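"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all deterministic under an explicit seed:

* ortholog panels — a random reference protein plus species copies whose
  substitutions concentrate in the termini and loops (and, among helices,
  only the last two), mirroring the conservation gradient of a 12-TM
  transporter family;
* variant catalogs — missense tables in HGVS p.-notation whose
  benign/pathogenic mix depends on region class, with optional hotspot
  enrichment;
* uptake replicate tables — truncated-normal assay values per genotype
  around a target percent-of-wild-type.

Species are generated independently from the reference (no phylogenetically
correlated substitution process); that is adequate for identity and tally
recovery but not for realistic tree shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .alignment import AA_CLASSES
from .io_formats import (
    Classification,
    OrthologPanel,
    ProteinSequence,
    UptakeRow,
    VariantTableRow,
)
from .topology import RegionClass, TopologyModel, region_class
from .variant_analysis import AA3_TO_1

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Transmembrane helices that tolerate substitutions in the generator; the
#: core helices (TM1-TM10) are held invariant by default.
PERIPHERAL_TMS = frozenset({"TM11", "TM12"})


def _rate_for_region(name: str, cfg: "PanelGeneratorConfig") -> float:
    rc = region_class(name)
    if rc is RegionClass.TERMINUS:
        return cfg.terminus_rate
    if rc is RegionClass.LOOP:
        return cfg.loop_rate
    return cfg.peripheral_tm_rate if name in PERIPHERAL_TMS else cfg.core_tm_rate


@dataclass
class PanelGeneratorConfig:
    """Per-residue substitution rates by region class.

    Defaults encode divergence concentrated in the termini, lighter in
    loops, absent from the core helices and rare in TM11-TM12, with 80% of
    substitutions staying within the reference residue's amino-acid class.
    """

    protein_length: int = 635
    n_species: int = 8
    terminus_rate: float = 0.02
    loop_rate: float = 0.01
    core_tm_rate: float = 0.0
    peripheral_tm_rate: float = 0.004
    same_class_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.terminus_rate, self.loop_rate, self.core_tm_rate,
                  self.peripheral_tm_rate, self.same_class_bias):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate/probability {r} outside [0, 1]")


def expected_identity_pct(cfg: PanelGeneratorConfig, topology: TopologyModel) -> float:
    """Closed-form expected percent identity of a generated species to the
    reference (1 minus the mean per-residue substitution rate)."""
    total = sum(_rate_for_region(r.name, cfg) * r.length for r in topology.regions)
    return 100.0 * (1.0 - total / topology.protein_length)


def _same_class_partners(aa: str) -> list[str]:
    partners: set[str] = set()
    for members in AA_CLASSES.values():
        if aa in members:
            partners |= set(members)
    partners.discard(aa)
    return sorted(partners)


def gen_ortholog_panel(
    cfg: PanelGeneratorConfig,
    topology: TopologyModel,
    reference_residues: str | None = None,
) -> OrthologPanel:
    """Reference plus ``n_species`` derived sequences.

    Each residue of each species mutates independently with its region's
    rate; a mutating residue stays within the reference residue's
    amino-acid class with probability ``same_class_bias``.  Configurations
    implying > 50% expected divergence are rejected: the panel must stay
    alignable as near-identical.
    """
    if topology.protein_length != cfg.protein_length:
        raise ValueError("topology length does not match config protein_length")
    if expected_identity_pct(cfg, topology) < 50.0:
        raise ValueError("expected divergence exceeds 50%; panel would not be near-identical")
    rng = np.random.default_rng(cfg.seed)
    if reference_residues is None:
        reference_residues = "".join(rng.choice(list(_AA), size=cfg.protein_length))
    elif len(reference_residues) != cfg.protein_length:
        raise ValueError("reference_residues length mismatch")
    rates = np.empty(cfg.protein_length)
    for region in topology.regions:
        rates[region.start - 1 : region.end] = _rate_for_region(region.name, cfg)
    seqs = [ProteinSequence("reference", reference_residues, "reference species")]
    for s in range(cfg.n_species):
        residues = list(reference_residues)
        hits = np.nonzero(rng.random(cfg.protein_length) < rates)[0]
        for pos in hits:
            ref_aa = residues[pos]
            same = _same_class_partners(ref_aa)
            if same and rng.random() < cfg.same_class_bias:
                residues[pos] = str(rng.choice(same))
            else:
                other = [a for a in _AA if a != ref_aa and a not in same]
                residues[pos] = str(rng.choice(other or [a for a in _AA if a != ref_aa]))
        seqs.append(
            ProteinSequence(f"species_{s + 1:02d}", "".join(residues),
                            f"synthetic species {s + 1}")
        )
    return OrthologPanel(seqs)


# ---------------------------------------------------------------------------
# Variant catalogs

@dataclass
class VariantGeneratorConfig:
    """Missense catalog generator.

    ``pathogenic_prob`` keys are region classes; placement weights multiply
    the per-residue sampling probability of each class, and the hotspot
    interval gets an extra enrichment factor.
    """

    n_variants: int = 43
    placement_weights: dict[RegionClass, float] = field(
        default_factory=lambda: {rc: 1.0 for rc in RegionClass}
    )
    pathogenic_prob: dict[RegionClass, float] = field(
        default_factory=lambda: {
            RegionClass.TERMINUS: 0.0,
            RegionClass.LOOP: 0.64,
            RegionClass.TM: 0.70,
        }
    )
    hotspot_interval: tuple[int, int] | None = None
    hotspot_enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.pathogenic_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pathogenic probability {p} outside [0, 1]")


def gen_variant_table(
    cfg: VariantGeneratorConfig,
    topology: TopologyModel,
    reference_residues: str | None = None,
) -> list[VariantTableRow]:
    """Missense HGVS rows with region-dependent pathogenic probabilities."""
    rng = np.random.default_rng(cfg.seed)
    L = topology.protein_length
    if reference_residues is None:
        reference_residues = "".join(rng.choice(list(_AA), size=L))
    weights = np.empty(L)
    for region in topology.regions:
        w = cfg.placement_weights.get(region_class(region), 1.0)
        weights[region.start - 1 : region.end] = w
    if cfg.hotspot_interval is not None:
        lo, hi = cfg.hotspot_interval
        weights[lo - 1 : hi] *= cfg.hotspot_enrichment
    weights = weights / weights.sum()
    positions = rng.choice(L, size=cfg.n_variants, p=weights) + 1
    rows = []
    for pos in positions:
        ref_aa = reference_residues[pos - 1]
        alt_aa = str(rng.choice([a for a in _AA if a != ref_aa]))
        rc = region_class(topology.region_of(int(pos)))
        p_path = cfg.pathogenic_prob.get(rc, 0.0)
        cls = (
            Classification.PATHOGENIC
            if rng.random() < p_path
            else Classification.BENIGN
        )
        rows.append(
            VariantTableRow(
                f"p.{_AA1_TO_3[ref_aa]}{int(pos)}{_AA1_TO_3[alt_aa]}",
                cls,
                "synthetic",
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Curated catalog matching the published regional composition

# (position, ref, alt, classification) — a synthetic stand-in for the public
# variant-database extraction: 43 missense variants arranged so that all 8
# terminus variants are benign, 16 of 25 loop variants (64%) and 7 of 10
# helix variants (70%) are pathogenic, 17 variants cluster in residues
# 305-415, and two alleles share Cys491.  Positions refer to the packaged
# default topology.
_B = Classification.BENIGN
_P = Classification.PATHOGENIC
_CATALOG: tuple[tuple[int, str, str, Classification], ...] = (
    # termini (8, all benign)
    (10, "A", "T", _B), (25, "S", "N", _B), (38, "V", "A", _B), (50, "E", "K", _B),
    (600, "R", "Q", _B), (610, "G", "S", _B), (620, "P", "L", _B), (630, "T", "M", _B),
    # loops outside the cluster (14: 7 pathogenic, 7 benign)
    (80, "G", "R", _P), (82, "N", "S", _B), (112, "R", "W", _P),
    (150, "C", "R", _P), (160, "D", "N", _B), (170, "Y", "C", _P),
    (180, "Q", "H", _B), (200, "W", "R", _P), (245, "K", "R", _B),
    (280, "F", "S", _P), (290, "I", "V", _B), (460, "L", "P", _P),
    (500, "V", "I", _B), (540, "T", "A", _B),
    # loops inside residues 305-415 (11: 9 pathogenic, 2 benign)
    (306, "P", "L", _P), (308, "G", "E", _P), (335, "R", "C", _P),
    (338, "S", "P", _P), (342, "A", "V", _B), (370, "P", "R", _P),
    (375, "G", "D", _P), (380, "N", "K", _P), (385, "C", "Y", _P),
    (390, "M", "V", _B), (395, "E", "G", _P),
    # helices inside residues 305-415 (6: 5 pathogenic, 1 benign)
    (315, "G", "R", _P), (320, "L", "P", _P), (350, "A", "D", _P),
    (360, "V", "M", _B), (405, "F", "C", _P), (410, "S", "F", _P),
    # helices outside (4: 2 pathogenic at the shared Cys, 2 benign)
    (95, "I", "L", _B), (491, "C", "Y", _P), (491, "C", "W", _P), (515, "M", "I", _B),
)


def curated_missense_catalog() -> list[VariantTableRow]:
    """The packaged synthetic 43-variant missense catalog (see `_CATALOG`)."""
    return [
        VariantTableRow(
            f"p.{_AA1_TO_3[ref]}{pos}{_AA1_TO_3[alt]}", cls, "curated_synthetic"
        )
        for pos, ref, alt, cls in _CATALOG
    ]


# ---------------------------------------------------------------------------
# Uptake replicates

@dataclass
class UptakeGeneratorConfig:
    """Replicate uptake values per genotype.

    Each genotype's replicates are truncated-normal (non-negative) around
    ``wt_mean * pct/100`` with a constant coefficient of variation
    ``wt_sd / wt_mean`` (assay noise scales with signal).
    """

    wt_mean: float = 10.0
    wt_sd: float = 1.2
    pct_of_wt_targets: dict[str, float] = field(
        default_factory=lambda: {f"SD{i}": 8.0 for i in range(1, 9)} | {"SD9": 71.0}
    )
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_mean <= 0 or self.wt_sd < 0:
            raise ValueError("wt_mean must be > 0 and wt_sd >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if any(p < 0 for p in self.pct_of_wt_targets.values()):
            raise ValueError("pct_of_wt targets must be >= 0")


def gen_uptake_data(cfg: UptakeGeneratorConfig) -> list[UptakeRow]:
    rng = np.random.default_rng(cfg.seed)
    cv = cfg.wt_sd / cfg.wt_mean
    rows: list[UptakeRow] = []
    targets = {"WT": 100.0} | dict(cfg.pct_of_wt_targets)
    for genotype, pct in targets.items():
        mean = cfg.wt_mean * pct / 100.0
        sd = cv * mean
        if sd == 0 or mean == 0:
            values = np.full(cfg.n_replicates, mean)
        else:
            a = (0.0 - mean) / sd  # truncate at zero: uptake is non-negative
            values = sp_stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=cfg.n_replicates, random_state=rng
            )
        rows.extend(
            UptakeRow(genotype, f"r{i + 1}", float(v))
            for i, v in enumerate(values)
        )
    return rows
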