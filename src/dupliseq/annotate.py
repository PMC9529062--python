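"""Cancer-association classification, prevalence conversion, detection limits.

A call is cancer-associated when its amino-acid change is known to PeCan, or
known to COSMIC with mutation-significance tier 1-3, or reported more than
five times in COSMIC. Cellular prevalence assumes a heterozygous diploid
locus (prevalence = 2 x VAF, clipped at 100% of cells); detectability tiers
bin mutations by which sequencing technology could have found them.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

__all__ = [
    "KnowledgeTable",
    "MutationRecord",
    "DetectabilityTier",
    "DetectionLimit",
    "classify_cancer_associated",
    "vaf_to_prevalence",
    "prevalence_to_vaf",
    "detectability_tier",
    "detection_limit",
    "round_to_sig_figs",
]

_SOURCES = {"PECAN", "COSMIC"}
_TIERS = {"1", "2", "3", "other", "none"}


class KnowledgeTable:
    """Local lookup of known cancer mutations shaped like PeCan/COSMIC exports.

    TSV schema: gene, key (amino-acid change such as ``G12D`` or a genomic
    key), source (PECAN|COSMIC), cosmic_tier (1|2|3|other|none; ``none`` for
    PECAN rows), report_count (integer).
    """

    def __init__(self) -> None:
        self.pecan: set = set()
        self.cosmic: Dict[Tuple[str, str], Tuple[str, int]] = {}

    def add(self, gene: str, key: str, source: str,
            cosmic_tier: str = "none", report_count: int = 0) -> None:
        if source not in _SOURCES:
            raise ValueError(f"unknown source {source!r}")
        if cosmic_tier not in _TIERS:
            raise ValueError(f"unknown COSMIC tier {cosmic_tier!r}")
        if source == "PECAN":
            self.pecan.add((gene, key))
        else:
            if (gene, key) in self.cosmic:
                raise ValueError(f"duplicate COSMIC key {(gene, key)}")
            self.cosmic[(gene, key)] = (cosmic_tier, int(report_count))

    @classmethod
    def from_tsv(cls, path) -> "KnowledgeTable":
        table = cls()
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("gene\t"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(f"knowledge table line {ln}: expected 5 columns")
                gene, key, source, tier, count = parts
                table.add(gene, key, source, tier, int(count))
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tkey\tsource\tcosmic_tier\treport_count\n")
            for gene, key in sorted(self.pecan):
                fh.write(f"{gene}\t{key}\tPECAN\tnone\t0\n")
            for (gene, key), (tier, count) in sorted(self.cosmic.items()):
                fh.write(f"{gene}\t{key}\tCOSMIC\t{tier}\t{count}\n")


class DetectabilityTier(str, enum.Enum):
    """Which sequencing technology could have detected a mutation.

    Cut points at VAF 0.01 / 0.05 / 0.3; lower bound inclusive, upper
    exclusive, except that the major clone is strictly VAF > 0.3.
    """

    MAJOR_CLONE = "major_clone"     # VAF > 0.3
    WGS_WES = "wgs_wes"             # 0.05 <= VAF <= 0.3
    DEEP_PANEL = "deep_panel"       # 0.01 <= VAF < 0.05
    DUPLEX_ONLY = "duplex_only"     # VAF < 0.01


@dataclass
class MutationRecord:
    """An annotated variant call."""

    contig: str
    position: int
    ref: str
    alt: str
    vaf: float
    gene: str
    protein_change: Optional[str] = None
    sample_id: Optional[str] = None
    cancer_associated: Optional[bool] = None
    reason: Optional[str] = None
    cellular_prevalence_pct: Optional[float] = None
    tier: Optional[DetectabilityTier] = None
    validated: Optional[bool] = None


def classify_cancer_associated(record: MutationRecord, table: KnowledgeTable) -> MutationRecord:
    """Classify a record against the knowledge table (idempotent).

    True iff the (gene, protein-change) key is in PeCan, or in COSMIC with
    tier 1-3, or in COSMIC reported more than 5 times; the reason records
    which branch fired. Records without a key classify False with reason
    ``unannotated``.
    """
    if not record.protein_change:
        record.cancer_associated = False
        record.reason = "unannotated"
        return record
    key = (record.gene, record.protein_change)
    if key in table.pecan:
        record.cancer_associated = True
        record.reason = "PECAN"
        return record
    if key in table.cosmic:
        tier, count = table.cosmic[key]
        if tier in {"1", "2", "3"}:
            record.cancer_associated = True
            record.reason = f"COSMIC_tier{tier}"
            return record
        if count > 5:
            record.cancer_associated = True
            record.reason = "COSMIC_recurrent"
            return record
    record.cancer_associated = False
    record.reason = "not_cancer_associated"
    return record


def vaf_to_prevalence(vaf: float, ploidy_model: str = "het-diploid") -> float:
    """Convert a VAF to percent of cells carrying the mutation.

    Under the default heterozygous-diploid model each mutant cell contributes
    one mutant allele out of two, so prevalence = 200 x VAF percent, clipped
    at 100%.
    """
    if vaf < 0:
        raise ValueError("VAF must be >= 0")
    if vaf > 1:
        raise ValueError("VAF must be <= 1")
    if ploidy_model != "het-diploid":
        raise ValueError(f"unknown ploidy model {ploidy_model!r}")
    return min(200.0 * vaf, 100.0)


def prevalence_to_vaf(prevalence_pct: float) -> float:
    """Inverse conversion (exact below the 100% clip point)."""
    if not (0.0 <= prevalence_pct <= 100.0):
        raise ValueError("prevalence must be in [0, 100] percent")
    return prevalence_pct / 200.0


def detectability_tier(vaf: float) -> DetectabilityTier:
    """Bin a VAF into its detectability tier (see :class:`DetectabilityTier`)."""
    if not (0.0 <= vaf <= 1.0):
        raise ValueError("VAF must be in [0, 1]")
    if vaf > 0.3:
        return DetectabilityTier.MAJOR_CLONE
    if vaf >= 0.05:
        return DetectabilityTier.WGS_WES
    if vaf >= 0.01:
        return DetectabilityTier.DEEP_PANEL
    return DetectabilityTier.DUPLEX_ONLY


def annotate_record(record: MutationRecord, table: KnowledgeTable) -> MutationRecord:
    """Full annotation: classification, prevalence and detectability tier."""
    classify_cancer_associated(record, table)
    record.cellular_prevalence_pct = vaf_to_prevalence(record.vaf)
    record.tier = detectability_tier(record.vaf)
    return record


def round_to_sig_figs(x: float, n: int = 1) -> float:
    """Round to ``n`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


@dataclass
class DetectionLimit:
    """Theoretical detection limit implied by the DNA input mass.

    ``cell_equivalents`` is the number of diploid genome copies in the input;
    the limiting prevalence is the cell fraction at which
    ``min_supporting_molecules`` mutant molecules are expected among them.
    Both are reported raw and rounded to one significant figure, because the
    two-fold ambiguity between "fraction of cells" and "fraction of alleles"
    makes only the order of magnitude meaningful.
    """

    input_mass_ng: float
    genome_mass_pg: float
    min_supporting_molecules: int
    cell_equivalents: float
    cell_equivalents_1sf: float
    limiting_prevalence_pct: float
    limiting_prevalence_pct_1sf: float


def detection_limit(
    input_ng: float,
    genome_mass_pg: float = 6.6,
    min_supporting_molecules: int = 2,
) -> DetectionLimit:
    """Compute genome equivalents and the limiting prevalence for an input mass.

    250 ng at 6.6 pg per diploid genome gives ~37,879 cell equivalents
    (40,000 at one significant figure); with the default of two supporting
    molecules the limiting prevalence is ~0.005%.
    """
    if input_ng <= 0:
        raise ValueError("input mass must be positive")
    if genome_mass_pg <= 0:
        raise ValueError("genome mass must be positive")
    if min_supporting_molecules < 1:
        raise ValueError("min_supporting_molecules must be >= 1")
    cells = input_ng * 1000.0 / genome_mass_pg
    prev_pct = 100.0 * min_supporting_molecules / cells
    return DetectionLimit(
        input_mass_ng=input_ng,
        genome_mass_pg=genome_mass_pg,
        min_supporting_molecules=min_supporting_molecules,
        cell_equivalents=cells,
        cell_equivalents_1sf=round_to_sig_figs(cells, 1),
        limiting_prevalence_pct=prev_pct,
        limiting_prevalence_pct_1sf=round_to_sig_figs(prev_pct, 1),
    )
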