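"""Barcode-family consensus: single-strand (SSCS) and duplex (DCS) collapsing.

A family is the set of raw reads sharing one molecule's barcode pair, strand
orientation and coordinates. Per position the SSCS base is the one supported
by at least ``cutoff`` of the family's reads (ties cannot pass because
``cutoff > 0.5``), otherwise N. The DCS keeps a base only where the two
strand consensuses agree and neither is N, which is what suppresses
first-round PCR errors: those are strand-private and cancel at the duplex
step.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .seq import N, TaggedRead, decode_seq

__all__ = [
    "FamilyKey",
    "ConsensusParams",
    "ConsensusRead",
    "ConsensusStats",
    "ConsensusResult",
    "group_families",
    "rep_barcode_filter",
    "build_sscs",
    "build_dcs",
    "trim_ends",
    "collapse_families",
]


class FamilyKey(NamedTuple):
    """Canonical identity of one strand family.

    ``tags`` is the lexicographically sorted barcode pair (identical for the
    two strands of one molecule); ``orientation`` is 0 when the read-observed
    order (tag_a, tag_b) already equals the sorted order, 1 otherwise, so the
    two strand families of one molecule share everything but the bit.
    """

    tags: Tuple[str, str]
    orientation: int
    contig: str
    start: int
    end: int

    @property
    def molecule_key(self) -> Tuple:
        return (self.tags, self.contig, self.start, self.end)


def family_key(read: TaggedRead) -> FamilyKey:
    a, b = read.tag_a, read.tag_b
    tags = (a, b) if a <= b else (b, a)
    return FamilyKey(tags, 0 if (a, b) == tags else 1, read.contig, read.start, read.end)


@dataclass
class ConsensusParams:
    """Collapsing parameters (duplex-pipeline standard values)."""

    cutoff: float = 0.7
    minmem: int = 3
    maxmem: int = 200
    rep_filt: int = 9
    end_trim: int = 5
    max_n_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0.5 < self.cutoff <= 1.0):
            raise ValueError("cutoff must satisfy 0.5 < cutoff <= 1")
        if self.minmem < 1:
            raise ValueError("minmem must be >= 1")
        if self.maxmem < self.minmem:
            raise ValueError("maxmem must be >= minmem")
        if not (0.0 <= self.max_n_fraction <= 1.0):
            raise ValueError("max_n_fraction must be in [0, 1]")


@dataclass
class ConsensusRead:
    """An SSCS or DCS with per-base agreement and provenance."""

    name: str
    tier: str  # "SSCS" | "DCS"
    contig: str
    start: int
    end: int
    seq: np.ndarray
    agreement: np.ndarray
    family_size: int                  # reads used (after maxmem down-sampling)
    family_size_b: Optional[int] = None  # second strand's size, DCS only
    key: Optional[FamilyKey] = None
    softclip: bool = False

    @property
    def length(self) -> int:
        return int(self.seq.size)

    @property
    def sequence(self) -> str:
        return decode_seq(self.seq)

    @property
    def n_fraction(self) -> float:
        return float((self.seq == N).mean())


@dataclass
class GroupingResult:
    families: Dict[FamilyKey, List[TaggedRead]]
    n_missing_tags: int


def group_families(reads: Iterable[TaggedRead]) -> GroupingResult:
    """Partition tagged reads into strand families; untagged reads are counted."""
    families: Dict[FamilyKey, List[TaggedRead]] = {}
    missing = 0
    for read in reads:
        if not read.has_tags():
            missing += 1
            continue
        families.setdefault(family_key(read), []).append(read)
    return GroupingResult(families, missing)


def _max_homopolymer_run(tag: str) -> int:
    best = run = 1
    for prev, cur in zip(tag, tag[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if tag else 0


def rep_barcode_filter(key: FamilyKey, params: ConsensusParams) -> bool:
    """True (pass) unless either tag contains a homopolymer run >= rep_filt."""
    for tag in key.tags:
        if not tag:
            raise ValueError("empty barcode tag")
        if _max_homopolymer_run(tag) >= params.rep_filt:
            return False
    return True


def build_sscs(reads: Sequence[TaggedRead], params: ConsensusParams) -> Optional[ConsensusRead]:
    """Collapse one strand family to its single-strand consensus.

    Families below ``minmem`` are rejected (returns None); families above
    ``maxmem`` are down-sampled deterministically to the first ``maxmem``
    reads after a stable sort by read name. A position's consensus base needs
    agreement fraction >= cutoff (inclusive), else N; raw N bases are
    excluded from both numerator and denominator. Consensus reads whose N
    fraction exceeds ``max_n_fraction`` are rejected.
    """
    reads = list(reads)
    if not reads:
        return None
    lengths = {r.length for r in reads}
    if len(lengths) != 1:
        raise ValueError("family reads have unequal lengths")
    positions = {(r.contig, r.start, r.end) for r in reads}
    if len(positions) != 1:
        raise ValueError("family reads have inconsistent coordinates")
    if len(reads) < params.minmem:
        return None
    used = sorted(reads, key=lambda r: r.name)[: params.maxmem]

    mat = np.stack([r.seq for r in used])
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)], axis=1)  # (L, 4)
    denom = (mat != N).sum(axis=0)
    best = counts.argmax(axis=1)
    best_counts = counts[np.arange(counts.shape[0]), best]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, best_counts / np.maximum(denom, 1), 0.0)
    seq = np.where(frac >= params.cutoff, best, N).astype(np.uint8)

    key = family_key(used[0])
    cons = ConsensusRead(
        name=f"sscs_{key.tags[0]}-{key.tags[1]}_{key.orientation}_{key.contig}",
        tier="SSCS", contig=used[0].contig, start=used[0].start, end=used[0].end,
        seq=seq, agreement=frac, family_size=len(used), key=key,
        softclip=all(r.softclip for r in used),
    )
    if cons.n_fraction > params.max_n_fraction:
        return None
    return cons


def build_dcs(sscs_top: ConsensusRead, sscs_bottom: ConsensusRead) -> ConsensusRead:
    """Pair the two strand consensuses of one molecule into a duplex consensus."""
    if sscs_top.key is None or sscs_bottom.key is None:
        raise ValueError("SSCS reads must carry family keys")
    if sscs_top.key.molecule_key != sscs_bottom.key.molecule_key:
        raise ValueError("SSCS reads derive from different molecules")
    if sscs_top.key.orientation == sscs_bottom.key.orientation:
        raise ValueError("both SSCS have the same strand orientation")
    if sscs_top.length != sscs_bottom.length:
        raise ValueError("SSCS lengths differ")
    match = (sscs_top.seq == sscs_bottom.seq) & (sscs_top.seq != N)
    seq = np.where(match, sscs_top.seq, N).astype(np.uint8)
    agreement = np.where(match, (sscs_top.agreement + sscs_bottom.agreement) / 2.0, 0.0)
    tags = sscs_top.key.tags
    return ConsensusRead(
        name=f"dcs_{tags[0]}-{tags[1]}_{sscs_top.contig}",
        tier="DCS", contig=sscs_top.contig, start=sscs_top.start, end=sscs_top.end,
        seq=seq, agreement=agreement,
        family_size=sscs_top.family_size, family_size_b=sscs_bottom.family_size,
        key=sscs_top.key, softclip=sscs_top.softclip and sscs_bottom.softclip,
    )


def trim_ends(read: ConsensusRead, end_trim: int) -> ConsensusRead:
    """Remove ``end_trim`` bases from each end (ligation-proximal artifacts)."""
    if end_trim < 0:
        raise ValueError("end_trim must be >= 0")
    if end_trim == 0:
        return read
    if read.length <= 2 * end_trim:
        raise ValueError(f"read of length {read.length} too short to trim {end_trim} per end")
    key = read.key
    if key is not None:
        key = key._replace(start=key.start + end_trim, end=key.end - end_trim)
    return replace(
        read,
        seq=read.seq[end_trim:-end_trim],
        agreement=read.agreement[end_trim:-end_trim],
        start=read.start + end_trim,
        end=read.end - end_trim,
        key=key,
    )


@dataclass
class ConsensusStats:
    """Pipeline accounting plus the fragments-per-region QC statistic.

    ``fragments_per_region`` counts distinct molecules observed per contig;
    a region whose read mass collapses to very few molecules (the pathological
    giant-family failure mode) shows up here, but no pass/fail threshold is
    imposed.
    """

    n_reads: int = 0
    n_missing_tags: int = 0
    n_families: int = 0
    rejected_rep_filter: int = 0
    rejected_minmem: int = 0
    rejected_n_fraction: int = 0
    n_sscs: int = 0
    n_dcs: int = 0
    max_family_size: int = 0
    fragments_per_region: Dict[str, int] = field(default_factory=dict)


@dataclass
class ConsensusResult:
    sscs: List[ConsensusRead]
    dcs: List[ConsensusRead]
    stats: ConsensusStats


def collapse_families(
    reads: Iterable[TaggedRead],
    params: Optional[ConsensusParams] = None,
    trim: bool = True,
) -> ConsensusResult:
    """Full collapsing pipeline: group, filter barcodes, SSCS, pair to DCS, trim."""
    params = params or ConsensusParams()
    grouping = group_families(reads)
    stats = ConsensusStats(
        n_reads=sum(len(v) for v in grouping.families.values()) + grouping.n_missing_tags,
        n_missing_tags=grouping.n_missing_tags,
        n_families=len(grouping.families),
    )

    sscs_by_molecule: Dict[Tuple, Dict[int, ConsensusRead]] = {}
    sscs_out: List[ConsensusRead] = []
    molecule_contigs: Dict[str, set] = {}
    for key, fam in grouping.families.items():
        stats.max_family_size = max(stats.max_family_size, len(fam))
        molecule_contigs.setdefault(key.contig, set()).add(key.molecule_key)
        if not rep_barcode_filter(key, params):
            stats.rejected_rep_filter += 1
            continue
        if len(fam) < params.minmem:
            stats.rejected_minmem += 1
            continue
        cons = build_sscs(fam, params)
        if cons is None:
            stats.rejected_n_fraction += 1
            continue
        sscs_out.append(cons)
        sscs_by_molecule.setdefault(key.molecule_key, {})[key.orientation] = cons
    stats.fragments_per_region = {c: len(s) for c, s in molecule_contigs.items()}

    dcs_out: List[ConsensusRead] = []
    for strands in sscs_by_molecule.values():
        if len(strands) == 2:  # both strand families independently passed
            dcs_out.append(build_dcs(strands[0], strands[1]))

    if trim and params.end_trim > 0:
        sscs_out = [trim_ends(r, params.end_trim) for r in sscs_out
                    if r.length > 2 * params.end_trim]
        dcs_out = [trim_ends(r, params.end_trim) for r in dcs_out
                   if r.length > 2 * params.end_trim]

    stats.n_sscs = len(sscs_out)
    stats.n_dcs = len(dcs_out)
    return ConsensusResult(sscs=sscs_out, dcs=dcs_out, stats=stats)
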