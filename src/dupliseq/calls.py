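"""Pileup over consensus reads and low-VAF variant calling.

Calling mirrors a VarScan-style screen on duplex data: a non-reference base
is emitted when its allele fraction reaches ``min_var_freq`` (inclusive) and
a one-sided exact binomial test against a configurable per-base background
error rate is at or below ``p_value``. Artifact filters (soft-clip support,
cross-sample recurrence, population databases) only annotate flags — no call
is ever silently dropped — mirroring a workflow where flagged loci are
manually assessed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .consensus import ConsensusRead
from .seq import BASE_ALPHABET, encode_seq
from .simulate import TargetPanel

__all__ = [
    "CallingParams",
    "DS_PARAMS",
    "DEEP_PANEL_PARAMS",
    "AMPLICON_PARAMS",
    "PileupColumn",
    "VariantCall",
    "pileup",
    "call_variants",
    "find_supporting_reads",
    "softclip_filter",
    "recurrence_flag",
    "load_blacklist",
    "population_filter",
    "sscs_rescue",
    "RescueEstimate",
]


@dataclass
class CallingParams:
    """Variant-calling thresholds.

    ``DS_PARAMS`` is the duplex default (min VAF 0.1%, p 0.1, qual 25);
    ``DEEP_PANEL_PARAMS`` the personalised deep-panel mode (min VAF 1e-6,
    qual 30, binomial gate disabled); ``AMPLICON_PARAMS`` the multiplex-PCR
    resequencing mode.
    """

    min_var_freq: float = 0.001
    p_value: float = 0.1
    min_avg_qual: int = 25
    strand_filter: bool = False
    max_depth: int = 30_000
    min_mapq: int = 55
    background_error: float = 1e-4  # per-base background at the calling tier

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_var_freq <= 1.0):
            raise ValueError("min_var_freq must be in [0, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")
        if not (0.0 <= self.background_error < 1.0):
            raise ValueError("background_error must be in [0, 1)")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


DS_PARAMS = CallingParams()
DEEP_PANEL_PARAMS = CallingParams(min_var_freq=1e-6, min_avg_qual=30, p_value=1.0)
AMPLICON_PARAMS = CallingParams(min_var_freq=0.001, p_value=0.05, strand_filter=False)


@dataclass
class PileupColumn:
    """Per-position base counts at one consensus tier.

    ``depth`` is the sum of all five base counts (N included), capped by the
    deterministic read truncation applied in :func:`pileup`.
    """

    contig: str
    position: int
    ref: str
    counts: np.ndarray  # (5,) A/C/G/T/N
    tier: str

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    def count(self, base: str) -> int:
        return int(self.counts[encode_seq(base)[0]])


@dataclass
class VariantCall:
    contig: str
    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    vaf: float
    tier: str
    p_value: float
    sample_id: Optional[str] = None
    softclip_fail: bool = False
    recurrent_region: bool = False
    population_db: bool = False
    low_qual: bool = False
    population_reason: Optional[str] = None

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def filters(self) -> List[str]:
        out = []
        if self.softclip_fail:
            out.append("softclip_fail")
        if self.recurrent_region:
            out.append("recurrent_region")
        if self.population_db:
            out.append("population_db")
        if self.low_qual:
            out.append("low_qual")
        return out


def pileup(
    reads: Sequence[ConsensusRead],
    panel: TargetPanel,
    params: Optional[CallingParams] = None,
    tier: Optional[str] = None,
) -> List[PileupColumn]:
    """Pile consensus reads into per-position base counts.

    ``tier`` selects SSCS or DCS reads; when None all reads must share one
    tier. The depth cap is applied per region by keeping the first
    ``max_depth`` reads after a stable sort by read name (deterministic
    truncation, not random sampling). Uncovered positions are omitted.
    """
    params = params or DS_PARAMS
    if tier is not None:
        reads = [r for r in reads if r.tier == tier]
    tiers = {r.tier for r in reads}
    if len(tiers) > 1:
        raise ValueError(f"mixed consensus tiers in pileup input: {sorted(tiers)}")
    read_tier = tier or (tiers.pop() if tiers else "DCS")

    by_contig: Dict[str, List[ConsensusRead]] = {}
    for r in reads:
        by_contig.setdefault(r.contig, []).append(r)

    columns: List[PileupColumn] = []
    for contig in sorted(by_contig):
        rs = sorted(by_contig[contig], key=lambda r: r.name)[: params.max_depth]
        lo = min(r.start for r in rs)
        hi = max(r.end for r in rs)
        counts = np.zeros((hi - lo, 5), dtype=np.int64)
        for r in rs:
            span = np.arange(r.start - lo, r.end - lo)
            np.add.at(counts, (span, r.seq.astype(np.int64)), 1)
        covered = counts.sum(axis=1) > 0
        for off in np.flatnonzero(covered):
            pos = lo + int(off)
            columns.append(PileupColumn(
                contig=contig, position=pos, ref=panel.ref_base(contig, pos),
                counts=counts[off].copy(), tier=read_tier))
    return columns


def call_variants(
    columns: Iterable[PileupColumn],
    params: Optional[CallingParams] = None,
    sample_id: Optional[str] = None,
) -> List[VariantCall]:
    """Emit a call per non-reference base meeting the VAF and binomial gates.

    Multi-allelic columns yield one call per alternate base. The VAF
    threshold is inclusive (a call at exactly ``min_var_freq`` passes); the
    binomial test is one-sided (alt count or more under the background error
    rate), with ``p <= p_value`` inclusive.
    """
    params = params or DS_PARAMS
    out: List[VariantCall] = []
    for col in columns:
        depth = col.depth
        if depth == 0:
            continue
        ref_code = int(encode_seq(col.ref)[0])
        for code in range(4):
            if code == ref_code:
                continue
            alt_count = int(col.counts[code])
            if alt_count == 0:
                continue
            vaf = alt_count / depth
            if vaf < params.min_var_freq:
                continue
            p = float(sps.binom.sf(alt_count - 1, depth, params.background_error))
            if p > params.p_value:
                continue
            out.append(VariantCall(
                contig=col.contig, position=col.position, ref=col.ref,
                alt=BASE_ALPHABET[code], alt_count=alt_count, depth=depth,
                vaf=vaf, tier=col.tier, p_value=p, sample_id=sample_id))
    return out


def find_supporting_reads(reads: Sequence[ConsensusRead], call: VariantCall) -> List[ConsensusRead]:
    """Consensus reads carrying the call's alternate base at its position."""
    alt_code = encode_seq(call.alt)[0]
    out = []
    for r in reads:
        if r.contig == call.contig and r.start <= call.position < r.end:
            if r.seq[call.position - r.start] == alt_code:
                out.append(r)
    return out


def softclip_filter(call: VariantCall, supporting_reads: Sequence[ConsensusRead]) -> VariantCall:
    """Flag calls whose every mutant-supporting read is soft-clipped.

    A call with no recorded supporting reads is flagged conservatively: the
    requirement is at least one unclipped mutant read.
    """
    call.softclip_fail = (not supporting_reads) or all(r.softclip for r in supporting_reads)
    return call


def recurrence_flag(calls: Sequence[VariantCall], threshold: int = 10) -> List[VariantCall]:
    """Flag variants recurring in more than ``threshold`` samples.

    Flags mark the region for manual assessment; nothing is removed.
    """
    samples_by_site: Dict[Tuple[str, int, str], set] = {}
    for c in calls:
        samples_by_site.setdefault((c.contig, c.position, c.alt), set()).add(c.sample_id)
    for c in calls:
        c.recurrent_region = len(samples_by_site[(c.contig, c.position, c.alt)]) > threshold
    return list(calls)


_BLACKLIST_REASONS = {"AC0_RF", "common"}


def load_blacklist(path) -> Dict[Tuple[str, int, str, str], str]:
    """Load a population blacklist TSV: contig, position(1-based), ref, alt, reason.

    Reasons mirror the database cross-checks: ``AC0_RF`` (failed AC0 or the
    random-forest filter in both genome and exome data) and ``common``
    (common population variant).
    """
    table: Dict[Tuple[str, int, str, str], str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"blacklist line {ln}: expected 5 columns, got {len(parts)}")
            contig, pos_s, ref, alt, reason = parts
            if reason not in _BLACKLIST_REASONS:
                raise ValueError(f"blacklist line {ln}: unknown reason {reason!r}")
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"blacklist line {ln}: bad position {pos_s!r}") from exc
            table[(contig, pos - 1, ref.upper(), alt.upper())] = reason
    return table


def population_filter(call: VariantCall, blacklist: Mapping[Tuple[str, int, str, str], str]) -> VariantCall:
    """Flag calls present in the population blacklist; reason is recorded."""
    reason = blacklist.get(call.key)
    call.population_db = reason is not None
    call.population_reason = reason
    return call


@dataclass
class RescueEstimate:
    """SSCS-tier VAF estimate for an a-priori target (no calling thresholds)."""

    contig: str
    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    vaf: float
    status: str  # "ok" | "uncovered"


def sscs_rescue(
    targets: Sequence[Tuple[str, int, str, str]],
    sscs_columns: Sequence[PileupColumn],
) -> List[RescueEstimate]:
    """Estimate VAFs for known variants directly from an SSCS pileup.

    Used when a timepoint's duplex coverage is too low for calling (e.g.
    relapse variants queried back at earlier samples): every target is
    reported, including zero-alt targets (VAF 0); targets outside covered
    positions come back with status ``uncovered``.
    """
    by_pos = {(c.contig, c.position): c for c in sscs_columns}
    out = []
    for contig, pos, ref, alt in targets:
        col = by_pos.get((contig, pos))
        if col is None or col.depth == 0:
            out.append(RescueEstimate(contig, pos, ref, alt, 0, 0, 0.0, "uncovered"))
            continue
        alt_count = col.count(alt)
        out.append(RescueEstimate(
            contig, pos, ref, alt, alt_count, col.depth, alt_count / col.depth, "ok"))
    return out
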