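"""SAM and VCF import/export for simulated reads, consensus reads and calls.

Custom SAM tags: RX = barcode pair ("TAGA-TAGB" in observed order), MI =
fragment id, XO = tag orientation (ab/ba), XC = soft-clip flag, XT =
consensus tier, XF/XG = strand family sizes, XA = per-base agreement.
Coordinates are 0-based half-open in memory and 1-based in VCF output.
"""
from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pysam

from .calls import VariantCall
from .consensus import ConsensusRead, family_key
from .seq import TaggedRead, encode_seq
from .simulate import TargetPanel

__all__ = [
    "sam_header",
    "write_reads_sam",
    "read_tagged_reads",
    "write_consensus_sam",
    "read_consensus_sam",
    "write_truth_vcf",
    "write_calls_vcf",
]


def sam_header(panel: TargetPanel) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.contig, "LN": r.end} for r in panel.regions],
    })


def _segment(header: pysam.AlignmentHeader, name: str, contig: str, start: int,
             seq: str, quality: int = 37) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.reference_id = header.get_tid(contig)
    seg.reference_start = start
    seg.mapping_quality = 60
    seg.cigartuples = [(0, len(seq))]
    seg.query_sequence = seq
    seg.query_qualities = pysam.qualitystring_to_array(chr(quality + 33) * len(seq))
    return seg


def write_reads_sam(path, reads: Iterable[TaggedRead], panel: TargetPanel,
                    quality: int = 37) -> None:
    """Write tagged raw reads as plain-text SAM."""
    header = sam_header(panel)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = _segment(header, r.name, r.contig, r.start, r.sequence, quality)
            seg.set_tag("RX", f"{r.tag_a}-{r.tag_b}")
            seg.set_tag("XO", r.orientation)
            seg.set_tag("XC", int(r.softclip))
            if r.fragment_id is not None:
                seg.set_tag("MI", str(r.fragment_id))
            out.write(seg)


def read_tagged_reads(path) -> List[TaggedRead]:
    """Load tagged reads from SAM; reads lacking the RX tag get empty tags."""
    reads: List[TaggedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            tag_a = tag_b = None
            if seg.has_tag("RX"):
                rx = str(seg.get_tag("RX"))
                if "-" in rx:
                    tag_a, tag_b = rx.split("-", 1)
            frag = int(seg.get_tag("MI")) if seg.has_tag("MI") else None
            reads.append(TaggedRead(
                name=seg.query_name,
                contig=seg.reference_name,
                start=seg.reference_start,
                end=seg.reference_start + len(seg.query_sequence),
                seq=encode_seq(seg.query_sequence),
                tag_a=tag_a, tag_b=tag_b,
                orientation=str(seg.get_tag("XO")) if seg.has_tag("XO") else "ab",
                softclip=bool(seg.get_tag("XC")) if seg.has_tag("XC") else False,
                fragment_id=frag,
            ))
    return reads


def write_consensus_sam(path, reads: Iterable[ConsensusRead], panel: TargetPanel) -> None:
    header = sam_header(panel)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = _segment(header, r.name, r.contig, r.start, r.sequence)
            seg.set_tag("XT", r.tier)
            seg.set_tag("XF", int(r.family_size))
            if r.family_size_b is not None:
                seg.set_tag("XG", int(r.family_size_b))
            seg.set_tag("XC", int(r.softclip))
            seg.set_tag("XA", [float(a) for a in r.agreement])
            if r.key is not None:
                seg.set_tag("RX", f"{r.key.tags[0]}-{r.key.tags[1]}")
                seg.set_tag("XO", "ab" if r.key.orientation == 0 else "ba")
            out.write(seg)


def read_consensus_sam(path) -> List[ConsensusRead]:
    reads: List[ConsensusRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            seq = encode_seq(seg.query_sequence)
            if seg.has_tag("XA"):
                agreement = np.array(seg.get_tag("XA"), dtype=float)
            else:
                agreement = np.ones(seq.size)
            key = None
            if seg.has_tag("RX") and seg.has_tag("XO"):
                a, b = str(seg.get_tag("RX")).split("-", 1)
                dummy = TaggedRead(
                    name=seg.query_name, contig=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_start + seq.size, seq=seq,
                    tag_a=a if seg.get_tag("XO") == "ab" else b,
                    tag_b=b if seg.get_tag("XO") == "ab" else a,
                    orientation=str(seg.get_tag("XO")))
                key = family_key(dummy)
            reads.append(ConsensusRead(
                name=seg.query_name, tier=str(seg.get_tag("XT")),
                contig=seg.reference_name, start=seg.reference_start,
                end=seg.reference_start + seq.size, seq=seq, agreement=agreement,
                family_size=int(seg.get_tag("XF")),
                family_size_b=int(seg.get_tag("XG")) if seg.has_tag("XG") else None,
                key=key,
                softclip=bool(seg.get_tag("XC")) if seg.has_tag("XC") else False,
            ))
    return reads


def _vcf_header_lines(panel: TargetPanel, extra: Sequence[str]) -> List[str]:
    lines = ["##fileformat=VCFv4.2", "##source=dupliseq"]
    lines += [f"##contig=<ID={r.contig},length={r.end}>" for r in panel.regions]
    lines += list(extra)
    return lines


def write_truth_vcf(path, truth, panel: TargetPanel) -> None:
    """Write the simulator truth table as VCF (INFO: TRUE_VAF, CLONE, counts)."""
    extra = [
        '##INFO=<ID=TRUE_VAF,Number=1,Type=Float,Description="True VAF from the clone tree">',
        '##INFO=<ID=REALIZED_VAF,Number=1,Type=Float,Description="Mutant/total molecules among simulated fragments">',
        '##INFO=<ID=CLONE,Number=1,Type=String,Description="Clone of origin">',
        '##INFO=<ID=MUT_MOL,Number=1,Type=Integer,Description="Mutant molecules simulated">',
        '##INFO=<ID=TOT_MOL,Number=1,Type=Integer,Description="Total molecules simulated">',
    ]
    with open(path, "w") as fh:
        for line in _vcf_header_lines(panel, extra):
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in truth.itertuples():
            info = (f"TRUE_VAF={row.true_vaf:.6g};REALIZED_VAF={row.realized_vaf:.6g};"
                    f"CLONE={row.clone};MUT_MOL={row.mutant_molecules};"
                    f"TOT_MOL={row.total_molecules}")
            fh.write(f"{row.contig}\t{row.position + 1}\t{row.variant_id}\t"
                     f"{row.ref}\t{row.alt}\t.\tPASS\t{info}\n")


def write_calls_vcf(path, calls: Sequence[VariantCall], panel: TargetPanel,
                    sample_id: Optional[str] = None) -> None:
    """Write variant calls as single-sample VCF with filter flags."""
    extra = [
        '##FILTER=<ID=softclip_fail,Description="All mutant-supporting reads soft-clipped">',
        '##FILTER=<ID=recurrent_region,Description="Variant recurs in more samples than the recurrence threshold">',
        '##FILTER=<ID=population_db,Description="Present in the population blacklist">',
        '##FILTER=<ID=low_qual,Description="Below quality threshold">',
        '##INFO=<ID=TIER,Number=1,Type=String,Description="Consensus tier (SSCS/DCS)">',
        '##INFO=<ID=PVAL,Number=1,Type=Float,Description="One-sided binomial p against background error">',
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alternate allele count">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=VF,Number=1,Type=Float,Description="Variant allele frequency">',
    ]
    sample = sample_id or (calls[0].sample_id if calls and calls[0].sample_id else "SAMPLE")
    with open(path, "w") as fh:
        for line in _vcf_header_lines(panel, extra):
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.position, c.alt)):
            filt = ";".join(c.filters) or "PASS"
            info = f"TIER={c.tier};PVAL={c.p_value:.3g}"
            fh.write(f"{c.contig}\t{c.position + 1}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t"
                     f"{info}\tAD:DP:VF\t{c.alt_count}:{c.depth}:{c.vaf:.6g}\n")
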