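"""Synthetic duplex-sequencing data generation.

Everything downstream of library preparation is testable without real data:
this module builds a targeted panel, a rooted clone hierarchy with
per-timepoint cellular prevalences, somatic SNVs assigned to clones, and
barcode-tagged duplex read families with separate pre-barcode (PCR on the
original molecule, shared by all reads of one strand) and post-barcode
(amplification + sequencing, private to each read) substitution error
processes. A truth table accompanies every simulation so recovery can be
scored exactly.

Cellular prevalences are *inclusive* (fishplot convention): a clone's
prevalence counts its own cells plus all descendant cells, so children sum
to at most their parent. For a heterozygous diploid locus the true VAF of a
mutation is half the inclusive prevalence of its clone of origin.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .seq import TaggedRead, decode_seq, encode_seq

__all__ = [
    "GENE_LABELS",
    "Region",
    "TargetPanel",
    "Clone",
    "CloneTree",
    "CloneTreeError",
    "SomaticVariant",
    "FamilySizeModel",
    "SimulationConfig",
    "DuplexFragment",
    "generate_panel",
    "generate_clone_tree",
    "assign_variants",
    "simulate_families",
    "simulate_trajectory_matrix",
    "fragments_to_reads",
]

# 28 gene labels mirroring a leukemia hotspot panel: PI3K/RAS and other genes
# recurrently mutated in KMT2A-rearranged ALL, padded with common leukemia genes.
GENE_LABELS = (
    "KRAS", "NRAS", "FLT3", "TP53", "PIK3CA", "PAX5", "PIK3R1", "PTPN11",
    "SRSF2", "CEBPA", "NPM1", "CRLF2", "IKZF1", "JAK2", "JAK3", "KMT2D",
    "CREBBP", "SETD2", "NT5C2", "NSD2", "EZH2", "ABL1", "RUNX1", "ETV6",
    "GATA3", "IL7R", "SH2B3", "WT1",
)


@dataclass(frozen=True)
class Region:
    """One capture-probe target region (0-based half-open coordinates)."""

    contig: str
    start: int
    end: int
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.contig}: end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"region {self.contig}: sequence length mismatch")

    @property
    def length(self) -> int:
        return self.end - self.start


class TargetPanel:
    """A set of non-overlapping target regions with reference sequence."""

    def __init__(self, regions: Sequence[Region]):
        by_contig: Dict[str, List[Region]] = {}
        for r in regions:
            by_contig.setdefault(r.contig, []).append(r)
        for contig, rs in by_contig.items():
            rs.sort(key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping regions on contig {contig}")
        self.regions: List[Region] = sorted(regions, key=lambda r: (r.contig, r.start))
        self._by_contig = by_contig

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_span(self) -> int:
        return sum(r.length for r in self.regions)

    def region_for(self, contig: str, position: int) -> Optional[Region]:
        for r in self._by_contig.get(contig, ()):
            if r.start <= position < r.end:
                return r
        return None

    def ref_base(self, contig: str, position: int) -> str:
        r = self.region_for(contig, position)
        if r is None:
            raise KeyError(f"{contig}:{position} not covered by panel")
        return r.sequence[position - r.start]

    # -- I/O ---------------------------------------------------------------
    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.gene}\n")

    def to_fasta(self, path) -> None:
        """Write contig sequences. Only valid when every region starts at 0."""
        with open(path, "w") as fh:
            for r in self.regions:
                if r.start != 0:
                    raise ValueError("to_fasta requires regions anchored at position 0")
                fh.write(f">{r.contig}\n{r.sequence}\n")

    @classmethod
    def from_bed(cls, bed_path, fasta_path) -> "TargetPanel":
        """Load a panel from a BED (contig, start, end, gene) plus a FASTA."""
        import pyfaidx

        fasta = pyfaidx.Fasta(str(fasta_path))
        regions = []
        with open(bed_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
                gene = parts[3] if len(parts) > 3 else contig
                seq = str(fasta[contig][start:end]).upper()
                regions.append(Region(contig, start, end, gene, seq))
        return cls(regions)


def generate_panel(n_regions: int, region_length: int, seed: int) -> TargetPanel:
    """Generate a reproducible random panel of ``n_regions`` equal-length regions.

    Gene labels cycle through the 28 panel genes so that 71 regions mirror the
    study-scale layout (71 probes over 28 genes, ~6.3 kb).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if region_length < 20:
        raise ValueError("region_length must be >= 20")
    rng = np.random.default_rng(seed)
    regions = []
    for i in range(n_regions):
        gene = GENE_LABELS[i % len(GENE_LABELS)]
        contig = f"{gene}_p{i + 1:02d}"
        seq = decode_seq(rng.integers(0, 4, size=region_length).astype(np.uint8))
        regions.append(Region(contig, 0, region_length, gene, seq))
    return TargetPanel(regions)


# ---------------------------------------------------------------------------
# Clone trees
# ---------------------------------------------------------------------------

class CloneTreeError(ValueError):
    """Raised when a clone hierarchy violates its structural constraints."""


@dataclass
class Clone:
    id: str
    parent: Optional[str]
    prevalence: Dict[Hashable, float]
    mutations: List[str] = field(default_factory=list)  # mutations originating here


class CloneTree:
    """Rooted clone hierarchy with inclusive per-timepoint prevalences.

    ``validate=False`` skips the nesting (pigeonhole) check so that inferred
    trees with noisy prevalences can be represented; violations are then
    reported by :meth:`nesting_violations` instead of raised.
    """

    NESTING_TOL = 1e-9

    def __init__(self, clones: Sequence[Clone], timepoints: Sequence[Hashable],
                 validate: bool = True):
        self.timepoints = list(timepoints)
        if len(self.timepoints) == 0:
            raise CloneTreeError("at least one timepoint required")
        self.clones: Dict[str, Clone] = {}
        for c in clones:
            if c.id in self.clones:
                raise CloneTreeError(f"duplicate clone id {c.id!r}")
            self.clones[c.id] = c
        roots = [c.id for c in clones if c.parent is None]
        if len(roots) != 1:
            raise CloneTreeError(f"expected exactly one root clone, found {len(roots)}")
        self.root = roots[0]
        for c in clones:
            if c.parent is not None and c.parent not in self.clones:
                raise CloneTreeError(f"clone {c.id!r} has unknown parent {c.parent!r}")
            missing = [t for t in self.timepoints if t not in c.prevalence]
            if missing:
                raise CloneTreeError(f"clone {c.id!r} missing prevalence at {missing}")
            for t, p in c.prevalence.items():
                if not (0.0 <= p <= 1.0):
                    raise CloneTreeError(f"clone {c.id!r} prevalence {p} at {t} outside [0,1]")
        self._check_acyclic()
        if validate:
            violations = self.nesting_violations()
            if violations:
                raise CloneTreeError("; ".join(violations))

    def _check_acyclic(self) -> None:
        for cid in self.clones:
            seen = set()
            cur: Optional[str] = cid
            while cur is not None:
                if cur in seen:
                    raise CloneTreeError(f"cycle detected through clone {cur!r}")
                seen.add(cur)
                cur = self.clones[cur].parent

    # -- structure ---------------------------------------------------------
    def children(self, clone_id: str) -> List[str]:
        return [c.id for c in self.clones.values() if c.parent == clone_id]

    def descendants(self, clone_id: str) -> List[str]:
        out: List[str] = []
        stack = self.children(clone_id)
        while stack:
            cid = stack.pop()
            out.append(cid)
            stack.extend(self.children(cid))
        return out

    def ancestors(self, clone_id: str) -> List[str]:
        out: List[str] = []
        cur = self.clones[clone_id].parent
        while cur is not None:
            out.append(cur)
            cur = self.clones[cur].parent
        return out

    def nesting_violations(self, tol: float = NESTING_TOL) -> List[str]:
        """Check children-sum-within-parent and root <= 1 at every timepoint."""
        out = []
        for t in self.timepoints:
            if self.clones[self.root].prevalence[t] > 1.0 + tol:
                out.append(f"root prevalence exceeds 1 at timepoint {t}")
            for cid, clone in self.clones.items():
                kids = self.children(cid)
                if not kids:
                    continue
                s = sum(self.clones[k].prevalence[t] for k in kids)
                if s > clone.prevalence[t] + tol:
                    out.append(
                        f"children of {cid!r} sum to {s:.6g} > parent {clone.prevalence[t]:.6g}"
                        f" at timepoint {t}"
                    )
        return out

    def exclusive_prevalence(self, clone_id: str, timepoint: Hashable) -> float:
        """Fraction of cells whose most-derived clone is ``clone_id``."""
        p = self.clones[clone_id].prevalence[timepoint]
        for k in self.children(clone_id):
            p -= self.clones[k].prevalence[timepoint]
        return max(p, 0.0)

    def normal_fraction(self, timepoint: Hashable) -> float:
        return max(1.0 - self.clones[self.root].prevalence[timepoint], 0.0)

    def carried_mutations(self, clone_id: str) -> List[str]:
        """Mutations carried by cells of this clone (own + ancestral)."""
        out = list(self.clones[clone_id].mutations)
        for a in self.ancestors(clone_id):
            out.extend(self.clones[a].mutations)
        return out

    def clone_of_mutation(self, mutation_id: str) -> str:
        for cid, clone in self.clones.items():
            if mutation_id in clone.mutations:
                return cid
        raise KeyError(mutation_id)

    # -- export ------------------------------------------------------------
    def to_newick(self) -> str:
        def render(cid: str) -> str:
            kids = sorted(self.children(cid))
            if not kids:
                return cid
            return "(" + ",".join(render(k) for k in kids) + ")" + cid

        return render(self.root) + ";"

    def to_fishplot_frame(self) -> pd.DataFrame:
        """Long-format (clone, timepoint, prevalence, parent) table."""
        rows = [
            {"clone": cid, "timepoint": t,
             "prevalence": clone.prevalence[t], "parent": clone.parent or ""}
            for cid, clone in self.clones.items() for t in self.timepoints
        ]
        return pd.DataFrame(rows)


def generate_clone_tree(
    spec: Sequence[Tuple[str, Optional[str], Mapping[Hashable, float]]],
    timepoints: Sequence[Hashable],
) -> CloneTree:
    """Build and validate a clone tree from (id, parent, prevalence-map) rows."""
    clones = [Clone(cid, parent, dict(prev)) for cid, parent, prev in spec]
    return CloneTree(clones, timepoints, validate=True)


# ---------------------------------------------------------------------------
# Somatic variants
# ---------------------------------------------------------------------------

@dataclass
class SomaticVariant:
    """A heterozygous somatic SNV with its clone of origin and true VAFs."""

    id: str
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    clone: str
    vaf: Dict[Hashable, float]  # true VAF per timepoint (inclusive prevalence / 2)


def assign_variants(
    tree: CloneTree,
    panel: TargetPanel,
    per_clone_counts: Mapping[str, int],
    hotspots: Optional[Sequence[Tuple[str, int, str, str]]] = None,
    seed: int = 0,
) -> List[SomaticVariant]:
    """Place somatic SNVs on panel positions and assign each to one clone.

    Hotspots are (gene, position, ref, alt) tuples pinned to specific panel
    sites; they are consumed in order by the clones in ``per_clone_counts``
    iteration order before random positions fill the remaining counts. True
    per-timepoint VAFs are half the inclusive prevalence of the clone of
    origin (heterozygous diploid).
    """
    rng = np.random.default_rng(seed)
    for cid, n in per_clone_counts.items():
        if cid not in tree.clones:
            raise KeyError(f"unknown clone {cid!r}")
        if n < 0:
            raise ValueError("variant counts must be >= 0")

    hotspot_queue = list(hotspots or [])
    all_sites = [(r, off) for r in panel.regions for off in range(r.length)]
    rng.shuffle(all_sites)
    used_positions: set = set()
    variants: List[SomaticVariant] = []

    def add_variant(region: Region, offset: int, ref: str, alt: str, clone_id: str) -> None:
        key = (region.contig, region.start + offset, alt)
        if key in used_positions:
            raise ValueError(f"duplicate variant at {key}")
        used_positions.add(key)
        pos = region.start + offset
        vid = f"{region.gene}_{region.contig}:{pos + 1}{ref}>{alt}"
        vafs = {t: tree.clones[clone_id].prevalence[t] / 2.0 for t in tree.timepoints}
        variants.append(SomaticVariant(vid, region.contig, pos, ref, alt, clone_id, vafs))
        tree.clones[clone_id].mutations.append(vid)

    site_iter = iter(all_sites)
    for clone_id, count in per_clone_counts.items():
        for _ in range(count):
            if hotspot_queue:
                gene, pos, ref, alt = hotspot_queue.pop(0)
                region = next((r for r in panel.regions
                               if r.gene == gene and r.start <= pos < r.end), None)
                if region is None:
                    raise ValueError(f"hotspot {gene}:{pos} outside panel")
                offset = pos - region.start
                if region.sequence[offset] != ref:
                    raise ValueError(
                        f"hotspot ref mismatch at {gene}:{pos}: panel has "
                        f"{region.sequence[offset]}, hotspot says {ref}")
                add_variant(region, offset, ref, alt, clone_id)
                continue
            for region, offset in site_iter:
                key_any = (region.contig, region.start + offset)
                if any(k[:2] == key_any for k in used_positions):
                    continue
                ref = region.sequence[offset]
                alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
                add_variant(region, offset, ref, alt, clone_id)
                break
            else:
                raise ValueError("panel exhausted: too many variants requested")
    return variants


# ---------------------------------------------------------------------------
# Duplex read families
# ---------------------------------------------------------------------------

@dataclass
class FamilySizeModel:
    """Distribution of raw reads per strand family.

    ``ztnb``: zero-truncated negative binomial (mean/shape are the parameters
    of the untruncated law). ``constant``: every family has exactly ``size``
    reads, useful for forcing degenerate cases.
    """

    kind: str = "ztnb"
    mean: float = 5.0
    shape: float = 2.0
    size: int = 1

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, int(self.size), dtype=np.int64)
        if self.kind != "ztnb":
            raise ValueError(f"unknown family-size model {self.kind!r}")
        p = self.shape / (self.shape + self.mean)
        out = rng.negative_binomial(self.shape, p, size=n)
        zero = out == 0
        while zero.any():  # zero-truncation by resampling
            out[zero] = rng.negative_binomial(self.shape, p, size=int(zero.sum()))
            zero = out == 0
        return out.astype(np.int64)


@dataclass
class SimulationConfig:
    """Library-scale parameters of one simulated duplex experiment."""

    input_mass_ng: float = 250.0
    genome_mass_pg: float = 6.6  # mass of one diploid human genome
    capture_efficiency: float = 1.0
    family_size: FamilySizeModel = field(default_factory=FamilySizeModel)
    pre_barcode_error: float = 1e-3   # per base, once per strand template
    post_barcode_error: float = 1e-3  # per base, independently per read
    barcode_length: int = 12
    softclip_fraction: float = 0.0
    base_quality: int = 37
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("pre_barcode_error", "post_barcode_error"):
            e = getattr(self, name)
            if not (0.0 <= e < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.input_mass_ng <= 0 or self.genome_mass_pg <= 0:
            raise ValueError("masses must be positive")
        if not (0.0 < self.capture_efficiency <= 1.0):
            raise ValueError("capture_efficiency must be in (0, 1]")

    @property
    def genome_equivalents(self) -> float:
        """Number of genome copies in the input mass (1 ng = 1000 pg)."""
        return self.input_mass_ng * 1000.0 / self.genome_mass_pg

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        fs = d.pop("family_size", None)
        cfg = cls(**d)
        if fs is not None:
            cfg.family_size = FamilySizeModel(**fs)
        return cfg


@dataclass
class DuplexFragment:
    """One original double-stranded molecule and its raw reads.

    Both strands share the molecule's true allele sequence; pre-barcode
    errors are recorded per strand (they propagate to every read of that
    strand) and post-barcode errors per read, so tests can verify the two
    error processes by inspection.
    """

    id: int
    contig: str
    start: int
    end: int
    tag_a: str
    tag_b: str
    clone: Optional[str]  # None = normal (non-leukemic) cell
    variant_ids: Tuple[str, ...]
    true_seq: np.ndarray
    top_reads: np.ndarray      # (n_top, L) uint8
    bottom_reads: np.ndarray   # (n_bottom, L) uint8
    top_softclip: np.ndarray
    bottom_softclip: np.ndarray
    top_pre_errors: np.ndarray     # positions mutated on the top template
    bottom_pre_errors: np.ndarray
    top_post_errors: List[np.ndarray]    # per-read positions
    bottom_post_errors: List[np.ndarray]

    @property
    def n_reads(self) -> int:
        return int(self.top_reads.shape[0] + self.bottom_reads.shape[0])


def _mutate(rng: np.random.Generator, codes: np.ndarray, positions: np.ndarray) -> None:
    """Substitute each listed position with a uniformly random *different* base."""
    if positions.size:
        codes[positions] = (codes[positions] + rng.integers(1, 4, size=positions.size)) % 4


def simulate_families(
    panel: TargetPanel,
    variants: Sequence[SomaticVariant],
    tree: CloneTree,
    timepoint: Hashable,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> Tuple[List[DuplexFragment], pd.DataFrame]:
    """Simulate barcoded duplex read families for one timepoint.

    Per region the number of fragments equals the captured genome
    equivalents (``input mass x 1000 / genome mass x capture efficiency``).
    Each fragment's source cell is drawn from the clone exclusive
    prevalences (plus normal cells); heterozygous variants sit on one of the
    two alleles. Returns the fragments and an exact truth table with, per
    variant, the expected VAF from the tree and the realised molecular VAF
    (mutant molecules / total molecules, exact).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    if timepoint not in tree.timepoints:
        raise KeyError(f"timepoint {timepoint!r} not in tree")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_frag = int(round(config.genome_equivalents * config.capture_efficiency))
    if n_frag < 1:
        raise ValueError("configuration yields zero fragments per region")

    clone_ids = list(tree.clones)
    probs = np.array([tree.exclusive_prevalence(c, timepoint) for c in clone_ids]
                     + [tree.normal_fraction(timepoint)])
    probs = probs / probs.sum()
    carriers = {v.id: {v.clone, *tree.descendants(v.clone)} for v in variants}
    variants_by_contig: Dict[str, List[SomaticVariant]] = {}
    for v in variants:
        if panel.region_for(v.contig, v.position) is None:
            raise ValueError(f"variant {v.id} outside panel")
        variants_by_contig.setdefault(v.contig, []).append(v)

    fragments: List[DuplexFragment] = []
    mutant_count = {v.id: 0 for v in variants}
    total_count = {v.id: 0 for v in variants}
    frag_id = 0

    for region in panel.regions:
        L = region.length
        ref_codes = encode_seq(region.sequence)
        region_variants = variants_by_contig.get(region.contig, [])

        clone_idx = rng.choice(len(probs), size=n_frag, p=probs)
        # per fragment x region-variant: does this molecule carry the alt allele?
        present = np.zeros((n_frag, len(region_variants)), dtype=bool)
        for j, v in enumerate(region_variants):
            carrier = np.array([clone_ids[k] in carriers[v.id] if k < len(clone_ids)
                                else False for k in clone_idx])
            allele = rng.random(n_frag) < 0.5
            present[:, j] = carrier & allele
            mutant_count[v.id] += int(present[:, j].sum())
            total_count[v.id] += n_frag

        sizes_top = config.family_size.sample(rng, n_frag)
        sizes_bot = config.family_size.sample(rng, n_frag)
        barcodes = rng.integers(0, 4, size=(n_frag, 2, config.barcode_length)).astype(np.uint8)

        # bulk error masks: pre-barcode per strand template, post per read
        pre_top = rng.random((n_frag, L)) < config.pre_barcode_error
        pre_bot = rng.random((n_frag, L)) < config.pre_barcode_error
        post_top_all = rng.random((int(sizes_top.sum()), L)) < config.post_barcode_error
        post_bot_all = rng.random((int(sizes_bot.sum()), L)) < config.post_barcode_error
        off_top = np.concatenate([[0], np.cumsum(sizes_top)])
        off_bot = np.concatenate([[0], np.cumsum(sizes_bot)])

        sc_top_all = rng.random(int(sizes_top.sum())) < config.softclip_fraction
        sc_bot_all = rng.random(int(sizes_bot.sum())) < config.softclip_fraction

        for i in range(n_frag):
            true_seq = ref_codes.copy()
            vids = []
            for j, v in enumerate(region_variants):
                if present[i, j]:
                    true_seq[v.position - region.start] = encode_seq(v.alt)[0]
                    vids.append(v.id)

            strand_data = []
            for pre_mask, post_all, lo, hi, sc_all in (
                (pre_top[i], post_top_all, off_top[i], off_top[i + 1], sc_top_all),
                (pre_bot[i], post_bot_all, off_bot[i], off_bot[i + 1], sc_bot_all),
            ):
                template = true_seq.copy()
                pre_pos = np.flatnonzero(pre_mask)
                _mutate(rng, template, pre_pos)
                n_reads = hi - lo
                reads = np.repeat(template[None, :], n_reads, axis=0)
                post = post_all[lo:hi]
                post_positions = []
                for k in range(n_reads):
                    pos = np.flatnonzero(post[k])
                    _mutate(rng, reads[k], pos)
                    post_positions.append(pos)
                strand_data.append((reads, pre_pos, post_positions, sc_all[lo:hi].copy()))

            (top_reads, top_pre, top_post, top_sc), (bot_reads, bot_pre, bot_post, bot_sc) = strand_data
            clone = clone_ids[clone_idx[i]] if clone_idx[i] < len(clone_ids) else None
            fragments.append(DuplexFragment(
                id=frag_id, contig=region.contig, start=region.start, end=region.end,
                tag_a=decode_seq(barcodes[i, 0]), tag_b=decode_seq(barcodes[i, 1]),
                clone=clone, variant_ids=tuple(vids), true_seq=true_seq,
                top_reads=top_reads, bottom_reads=bot_reads,
                top_softclip=top_sc, bottom_softclip=bot_sc,
                top_pre_errors=top_pre, bottom_pre_errors=bot_pre,
                top_post_errors=top_post, bottom_post_errors=bot_post,
            ))
            frag_id += 1

    truth = pd.DataFrame([
        {
            "variant_id": v.id, "contig": v.contig, "position": v.position,
            "ref": v.ref, "alt": v.alt, "clone": v.clone,
            "true_vaf": v.vaf[timepoint],
            "mutant_molecules": mutant_count[v.id],
            "total_molecules": total_count[v.id],
            "realized_vaf": (mutant_count[v.id] / total_count[v.id]
                             if total_count[v.id] else float("nan")),
        }
        for v in variants
    ])
    return fragments, truth


def simulate_trajectory_matrix(
    tree: CloneTree,
    per_clone_counts: Mapping[str, int],
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Generate a mutations x timepoints VAF table directly from a clone tree.

    Each clone contributes ``per_clone_counts[clone]`` mutations whose true
    VAF is half the clone's inclusive prevalence; observed VAFs carry
    multiplicative lognormal noise ``exp(sigma * Z)`` (zero stays zero).
    Returns the frame and the true mutation-to-clone assignment.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rows = {}
    truth: Dict[str, str] = {}
    for cid, count in per_clone_counts.items():
        if cid not in tree.clones:
            raise KeyError(f"unknown clone {cid!r}")
        prev = tree.clones[cid].prevalence
        for k in range(count):
            mid = f"{cid}_m{k + 1}"
            vafs = []
            for t in tree.timepoints:
                true = prev[t] / 2.0
                obs = true * float(np.exp(noise_sigma * rng.standard_normal())) if true > 0 else 0.0
                vafs.append(min(obs, 1.0))
            rows[mid] = vafs
            truth[mid] = cid
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(tree.timepoints))
    return frame, truth


def fragments_to_reads(fragments: Iterable[DuplexFragment]) -> List[TaggedRead]:
    """Flatten fragments into tagged raw reads (the SAM-level view).

    Bottom-strand reads see the barcode pair in the opposite order, which is
    how the two strand families of one molecule are later re-paired.
    """
    reads: List[TaggedRead] = []
    for f in fragments:
        for k in range(f.top_reads.shape[0]):
            reads.append(TaggedRead(
                name=f"frag{f.id}_t{k}", contig=f.contig, start=f.start, end=f.end,
                seq=f.top_reads[k], tag_a=f.tag_a, tag_b=f.tag_b, orientation="ab",
                softclip=bool(f.top_softclip[k]), fragment_id=f.id))
        for k in range(f.bottom_reads.shape[0]):
            reads.append(TaggedRead(
                name=f"frag{f.id}_b{k}", contig=f.contig, start=f.start, end=f.end,
                seq=f.bottom_reads[k], tag_a=f.tag_b, tag_b=f.tag_a, orientation="ba",
                softclip=bool(f.bottom_softclip[k]), fragment_id=f.id))
    return reads
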