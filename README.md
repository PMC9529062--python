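# dupliseq

Duplex-sequencing simulation, consensus error correction, low-VAF variant
calling and subclonal evolution tracking for targeted leukemia panels.

## The problem

Standard next-generation sequencing resolves somatic mutations down to a
variant allele frequency (VAF) of roughly 0.01–0.05. In KMT2A-rearranged
infant and childhood acute lymphoblastic leukemia, most cancer-associated
mutations — including drug-resistant PI3K/RAS subclones that later drive
relapse — sit far below that, at VAFs of 10⁻⁴–10⁻². Duplex sequencing
reaches them by tagging both strands of every input DNA molecule: reads
sharing a barcode and strand collapse into a single-strand consensus (SSCS),
and the two strand consensuses of one molecule reconcile into a duplex
consensus (DCS) in which read-private sequencing errors and strand-private
PCR errors have both cancelled.

`dupliseq` implements that analysis chain end to end as a tested Python
library, together with a synthetic-data generator so every stage can be
validated against exact truth without any patient data:

- **simulate** — targeted panels, rooted clone trees with per-timepoint
  cellular prevalences, heterozygous somatic SNVs, and barcode-tagged duplex
  read families with separate pre-barcode (PCR) and post-barcode
  (amplification + sequencing) error processes, plus exact truth tables.
- **consensus** — family grouping by canonical barcode pair, homopolymer
  barcode filtering, SSCS building (agreement cutoff 0.7, family size 3–200),
  duplex pairing, and 5-bp end trimming.
- **calls** — pileup with a deterministic 30,000× depth cap, VarScan-style
  thresholded calling (duplex, deep-panel and amplicon presets), a one-sided
  binomial gate against a background error rate, and annotate-only artifact
  filters (soft-clip support, cross-sample recurrence, population blacklist),
  plus SSCS-tier rescue of known variants below the calling thresholds.
- **annotate** — cancer-association lookup (PeCan / COSMIC tier 1–3 /
  COSMIC reported >5×), VAF → cellular prevalence (prevalence = 2·VAF for a
  heterozygous diploid locus), detectability tiers (>0.3 / 0.05–0.3 /
  0.01–0.05 / <0.01), and input-mass detection limits.
- **clones** — hierarchical clustering of log₁₀ VAF trajectories into clones
  (≥2 mutations per clone), clone-tree assembly by prevalence containment,
  and selective-sweep detection (minor → dominant).
- **cohort** — Mann-Whitney U comparisons (exact enumeration for small
  cohorts), VAF-threshold fractions, 96-channel trinucleotide spectra and
  non-negative least-squares signature refitting.

Key identities used throughout: cellular prevalence (% of cells) =
200 × VAF for a heterozygous diploid locus; genome equivalents =
input mass (ng) × 1000 / 6.6 pg per diploid genome, so 250 ng ≈ 37,879 ≈
40,000 cell equivalents — the hard ceiling on detectable clone size.

## Worked example

`examples/05_track_clones.py` simulates a six-timepoint longitudinal design
(days 0–208) with four clones — founder A, major clone B, a subclone C lost
during treatment, and a subclone D at 0.2% of cells at diagnosis — then
clusters the mutation VAF trajectories, rebuilds the tree and scans for
sweeps:

```
16 mutation trajectories -> 4 clones (0 unassigned)
  C1: 4 mutations (true clone A), prevalence day0=0.9302 day208=0.971
  C2: 5 mutations (true clone B), prevalence day0=0.7978 day208=0.873
  C3: 4 mutations (true clone D), prevalence day0=0.0020 day208=0.824
  C4: 3 mutations (true clone C), prevalence day0=0.4405 day208=0.000

inferred tree: ((C3,C4)C2)C1;  (0 nesting violations)
selective sweep: clone C3 (true clone D) rose from 2.00% at day 173 to 82% at day 208

at diagnosis the sweeping clone was 0.25% of the major clone
```

Every inferred clone is pure (its mutations come from one true clone), the
branching topology A → B → {C, D} is recovered exactly, and the relapse
clone is flagged as a sweep: it stayed below 2% of cells for 173 days and
then expanded to dominance. `examples/03_consensus_error_correction.py`
shows the error-suppression chain the consensus machinery delivers
(per-base error 1.1×10⁻² in raw reads → 9×10⁻⁴ at SSCS → 0 observed at
DCS); the other examples cover simulation, low-VAF calling with SSCS
rescue, detection limits and cohort statistics.

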