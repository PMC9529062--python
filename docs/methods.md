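# Methods

This note records the models, parameter choices and numerical conventions
behind `dupliseq`, and what the synthetic-data generator does and does not
emulate.

## Simulation model

**Panel.** A target panel is a set of non-overlapping regions with uppercase
A/C/G/T reference sequence, 0-based half-open coordinates (1-based only in
VCF output). `generate_panel` draws i.i.d. random sequence and cycles gene
labels through 28 leukemia panel genes; the study-scale default (71 regions
× 89 nt ≈ 6.3 kb) mirrors a hotspot capture panel. Real panels enter through
`TargetPanel.from_bed` (BED + FASTA via pyfaidx).

**Clone trees.** Cellular prevalences are *inclusive* (fishplot convention):
a clone's prevalence counts its own cells plus all descendants, so the
structural constraints are: children sum to at most their parent at every
timepoint, and the root stays ≤ 1 (the remainder is non-leukemic). A
mutation originating in clone X therefore has true VAF =
inclusive_prevalence(X)/2 at a heterozygous diploid locus. The alternative
reading (exclusive prevalences summed over the descendant set) is
mathematically equivalent but interacts badly with the nesting constraint,
so the inclusive convention is used everywhere.

**Duplex families.** Per region, the number of double-stranded molecules is
the captured genome-equivalent count: mass(ng) × 1000 / genome mass(pg) ×
capture efficiency. The genome mass constant is 6.6 pg per diploid human
genome; it is what turns 250 ng into ~37,879 ≈ 40,000 cell equivalents.
Each molecule's source cell is drawn from the clones' exclusive prevalences
(plus normal cells); each heterozygous variant lands on one of the two
alleles with probability ½ independently (phasing between variants on one
molecule is not modelled). Errors are substitutions only:

- *pre-barcode* errors (first-round PCR) mutate the strand template once and
  propagate to every read of that strand family — they survive SSCS and die
  at the duplex step;
- *post-barcode* errors (amplification + sequencing) are applied
  independently per read — they die at the SSCS step.

Both error positions are recorded on the fragment so tests can verify the
two processes by direct inspection. Family sizes (reads per strand) follow a
zero-truncated negative binomial, mean 5, shape 2 by default; the published
pipelines report only that family size was "optimized", so these are this
package's own defaults, exposed in `SimulationConfig` together with a
degenerate constant-size option for forcing edge cases. Reads span their
whole region with explicit coordinates, so no aligner is needed; a
configurable fraction of reads is flagged soft-clipped solely to exercise
the soft-clip artifact filter. Truth tables record, per variant, the
expected VAF from the tree and the exact realised molecular VAF
(mutant molecules / total molecules).

*Not emulated:* indels/SVs/CNVs, fusion breakpoints, base-quality
variation, GC/capture bias, fragment-length variation, alignment and
soft-clipping artifacts beyond the boolean flag, and contamination. Passing
recovery tests therefore demonstrate correctness of the consensus/calling
arithmetic under the stated error model, not robustness to every real-data
failure mode.

## Consensus

Families are keyed by the canonical (sorted) barcode pair, an orientation
bit, and coordinates; the two strands of one molecule share everything but
the bit. Barcodes containing a homopolymer run ≥ `rep_filt` (default 9)
are discarded. SSCS building uses the standard duplex parameters: family
size ≥ `minmem` 3, down-sampling to `maxmem` 200, agreement cutoff 0.7.
Numerical conventions, chosen where the published parameters leave room:

- agreement exactly equal to the cutoff **passes** (≥, not >) — with family
  size 10 and 7 agreeing reads, a 0.7 cutoff must pass to be meaningful;
- `maxmem` down-sampling keeps the first `maxmem` reads after a stable sort
  by read name — deterministic and order-independent;
- raw-read Ns are excluded from both numerator and denominator of the
  agreement fraction (the default simulator emits none);
- a consensus whose N fraction exceeds `max_n_fraction` (default 0.3) is
  discarded;
- DCS requires **both** strand families to independently pass `minmem`
  (the stricter reading of duplex support), keeps bases only where the two
  SSCS agree and neither is N, and inherits a soft-clip flag only when both
  strands are flagged;
- consensus reads carry a fixed nominal base quality;
- 5 bp are trimmed from each end of every consensus read after collapsing.

With per-read error e and family size n, an SSCS base is wrong when
≥ ⌈0.7·n⌉ reads share the same wrong base (probability ≈ 3·Binom.sf with
per-base-per-target rate e/3), or when a strand-level PCR error passed
through (rate ≈ pre-barcode error). The DCS error rate is the product of
two independent strand failures and is effectively zero at realistic error
rates; tests verify the raw ≥ SSCS ≥ DCS hierarchy and the SSCS tail model
at both realistic (10⁻²) and exaggerated (0.2) error rates.

## Variant calling

Pileup counts all five symbols per position; **depth is the sum of all
counts, N included**, and the 30,000× depth cap keeps the first reads by
stable name sort (deterministic truncation). A call is emitted when the
alternate fraction is ≥ `min_var_freq` (boundary inclusive) and a one-sided
exact binomial test of the alternate count against a configurable per-base
background error (default 10⁻⁴ at DCS tier) gives p ≤ `p_value`.
Three presets mirror the published modes: duplex (min VAF 0.001, p 0.1,
qual 25), deep panel (min VAF 10⁻⁶, qual 30 — the binomial gate is disabled
in this preset because a personalised panel queried at known sites relies on
the VAF floor and manual review, and any background model at 10⁻⁶ would veto
the mode's purpose), and amplicon resequencing (min VAF 0.001, p 0.05,
strand filter off).

Artifact filters only annotate, never drop: soft-clip (fail when every
mutant-supporting read is clipped; conservatively fail with no recorded
support), recurrence (> 10 samples sharing a variant flags the region for
manual assessment), and a population blacklist (TSV fixtures standing in
for GnomAD AC0/RF failures and ExAC common variants — the package does no
live database queries). `sscs_rescue` reports alt/depth/VAF at SSCS tier
for an a-priori target list with no thresholds, the path used for relapse
variants queried back at low-coverage earlier timepoints; zero-alt targets
are reported (VAF 0), off-panel targets come back "uncovered".

## Annotation

Cancer association requires the amino-acid change to be present in PeCan,
or in COSMIC at mutation-significance tier 1–3, or reported more than five
times in COSMIC (boundary: exactly 5 is *not* enough). Knowledge tables are
local TSVs shaped like PeCan/COSMIC exports. Prevalence conversion is
het-diploid (200 × VAF %, clipped at 100% — a VAF of 0.75 under allelic
imbalance still reports 100% of cells, deliberately uncorrected).
Detectability tiers use cut points 0.01/0.05/0.3, lower bound inclusive,
upper exclusive, except the major clone which is strictly VAF > 0.3.

`detection_limit` reports both printed forms of the input-mass ceiling: the
cell-equivalent count (250 ng → 37,879 → "40,000" at one significant
figure) and the limiting prevalence. The two printed quantities ("roughly
0.005%" vs "1 of 40,000 cells" = 0.0025%) differ by ×2; with the default
`min_supporting_molecules = 2` the limiting prevalence is 2/37,879 =
0.00528% → 0.005% at one significant figure, which reconciles both. The
parameter is exposed rather than hidden because the required number of
supporting molecules is an assay policy, not a physical constant.

## Clone inference

Trajectories are log₁₀(VAF + pseudocount)-transformed (pseudocount 10⁻⁵,
chosen one decade below the smallest prevalences of interest) and clustered
with average-linkage hierarchical clustering on Euclidean distance, cut at
height 0.8. No clustering algorithm or cut criterion is published for this
analysis; the defaults are justified by the recovery suite (≥ 80% of 20
noisy replicates of the four-clone longitudinal design recover perfect
memberships, topology and sweep; see `tests/test_acceptance.py`). The cut
height trades merging of near-parallel clones (founder vs major clone)
against splitting of noisy ones: at σ = 0.05 multiplicative noise,
within-clone distances are ≈ 0.02·√(2T) while the closest clone pairs in
the study-like design are ≈ 1 apart, leaving a wide plateau around the
default. Missing VAFs are imputed as 0 and flagged; a per-timepoint weight
map lets callers down-weight low-coverage timepoints whose values came from
SSCS rescue. Clusters need ≥ 2 member mutations to become clones (never
violated structurally — smaller clusters are returned as "unassigned");
clone prevalence is 2 × the mean member VAF (median available), making it
invariant to duplicating a member's row.

Tree assembly uses prevalence containment: X is a candidate ancestor of Y
iff prevalence(X) ≥ prevalence(Y) − tolerance (default 0.05) at every
timepoint where Y is present; the candidate with minimal mean prevalence
becomes the parent. Mutual containment within tolerance (near-identical
clones) is broken toward the larger clone, keeping the relation
antisymmetric. Exactly one parentless clone must remain (the root), else
the build fails; sibling sums exceeding the parent are *reported* as
violations, never repaired. Clones absent early and appearing late (the
mutations-acquired-during-expansion pattern) are handled naturally because
containment is only checked where the descendant is present. A sweep is a
clone below the minor threshold (default 5% of cells) at every timepoint up
to some point and above the dominance threshold (default 50%) later; the
reported interval spans the last minor and first dominant timepoints.

## Cohort statistics

Mann-Whitney U uses the pairwise definition (ties count ½). For combined
n ≤ 12 the two-sided p is computed by full enumeration of group assignments
— the definitional null, valid under ties; larger samples use the normal
approximation with midrank tie correction and continuity correction
(matching R's `wilcox.test` / scipy's asymptotic method). No
multiple-testing correction is applied. VAF-threshold fractions use a
strict `>`. Spectra fold purine-strand substitutions to the pyrimidine
convention and count SNVs lacking a flank (region edge) in a separate edge
bucket so channels + edge always equals the input count. Signature
refitting is non-negative least squares (`scipy.optimize.nnls`) against a
user-supplied 96 × K matrix with a strict channel-order header check;
tests use synthetic Dirichlet-drawn signatures because no specific
reference signature set is bundled.

## Problem sizes and determinism

All simulations are driven by `numpy.random.default_rng` seeds; identical
config + seed reproduces fragments, truth tables and downstream results
bit-for-bit. The test suite runs the full calling-recovery experiment at
the study's stated operating point (40,000 genome equivalents, 20
replicates) and the error-suppression and clone-recovery experiments at a
few thousand molecules, sizes at which every Monte-Carlo tolerance in the
suite is set from the corresponding binomial/Poisson standard deviations
(4σ throughout).

## Known limitations

Indels and structural variants are out of scope end to end; alignment is
not re-implemented (simulated reads are pre-positioned); paired-end overlap
and real soft-clipping are not modelled; prevalence conversion ignores copy
number; clone inference is a point estimate (no uncertainty on memberships
or topology, no Bayesian clustering); and the cohort statistics operate on
supplied tables — the published patient-level counts derive from
undeposited sequencing data and are not reproducible here.
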