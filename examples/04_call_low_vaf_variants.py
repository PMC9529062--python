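"""Call a variant far below standard-NGS resolution, then rescue one below
the calling threshold from single-strand evidence.

A heterozygous SNV carried by 1% of cells (VAF 0.005) is simulated at 8,000
genome equivalents, collapsed to duplex consensus and called with duplex
thresholds (min VAF 0.1%). A second variant in a clone at 0.1% of cells sits
below those thresholds: its VAF is still quantifiable by direct SSCS-tier
inspection at its known position — the rescue path used for relapse variants
queried back at earlier timepoints.
"""
import dupliseq as dq

panel = dq.generate_panel(1, 60, seed=41)
tree = dq.generate_clone_tree(
    [("major", None, {0: 1.0}), ("sub", "major", {0: 0.01}),
     ("tiny", "sub", {0: 0.001})], [0])
variants = dq.assign_variants(tree, panel, {"sub": 1, "tiny": 1}, seed=41)
v_sub, v_tiny = variants

config = dq.SimulationConfig(input_mass_ng=8000 * 6.6 / 1000.0,
                             pre_barcode_error=1e-3, post_barcode_error=1e-2)
fragments, truth = dq.simulate_families(panel, variants, tree, 0, config, seed=41)
result = dq.collapse_families(dq.fragments_to_reads(fragments))
print(f"duplex depth: {len(result.dcs)} DCS reads")

columns = dq.pileup(result.dcs, panel)
calls = dq.call_variants(columns, dq.DS_PARAMS)
print("\nduplex calls (DS thresholds, min VAF 0.001):")
for c in calls:
    print(f"  {c.contig}:{c.position + 1} {c.ref}>{c.alt}  "
          f"alt={c.alt_count}/{c.depth}  VAF={c.vaf:.5f}  p={c.p_value:.2g}")
print(f"  true VAF of the called variant: {v_sub.vaf[0]:.5f}")

sscs_cols = dq.pileup(result.sscs, panel, tier="SSCS")
(rescue,) = dq.sscs_rescue([(v_tiny.contig, v_tiny.position, v_tiny.ref, v_tiny.alt)],
                           sscs_cols)
print(f"\nSSCS rescue of the 0.1%-of-cells variant (true VAF {v_tiny.vaf[0]:.5f}):")
print(f"  alt={rescue.alt_count}/{rescue.depth}  VAF={rescue.vaf:.6f}  [{rescue.status}]")
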