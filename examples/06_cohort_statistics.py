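"""Cohort statistics: burden comparison, VAF fractions, spectra, refitting.

A synthetic 27-patient cohort (20 infants averaging ~15 mutations, 7
children averaging ~31) is compared by Mann-Whitney U; call VAFs are split
at the standard-NGS boundary (VAF 0.01); a C>T-dominated variant set is
tallied into the 96 trinucleotide channels and refit as a non-negative
mixture of synthetic reference signatures.
"""
import numpy as np
import pandas as pd

import dupliseq as dq
from dupliseq.cohort import SPECTRUM_CHANNELS

rng = np.random.default_rng(4)

table = pd.DataFrame({
    "patient": [f"P{i:02d}" for i in range(27)],
    "group": ["infant"] * 20 + ["child"] * 7,
    "total_mutations": np.concatenate([rng.poisson(15, 20), rng.poisson(31, 7)]),
    "nonsynonymous": 0, "cancer_associated": 0, "relapse": False,
})
res = dq.compare_groups(table, "total_mutations")
print(f"mutation burden: infants mean {res.means[0]:.1f} (n={res.n[0]}) vs "
      f"children {res.means[1]:.1f} (n={res.n[1]}); "
      f"U={res.u_statistic:.0f}, two-sided p={res.p_value:.3g} [{res.method}]")

vafs = np.concatenate([rng.uniform(0.011, 0.4, 2), rng.uniform(1e-4, 0.009, 25)])
vf = dq.vaf_fraction(vafs, 0.01)
print(f"\nVAF > 0.01: {vf.n_above}/{vf.n} calls ({100 * vf.fraction_above:.1f}%); "
      f"{100 * vf.fraction_below:.1f}% below standard-NGS resolution")

panel = dq.generate_panel(4, 60, seed=2)
variants = []
for region in panel.regions:
    for pos in range(1, region.length - 1):
        ref = region.sequence[pos]
        if ref in "CG" and rng.random() < 0.5:
            alt = {"C": "T", "G": "A"}[ref]
            variants.append(type("V", (), dict(contig=region.contig, position=pos,
                                               ref=ref, alt=alt))())
spectrum = dq.spectrum_96(variants, panel)
ct = spectrum.to_series()[[c for c in SPECTRUM_CHANNELS if "C>T" in c]].sum()
print(f"\nspectrum: {spectrum.total} SNVs, {ct} in C>T channels "
      f"({100 * ct / spectrum.total:.0f}%), {spectrum.edge} at region edges")

sigs = pd.DataFrame(rng.dirichlet(np.ones(96) * 0.3, size=3).T,
                    index=list(SPECTRUM_CHANNELS), columns=["SYN1", "SYN2", "SYN3"])
mix = dq.Spectrum96(counts=(70 * sigs["SYN1"] + 30 * sigs["SYN3"]).to_numpy())
fit = dq.refit_signatures(mix, sigs)
print("\nsignature refit of a 70/30 synthetic mixture:")
print(fit.exposures.round(3).to_string())
print(f"residual: {fit.residual:.2e}")
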