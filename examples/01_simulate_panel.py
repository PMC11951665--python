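"""Build a synthetic phased reference panel of SNVs and SVs in LD.

The panel emulates a wild-population WGS resource: 100 phased haplotypes
(50 diploid samples) over a 10 Mb chromosome with 2,000 SNVs and 130 SVs
(100 deletions, 20 duplications, 10 inversions).  Haplotypes are mosaics
of 8 founder sequences, so nearby variants — including each SV and its
flanking SNVs — are correlated, which is what makes LD-based imputation
of SVs possible.
"""

import numpy as np

from svimpute import SimulationConfig, simulate_panel, extract_variable_sites

config = SimulationConfig(seed=7)
panel, variants = simulate_panel(config)

print(f"panel: {panel.n_haplotypes} haplotypes x {panel.n_variants} variants")
counts = {}
for v in variants:
    counts[v.var_class] = counts.get(v.var_class, 0) + 1
print("variant classes:", counts)

freq = panel.allele_freq()
print(f"alt-allele frequency: min {freq.min():.3f}, max {freq.max():.3f} "
      "(every site is polymorphic)")
assert len(extract_variable_sites(panel)) == panel.n_variants

# LD decay: each SV against its nearest SNV vs a distant (>= 1 Mb) SNV
H = panel.haplotypes.astype(float)
r2 = lambda a, b: np.corrcoef(H[:, a], H[:, b])[0, 1] ** 2
snvs = [(i, v.pos) for i, v in enumerate(variants) if v.var_class == "SNV"]
rng = np.random.default_rng(0)
near, far = [], []
for i, v in enumerate(variants):
    if not v.is_sv:
        continue
    near.append(r2(i, min(snvs, key=lambda t: abs(t[1] - v.pos))[0]))
    distant = [j for j, p in snvs if abs(p - v.pos) >= 1_000_000]
    far.append(r2(i, rng.choice(distant)))
print(f"mean r2(SV, nearest SNV) = {np.mean(near):.3f}; "
      f"mean r2(SV, random SNV >= 1 Mb away) = {np.mean(far):.3f}")
print("higher nearby r2 means flanking SNV haplotypes tag the SV allele.")
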