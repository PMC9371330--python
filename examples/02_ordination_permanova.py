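"""Ordination and permutational inference on a simulated season.

Computes Bray-Curtis distances on CSS+Hellinger-transformed counts, embeds
them with NMDS, and partitions community variation among collection date,
host subpopulation, and their interaction with a sequential PERMANOVA; the
paired infected/symptomless contrast uses permutations restricted within
plants.
"""

import phyllotraj as pt

table, _, _ = pt.simulate(pt.SimulationConfig(n_genotypes=20, n_otus=40,
                                              n_snps=50, seed=1))
clean = pt.flag_contaminants(table).pruned(table).real_samples()
dist = pt.bray_curtis(pt.hellinger_transform(pt.css_normalize(clean)))
meta = clean.sample_meta.loc[dist.ids]

ordn = pt.nmds(dist, k=2, seed=0, n_restarts=5)
print(f"NMDS stress = {ordn.stress:.3f}  "
      "(lower is better; ~0.1 or less is a close fit)")

res = pt.permanova(dist, meta, ["doy", "subpopulation",
                                "doy:subpopulation"], n_perm=199, seed=0)
print(res.table.round(3).to_string(index=False))
# R2 is each term's share of community variation; collection date should
# dominate, with a smaller late-season subpopulation effect

both = meta.groupby("genotype")["infected"].nunique()
ids = meta.index[meta["genotype"].isin(both[both > 1].index)]
paired = pt.permanova(dist.subset(ids.tolist()), meta.loc[ids],
                      ["infected"], strata="genotype", n_perm=199, seed=0)
row = paired.table.iloc[0]
print(f"paired infection test: R2 = {row['R2']:.3f}, p = {row['p']:.3f}")
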