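"""Cluster measured fiber morphologies and relate clusters to TIL counts.

Generates a two-phenotype stromal cohort, measures all 13 morphometrics
per region, runs PCA + hierarchical clustering on the retained principal
components (HCPC, k=3), and prints cluster characterization and the
pairwise TIL comparisons.
"""

from tmefib.experiments import phenotype_recovery, phenotype_region_table

regions = phenotype_region_table(n_per_arm=32, size=256, seed=1)
res = phenotype_recovery(regions, k=3, retain=7)
fcm = res["model"]

print(f"{len(regions)} stromal regions, retained {fcm.retained} PCs "
      f"({fcm.cumulative_variance:.1%} of variance)")
print(f"adjusted Rand index vs planted phenotypes: {res['ari']:.2f}")
print(f"phenotype-A-dominated cluster: {res['a_cluster']}")
print("\ncharacterization of that cluster (direction vs grand mean):")
for m, d in res["directions"].items():
    print(f"  {m:>20s}: {d}")
print("\nSpearman rho vs TIL count:")
for m, r in res["spearman"].items():
    print(f"  {m:>20s}: {r:+.2f}")
print("\npairwise TIL comparisons between clusters (Mann-Whitney):")
print(res["til_comparison"].to_string(index=False))
# ARI 1.0 means the fiber-architecture clusters coincide with the planted
# phenotypes; the gappy/long-fiber cluster carries the higher TIL counts.
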