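"""Methylation-expression coupling across genes within a region.

For the top-weight DMP genes of a GMV-associated region, the per-gene
mean methylation beta is correlated (Spearman) with that gene's regional
expression, and the correlation is tested against 5,000 permutations of
the gene pairing (one-way cumulative p in the observed direction).
"""

import numpy as np
import pandas as pd

import imgomix as im

study = im.generate_study(im.SynthConfig(seed=7))
region_results = im.test_regions(study.cohort)
sig_regions = im.significant_regions(region_results)
cpg_results = im.fit_cpg_glm(study.methylation, study.cohort)
dmps = im.select_dmps(cpg_results)

# use all promoter DMPs of one abnormal region's candidate genes
region = sig_regions[0]
table = pd.DataFrame({"cpg_id": dmps.index, "gene": dmps["gene"],
                      "region": region})
patients = study.cohort.patients().subjects.index
res = im.analyze_region(region, table, study.methylation, study.expression,
                        patients, n_perm=5000, seed=3)
print(f"region {res.region}: {len(res.genes)} genes")
print(f"Spearman rho = {res.rho:.3f} (parametric p = {res.p:.4g})")
print(f"permutation p = {res.p_perm:.4g} ({res.n_permutations} permutations)")

# expression maps of genes split by PLS sign vs the t-map
tmap = im.build_tmap(region_results, study.parcellation)
gene_table = im.bootstrap_gene_z(study.expression, tmap, 300, seed=2)
z = gene_table["z"]
genes = [g for g in set(table["gene"]) if g in z.index]
classes = {"PLS+": [g for g in genes if z[g] > 0],
           "PLS-": [g for g in genes if z[g] < 0]}
print()
print(im.expression_map_vs_tmap(classes, study.expression, tmap).round(4))
# A negative rho means genes whose promoters are more methylated tend to
# be expressed lower in that region; the class correlations show PLS+
# genes' expression maps tracking the t-map positively and PLS- genes'
# negatively.
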