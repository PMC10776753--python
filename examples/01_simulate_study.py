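"""Generate a synthetic multi-omics study with planted effects.

The study bundles a spherical parcellation, a regional expression atlas,
a two-group GMV cohort with covariates and clinical scores, a subject x
CpG methylation set, and GMT pathways. The `truth` record lists every
planted entity so downstream analyses can be scored against it.
"""

import imgomix as im

config = im.SynthConfig(n_parcels=120, n_genes=500, n_subjects_mdd=60,
                        n_subjects_hc=60, n_cpgs=4000, seed=7)
study = im.generate_study(config)

print(f"parcels:      {study.parcellation.n_parcels}")
print(f"expression:   {study.expression.data.shape} (parcels x genes)")
print(f"cohort GMV:   {study.cohort.gmv.shape} (subjects x parcels)")
print(f"methylation:  {study.methylation.beta.shape} (subjects x CpGs)")
print(f"pathways:     {len(study.pathways)}")
print()
t = study.truth
print(f"planted effect parcels:   {len(t['effect_parcels'])} "
      f"(GMV deficit, d={t['gmv_effect_size']})")
print(f"planted coupled genes:    {len(t['coupled_genes'])} "
      f"(spatial r={t['coupling_r']} with the deficit pattern)")
print(f"planted promoter DMPs:    {len(t['true_dmps'])} "
      f"(|delta beta|={t['dmp_delta_beta']})")
print(f"planted enriched pathways: {t['enriched_pathways']}")
# The deficit parcels, coupled genes and DMPs are what the GMV, PLS and
# DMP stages respectively should rediscover; the pcr_signal_r latent ties
# methylation at the true DMPs to GMV at the deficit parcels.
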