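# imgomix

Integrative imaging-transcriptomic-epigenomic analysis of regional
gray-matter abnormalities, with a planted-truth synthetic multi-omics
study generator as its test bed.

## The problem

Case-control MRI studies of major depressive disorder (MDD) find lower
gray-matter volume (GMV) in specific cortical regions. Two molecular
data types can be layered onto such a finding:

* **brain-wide gene expression** (an Allen-Human-Brain-Atlas-style
  region x gene matrix) asks *which genes' spatial expression pattern
  tracks the anatomical deficit pattern*, and
* **peripheral DNA methylation** (an Illumina-850K-style subject x CpG
  beta matrix) asks *whether epigenetic differences in those same genes
  relate to the deficit across individual patients*.

`imgomix` implements the full chain that connects the three: regional
case-control testing, spatial partial least squares with a spin
permutation null, epigenome-wide differential methylation, gene-set
overlap and pathway enrichment, principal-component regression with
stepwise selection and leave-one-out cross-validation, and a
permutation-tested methylation-expression coupling analysis. Because
real cohorts of this kind are not publicly deposited, the package ships
a synthetic-data module that generates a complete study with *known
planted effects*; recovering those effects is how the pipeline is
tested.

## The methods, briefly

* **GMV stage** — per parcel, the Wald *t* for the group indicator in
  `gmv ~ group + age + gender + education + medication + TIV`;
  Benjamini-Hochberg FDR across parcels; the *t*-map is the spatial
  response downstream.
* **PLS stage** — PLS regression of the standardised *t*-map **y** on
  column-standardised expression **X**; the first component's weight
  vector solves max<sub>‖w‖=1</sub> cov(Xw, y). Significance comes from
  a spin test: random rotations **R** of the spherical parcel centroids,
  each parcel taking the value of its nearest original centroid, which
  preserves the map's spatial autocorrelation under the null. Gene
  weights are normalised to Z = w / SE<sub>boot</sub> by resampling
  parcels with replacement; genes with Z > 3 (PLS1+) or Z < −3 (PLS1−)
  at FDR 0.05 are the candidate lists.
* **DMP stage** — the same GLM per CpG on methylation beta values (age,
  gender, education, medication as covariates), promoter-restricted
  selection, covariate-adjusted Δβ.
* **Integration** — overlap(PLS genes, DMP genes); one-sided
  hypergeometric pathway enrichment of the overlap; DMPs of
  overlap-genes-in-enriched-pathways as features; PCA to the smallest k
  with ≥ 80% cumulative variance; stepwise regression (entry p < 0.05,
  removal p > 0.10) of each abnormal region's patient GMV on the
  component scores, FDR across regions on a selection-adjusted model p;
  LOOCV refitting the whole PCA + stepwise chain per fold; per-region
  composite DMP weights Σ|loading × standardised coefficient| with a
  0.2 reporting threshold; stepwise models of HAMD/HAMA on the same
  feature blocks.
* **Coupling stage** — per region, Spearman ρ across genes between mean
  promoter methylation and regional expression, tested against 5,000
  permutations of the gene pairing (one-way cumulative p in the observed
  direction), plus Pearson correlations of PLS+/PLS− mean expression
  maps with the *t*-map.

## Worked example

`examples/` contains one short script per capability. The end-to-end
run (`python examples/07_run_all.py`) prints:

```
significant GMV regions: 14/180
PLS1 variance explained: 49.3% (p_spin = 0.003322)
PLS1 genes: 101+ / 106-
DMPs: 340 in 306 genes
overlap genes: 71; enriched pathways: 5
PCA: 13 components (80.7% variance)
significant PCR regions: 12/14
LOOCV r: min 0.305, mean 0.456
coupling in P127: rho=0.170, p_perm=0.1459
coupling in P132: rho=0.178, p_perm=0.1469
coupling in P135: rho=0.140, p_perm=0.2058
```

Reading: 14 parcels show FDR-significant GMV loss; the first PLS
component of regional expression explains 49% of the t-map's variance
and survives the spin null (p ≈ 0.003); 207 genes pass the |Z| > 3
bootstrap cut, 71 of which also carry promoter DMPs; those genes'
methylation components significantly predict GMV in 12 of the 14
abnormal regions, and the prediction holds up under leave-one-out
cross-validation (mean r ≈ 0.46 across held-out patients). On this
synthetic study all five planted pathway sets are flagged and the
planted deficit parcels, coupled genes and DMPs are recovered (see
`examples/01`–`06` for the stage-by-stage versions with truth
comparisons).

## Command line

Each stage is also a subcommand sharing one run directory:

```bash
imgomix simulate --seed 7 --out study/
imgomix gmv      --study study/ --out run/
imgomix pls      --study study/ --out run/ --spins 1000 --boot 1000
imgomix dmp      --study study/ --out run/
imgomix integrate --study study/ --out run/
imgomix methexpr --study study/ --out run/ --perms 5000
imgomix run-all  --config cfg.yaml        # everything from one YAML
```

`imgomix prep-expression` additionally builds a parcels x genes matrix
from donor-level sample tables (probe filtering, probe-to-gene collapse,
nearest-centroid assignment, scaled-robust-sigmoid normalisation,
cross-donor averaging); a ready-made expression TSV is an equally valid
entry point.

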