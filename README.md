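# geotrace

Genotype-based population delineation and continuous-space geographic
origin tracing for traded wildlife.

Wildlife-forensics labs increasingly need to answer two questions from a
SNP genotype: *which population does this confiscated animal belong to*,
and *where on the map did it most likely come from*? `geotrace`
implements the full analysis chain used in range-wide provenance
studies of heavily trafficked species (pangolins being the canonical
case): variant and sample QC, model-based population structure,
isolation-by-distance diagnostics, neural-network geographic assignment
with bootstrap confidence, and trade-distance / sourcing-hotspot
summaries. A seeded spatial genotype simulator with known ground truth
makes every stage testable end to end without any sequencing data.

## What it computes

**QC** (`geotrace.qc`) — hard site filters (indels, mean depth < 8x or
above a species cap, site missingness > 30%, quality < Phred 20, minor
allele count < 3), removal of individuals with > 75% missing genotypes,
a neutrality partition by locus-level Tajima's D outside (−2, 2),
sliding-window LD pruning (50 SNPs / step 10 / r² > 0.2), and duplicate
removal at KING-robust kinship φ > 0.354, where

    φ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(i) + N_Aa(j)).

**Population structure** (`geotrace.structure`) — genotype PCA
(mean-imputed, √p(1−p)-scaled) and a binomial admixture model

    L(Q, F) = Σ_il [ g_il ln(Σ_k q_ik f_kl) + (2 − g_il) ln(1 − Σ_k q_ik f_kl) ]

maximized by EM over ancestry proportions Q and cluster frequencies F,
with the number of clusters K chosen by masked-genotype
cross-validation (`AdmixtureModel(matrix, K).fit()` returns an
`AdmixtureResults` with `Q`, `F`, the likelihood trace and a
`summary()`).

**Spatial diagnostics** (`geotrace.spatial`) — one-sided Mantel
permutation test of haversine geographic vs Euclidean genetic distance
(isolation by distance), and triangle-plot analysis (hybrid index vs
interclass heterozygosity at ancestry-informative markers with allele
frequency difference ≥ 0.9) to separate continuous clines from discrete
admixture.

**Origin assignment** (`geotrace.assign`) — a feed-forward network
(dropout 0.25, early stopping with 100-epoch patience) regresses
standardized (lon, lat) on SNP dosages of geo-referenced references; a
100-replicate SNP bootstrap gives each query a cloud of predicted
points, its centroid, and a *prediction variability* in km. Validation:
spatially stratified one-third hold-out, leave-one-out
cross-validation, and fraction-within-radius summaries.

**Trade reporting** (`geotrace.trade`) — great-circle distances from
seizure/market points to predicted source centroids, grouped by
site-type, plus a normalized 2-D Gaussian KDE of all bootstrap points
as a sourcing-hotspot surface. All distances everywhere are haversine
kilometres on a sphere of radius 6371.0088 km.

## Worked example

```python
import geotrace as gt
from geotrace.assign import AssignmentModel, AssignmentModelConfig

# a 2000 x 2000 km isolation-by-distance landscape with known truth,
# 25 samples turned into trade queries displaced 500 km from source
cfg = gt.SimulationConfig(seed=7, n_loci=600, cline_strength=2.0)
ds = gt.simulate_ibd_landscape(cfg, 200)
scenario = gt.make_trade_scenario(ds, n_queries=25,
                                  displacement_km_dist=500.0, seed=7)

net = AssignmentModelConfig(hidden_layers=2, hidden_width=32,
                            max_epochs=250, early_stop_patience=40,
                            learning_rate=3e-3, seed=7)
model = AssignmentModel(ds.genotypes, ds.samples, net)
result = model.fit_bootstrap(B=100)
print(result.summary())

summary = gt.trade_distances(result, scenario.seizure_coords,
                             ds.samples.set_index("sampleID")["site_type"])
print(summary.summary())
```

prints

```
Geographic assignment (bootstrap ensemble)
  queries:             25
  bootstrap replicates: 100
  prediction variability: mean 169.0 km (95% interval 152.4-183.5 km)
Trade-distance summary (seizure point to predicted source centroid)
  long_range_market        n=25   mean=439.5 km  range 275.0-577.5 km
```

The recovered group-mean trade distance (439.5 km) sits within the
model's own assignment error of the planted 500 km displacement, and
the per-query variability (mean 169 km) is the confidence proxy a
forensic report would quote alongside each predicted origin. A Mantel
test on the same landscape's reference samples gives r = 0.98 at the
permutation floor p = 1/1001, confirming the simulated IBD signal.

## Command line

Each stage is also exposed as a subcommand operating on VCF + sample
TSV files (`sampleID  x  y  site_type`, x = longitude, NA for unknown
origins):

```sh
geotrace simulate --kind ibd --n-samples 200 --trade-queries 25 --seed 7 --out-prefix demo
geotrace qc        --vcf demo.vcf --samples demo.samples.tsv --out-prefix demo
geotrace structure --vcf demo.neutral.vcf --k-min 1 --k-max 10 --seed 7 --out-prefix demo
geotrace spatial   --vcf demo.filtered.vcf --samples demo.samples.tsv --out-prefix demo
geotrace assign    --vcf demo.vcf --samples demo.samples.tsv --bootstraps 100 --out-prefix demo
geotrace validate  --vcf demo.vcf --samples demo.samples.tsv --scheme loocv --out-prefix demo
geotrace report    --assignments demo.assignments.tsv --bootstrap demo.bootstrap.tsv \
                   --samples demo.samples.tsv --out demo_report
```

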