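# coregrad

Core-microbiota and geographic-gradient analysis of 16S amplicon (ASV) count
tables, built for insect gut-microbiome surveys sampled along environmental
transects — the motivating case is the gut microbiota of a tephritid fruit
fly collected from a single host plant across latitudinal and altitudinal
gradients, where the questions are (i) how much community turnover the
gradients explain, (ii) whether samples form discrete community clusters,
(iii) which genera track the gradient, and (iv) whether a *core microbiota*
persists across all sites.

Given a feature table (ASVs × samples), a taxonomy map, a rooted phylogeny
and per-sample metadata (stage, site, latitude, altitude, transect), the
package runs the full analysis chain:

1. **Filtering** — chloroplast/mitochondria ASVs removed by lineage match.
2. **SRS normalization** — scaling with ranked subsampling to a fixed depth
   C<sub>min</sub> (5,000 reads for fly samples, 500 for fruit pulp):
   counts are scaled by C<sub>min</sub>/N, integer parts kept, and the
   remainder allocated one read at a time by ranked fractional part.
3. **Beta diversity** — unweighted UniFrac,
   d(A,B) = Σ<sub>unique branches</sub> ℓ / Σ<sub>covered branches</sub> ℓ,
   and PCoA via Gower double-centering B = −½·J·D²·J.
4. **Cluster number** — the gap statistic, Gap(k) = E*[log W<sub>k</sub>] −
   log W<sub>k</sub> with k-means over a uniform reference null and the
   one-standard-error selection rule.
5. **PERMANOVA** — pseudo-F = (tr(HGH)/m) / (tr((I−H)G(I−H))/(n−m−1)) for
   continuous (latitude, altitude) and categorical (cluster) covariates,
   with permutation p-values.
6. **Gradient associations** — per genus, OLS of log₂ TSS relative
   abundance on the gradient with half-minimum pseudocounts and
   Benjamini–Hochberg q-values.
7. **Cluster biomarkers** — LDA effect size (Kruskal–Wallis screen, then a
   bootstrapped linear discriminant; biomarkers at LDA > 2, p < 0.05).
8. **Core microbiota** — 1,000 rarefactions with replacement per sample; a
   feature is core when its prevalence reaches the prevalence threshold
   (75% fly, 65% pulp) in at least 95% of replicates; group-wise cores and
   their Venn regions.

Because raw survey data of this kind are rarely deposited, the package
includes a first-class synthetic-community generator
(`coregrad.synthetic_data`) that emulates the two-transect study design
(16 sites, 4 stages, 5 replicates) with planted core membership,
genus–latitude log-linear effects and stage-composition structure — and
returns the ground truth, so every stage is validated by parameter
recovery.

## Worked example

```python
from coregrad import (
    SimulationConfig, simulate_dataset, filter_taxa, SrsParams, srs_normalize_table,
    unifrac_matrix, pcoa, permanova, CoreParams, bootstrap_core,
)

config = SimulationConfig(n_sites_lat=6, n_sites_alt=0, replicates_per_stage_site=5,
                          stages=("larva",), n_features=120, seed=7)
table, taxonomy, tree, metadata, truth = simulate_dataset(config)

table = filter_taxa(table, taxonomy)                     # drop organelle ASVs
normalized, excluded = srs_normalize_table(table, SrsParams(c_min=5000))
dm = unifrac_matrix(normalized, tree)                    # unweighted UniFrac
ordination = pcoa(dm)
res = permanova(dm, metadata.loc[normalized.sample_ids, "latitude_deg_n"],
                n_permutations=999, seed=1)
core = bootstrap_core(normalized, CoreParams(n_boot=1000, seed=1))

print(f"{table.shape[0]} ASVs x {table.shape[1]} larval samples after filtering")
print(f"PCoA axes 1+2 capture {100 * ordination.proportion_explained[:2].sum():.1f}% of the variance")
print(f"latitude PERMANOVA: R2 = {res.r_squared:.3f}, F = {res.pseudo_f:.2f}, p = {res.p_value:.3f}")
print(f"core microbiota: {len(core.core_set)} ASVs, planted: {len(truth.core_features['larva'])}")
print("recovered planted core:", sorted(core.core_set) == sorted(truth.core_features["larva"]))
```

prints

```
115 ASVs x 30 larval samples after filtering
PCoA axes 1+2 capture 24.9% of the variance
latitude PERMANOVA: R2 = 0.047, F = 1.39, p = 0.107
core microbiota: 9 ASVs, planted: 9
recovered planted core: True
```

Reading: 5 of the 120 simulated ASVs were organelle contaminants; the first
two principal coordinates summarise a quarter of the UniFrac variance;
latitude explains ~5% of community turnover in this 30-sample subset (not
significant at this size — presence/absence UniFrac reacts only weakly to
planted abundance gradients); and the bootstrap core procedure returns
exactly the nine ASVs whose high occupancy (95%) and abundance (2%) were
planted.

## Command line

Every stage is also a `coregrad` subcommand operating on plain TSV/Newick
files, and `coregrad run` executes the whole chain from a YAML config with
derived per-stage seeds and a checksum manifest (re-runs are
byte-identical):

```sh
coregrad simulate --out-dir data/
coregrad normalize --table data/feature_table.tsv --method srs --depth 5000 --out norm.tsv
coregrad unifrac --table norm.tsv --tree data/tree.nwk --out dist.tsv
coregrad permanova --dist dist.tsv --meta data/metadata.tsv --var latitude_deg_n --perms 999 --seed 1
coregrad run --config run.yaml --out-dir results/
```

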