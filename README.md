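# phylometab

Phylogenetic comparative analysis of microbial metabolome surveys.

Given a phylogeny of populations, replicate-level metabolite intensity
tables (targeted and/or non-targeted channels), and optionally metabolite
yield profiles, `phylometab` answers three questions a comparative
metabolomics study asks:

1. **How diverged are metabolomes?** The metabolome divergence between two
   profiles is the mean squared difference of log-scale normalized levels,
   `D(k,l) = Σᵢ (m_{k,i} − m_{l,i})² / N`; between populations it is
   averaged over all cross strain pairs, and dividing by patristic distance
   gives a per-unit-time rate of metabolome evolution.
2. **Does divergence track the phylogeny?** Mantel correlations between
   divergence and patristic distance matrices, with uniform or
   phylogeny-weighted permutation nulls, and a group-ratio permutation test
   comparing (rate-adjusted) divergence between groups of population pairs
   (e.g. domesticated vs wild), with the add-one p-value
   `p = (#{stat* ≥ stat} + 1)/(B + 1)`.
3. **Is there a convergent niche signature?** Per-metabolite phylogenetic
   ANOVA (generalized least squares with Brownian covariance,
   `Cov(ε) = σ²V`, `V_ij` = shared root-to-MRCA branch length) of
   population mean levels on a group indicator, optionally controlling for
   growth state — detecting metabolites shifted the same way in
   independently derived lineages beyond what shared ancestry predicts.

Upstream of the statistics, the `normalize` module implements the standard
flow-injection/LC–MS hygiene: QC-based feature filters (detection ≥ 87.5%
of pooled QC injections, QC CV < 25%, detection ≥ 90% of biological
samples), k-nearest-neighbour imputation, probabilistic quotient
normalization (PQN), and regression of growth (OD at sampling) out of log
intensities. A first-class synthetic-data module generates complete studies
— tree, Brownian traits, convergent shifts, nested strains/replicates,
dilution, growth leakage, dropout, QC samples — with stored ground truth,
so every stage is testable end to end.

## Worked example

```python
from phylometab import synthetic_data as sd, normalize as nz
from phylometab import divergence as dv, phylostats as ps, treeio

# a 17-population study with two domesticated clades carrying a
# convergent shift on 7 of 19 amino-acid traits
ds = sd.simulate_dataset(sd.SimulationConfig(seed=3))

profiles, _ = nz.normalize_pipeline(ds.targeted, "targeted", level="strain")
div = dv.group_divergence(profiles, ds.truth.strain_to_population)
labels, P = treeio.patristic_distance_matrix(ds.tree, div.labels)
patristic = dv.DistanceMatrix(labels, P, "patristic")
adjusted = dv.phylo_adjusted_divergence(div, patristic)

wild = [l for l, g in ds.truth.groups.items() if g == "wild"]
mantel = ps.mantel_test(div.reorder(wild), patristic.reorder(wild),
                        n_permutations=9999, seed=1)
print(f"Mantel r={mantel.r:.3f} p={mantel.p_value:.4f}")

eligible = dv.wild_pairs(ds.truth.groups) + dv.same_clade_pairs(ds.truth.clades)
ratio = ps.group_ratio_permutation_test(adjusted, ds.truth.groups,
                                        n_permutations=9999, seed=1,
                                        eligible_pairs=eligible)
print(f"rate ratio={ratio.observed:.2f} p={ratio.p_value:.4f}")

pop_profiles, _ = nz.normalize_pipeline(ds.targeted, "targeted", level="population")
scan = ps.domestication_signature_scan(pop_profiles, ds.tree, ds.truth.groups)
print(f"signature metabolites: {int(scan['significant'].sum())} of {len(scan)}")
```

prints

```
Mantel r=0.861 p=0.0001
rate ratio=3.02 p=0.0148
signature metabolites: 7 of 19
```

Read: among wild populations metabolome divergence tracks phylogenetic
distance strongly (r = 0.86); domesticated population pairs diverge ~3×
faster per unit branch length than wild pairs (permutation p ≈ 0.015); and
the per-metabolite phylogenetic ANOVA flags exactly the 7 planted shift
traits as carrying a convergent domestication signature.

The same stages are scriptable from a shell:

```bash
phylometab simulate --seed 3 --out data/
phylometab normalize --in data/targeted.csv --channel targeted --out profiles.csv
phylometab run --config run.yaml
```

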