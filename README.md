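# radpopgen

Population-structure analysis of RAD-seq SNP genotypes for marine species
with large, weakly differentiated populations — the regime typical of
broadcast spawners such as the California sea cucumber, where pairwise
F<sub>ST</sub> between collection sites sits in the 0.001–0.015 range and
the management question is whether that weak structure reflects limited
dispersal.

The package provides, as a library plus a `radpopgen` command-line tool:

* **QC cascade** for SNP genotype matrices read from VCF: indel/multi-allelic
  removal, QUAL, per-locus and per-individual missingness, minor allele
  frequency (MAF ≥ 0.05 kept), one SNP per RAD tag (highest MAF), and a
  Hardy–Weinberg screen that drops a locus only when it fails (BH q < 0.05)
  in ≥ 2 collection sites. Replicate-sequenced individuals give a
  genotyping-error (discordance) estimate.
* **Diversity and differentiation**: per-site H<sub>E</sub> (unbiased),
  H<sub>O</sub>, Weir–Cockerham f (F<sub>IS</sub>), proportion polymorphic;
  Weir–Cockerham θ (global, pairwise, per-locus) as the ratio of summed
  variance components a/(a+b+c), with a percentile bootstrap CI over loci;
  Monte-Carlo G-tests of genic differentiation combined across loci by
  Fisher's method.
* **Hierarchical AMOVA** (Φ<sub>CT</sub>, Φ<sub>SC</sub>, Φ<sub>ST</sub>)
  on squared-Euclidean dosage distances with permutation tests, including
  the five standard site groupings built from site labels (North Pacific
  Current, Victoria Sill, Admiralty Inlet, all barriers jointly, state).
* **Isolation by distance and dispersal**: one-sided Mantel tests (exact
  enumeration up to 6 sites), OLS of linearized F<sub>ST</sub> = θ/(1−θ)
  on in-water distance, and a density-conditioned dispersal model
  σ = (8·D·b)<sup>−1/2</sup> km, where b is the IBD slope (km⁻¹) and D the
  effective density (adults/km).
* **Adaptive/neutral partition**: union-of-rules classification from
  external evidence tables (F<sub>ST</sub>-outlier flags, Bayes factors ≥ 10,
  ordination loadings beyond 3 SD), so every analysis can be rerun per SNP set.
* **Two-deme drift–migration simulator**: forward-time Wright–Fisher demes
  of size N<sub>e</sub> exchanging a fraction m of their gene pool per
  generation; a grid over (N<sub>e</sub>, m, T) maps simulated pairwise θ
  onto the empirical F<sub>ST</sub> range to translate observed
  differentiation into migration rates.
* **Synthetic data generators** (Balding–Nichols and linear stepping-stone)
  with truth manifests, so the full pipeline is testable end to end without
  any external download.

## Worked example

Generate a nine-site stepping-stone transect with genuine isolation by
distance and recover the dispersal scale:

```python
from radpopgen.synthetic import generate_ibd_transect
from radpopgen.diversity import pairwise_theta
from radpopgen.ibd import ibd_regression, dispersal_distance

G, dist, truth = generate_ibd_transect(
    K_sites=9, spacing_km=150, Ne=1000, m_neighbor=0.01,
    T=500, L=2000, n_per_site=30, seed=4,
)
pw = pairwise_theta(G)
reg = ibd_regression(pw.theta, dist, n_perm=999, seed=4)
print(f"Mantel r = {reg.mantel_r:.3f} (p = {reg.mantel_p:.4g}); "
      f"slope = {reg.slope:.3g} /km, adj R^2 = {reg.adj_r2:.3f}")
print(dispersal_distance(reg.slope).rounded)
```

prints

```
Mantel r = 0.995 (p = 0.001); slope = 5.96e-05 /km, adj R^2 = 0.989
         all
density
1         46
10        14
100        5
1000       1
10000      0
100000     0
```

The Mantel test confirms differentiation increases with distance along the
transect; the fitted slope, combined with an assumed effective density of
e.g. 100 adults per km of coastline, converts to a mean per-generation
dispersal distance of 5 km — each row conditions the same slope on a
different density because field densities are rarely known.

The same analyses run from the shell on a VCF plus metadata tables:

```sh
radpopgen synth study_dir --sites 9 --loci 500 --n-per-site 25
radpopgen fst study_dir/genotypes.vcf study_dir/samples.tsv
# -> global theta = 0.0074  95% CI [0.0062, 0.0086]
radpopgen run-all config.yaml   # full pipeline, YAML-configured
```

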