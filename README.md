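# morphosus

Geometric-morphometrics inference for *Sus scrofa* teeth and heel bones.

Zooarchaeologists studying the Pre-Pottery Neolithic of Cyprus face a
question that ancient DNA cannot answer there (collagen and DNA preserve
poorly in arid sites): were the island's suids one endemic wild-boar
population, where did that population come from on the continent, and did
PPNB villagers begin controlling their mobility?  The analytical toolkit
that answers those questions from bones alone is 2D/3D landmark-based
geometric morphometrics: molar occlusal shape carries a biosystematic and
phylogenetic signal, molar size carries demographic signal, and calcaneus
shape records the mobility regime an animal grew up under (free-ranging,
penned, or domestic).  `morphosus` implements that full analysis chain as a
tested, reusable Python package, exercised end-to-end on synthetic landmark
data with known ground truth.

## The analysis

Each specimen is an ordered configuration of landmarks: for the lower
second molar (M/2), 8 anatomical landmarks plus 67 semilandmarks placed
equidistantly by arc length along the crown outline (75 points); for the
M/3, 9 + 99 (108 points); calcanei are 3D point sets.  The chain is:

1. **Superimposition.** Generalized Procrustes Analysis (GPA) removes
   position, orientation and scale: every configuration is centered, scaled
   to unit centroid size `CS = sqrt(sum_i ||x_i - x_bar||^2)`, and rotated
   to an iteratively refined consensus.  The aligned coordinates are the
   *shape* variables; appending `log CS` gives the *form* matrix
   (specimens × (k·p + 1)).
2. **Size and allometry.** One-way permutation ANOVA of `log CS` across
   groups; multivariate regression of shape on `log CS` (Procrustes ANOVA,
   `R² = SS_model / SS_total`); a MANCOVA group × size interaction test of
   whether the allometric slope is shared across populations
   (Freedman–Lane permutation of reduced-model residuals).
3. **Group structure.** Goodall-type permutation MANOVA of shape/form over
   groups; PCA retaining 95% of variance followed by LDA, with per-group
   classification accuracy from stratified two-fold cross-validation
   repeated over many random splits; an unrooted neighbour-joining tree on
   Euclidean distances between group mean forms.
4. **Population count.** Univariate Gaussian mixtures of `log CS` fitted by
   EM under equal- and free-variance families, component count selected by
   BIC — one component means one population.
5. **Ecophenotype.** Calcaneus forms of unknowns are projected into the
   discriminant space of a free-ranging / captive / domestic training set
   and classified by k-nearest-neighbour majority vote with
   `k = floor(sqrt(N))`.

Because the original specimen data are not deposited anywhere, the package
ships a first-class synthetic generator (`morphosus.synthetic`) whose
model is exactly the one GPA inverts — template + group offset + allometric
term + isotropic landmark noise, then a random similarity transform — with
named scenarios fixing group sizes to the published sample accounting
(`morphosus.samples`).

## Worked example

```python
import numpy as np
import morphosus as m

scen = m.preset_scenario("two-island-populations", seed=11)   # KLI n=33, SHI-A n=25
dataset, truth = m.simulate_shape_populations(scen.truth, scen.n_per_group)

aligned = m.generalized_procrustes(dataset)                   # GPA
form = m.build_form_matrix(aligned)                           # shape ⊕ log CS
groups = np.asarray(aligned.groups)
logcs = np.log(aligned.centroid_sizes)

print(m.allometry_regression(aligned.shape_coordinates, logcs, 199, seed=11).to_dict())
print(m.shape_manova(form.values, groups, 199, seed=11).to_dict())
print(m.fit_size_mixture(logcs, seed=11).G)
```

prints (exactly, for this seed):

```
{'Rsq': 0.03069351930102705, 'F': 1.773264818799159, 'p': 0.005, 'n_permutations': 199}
{'term': 'group', 'df_between': 1, 'df_within': 56, 'F': 5.707607146706621, 'p': 0.005, 'n_permutations': 199}
1
```

Read: ~3% of shape variation is allometric (significant — the generator
injects a shared slope), the two island groups differ significantly in
form (Goodall F = 5.7, smallest attainable permutation p = 1/200), and the
pooled log-size distribution is unimodal — one size population, as in the
single-island-population scenario the generator emulates.

The same run is available from the shell:

```bash
morphosus run --config run.yaml     # scenario/seed/outdir in YAML
morphosus simulate --scenario three-ecoclasses --seed 7 --out fixtures/eco
```

`run` writes aligned/form CSVs, JSON test reports, LD scores, a mixture
report, a Newick tree and a one-page markdown summary, byte-identical for
identical config + seed.

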