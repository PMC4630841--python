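# morphotraj

Geometric-morphometrics toolkit for comparing **ontogenetic (growth)
trajectories** of cranial and mandibular shape across related species from
3D landmark data — built around the classic study design of four bear
species (*Ursus arctos*, *U. americanus*, *U. maritimus* and the extinct
cave bear *U. spelaeus*), with juvenile and adult age classes, bilaterally
symmetric 36-landmark crania and one-sided 9-landmark mandibles.

It is aimed at evolutionary morphologists who want a tested, scriptable
version of the standard inference chain:

1. **Landmark I/O and validation** — Rohlf-style TPS files and a CSV
   dialect, with explicit missing-landmark masks (`morphotraj.io`,
   `morphotraj.templates`).
2. **Missing-landmark estimation** — 3D thin-plate-spline (kernel
   U(r) = r) warping of a Procrustes grand-mean reference onto each
   incomplete specimen's observed landmarks (`morphotraj.missing`).
3. **Generalized Procrustes Analysis** — partial Procrustes (unit centroid
   size), with the reflect–relabel **object-symmetry** decomposition for
   structures digitized on both sides; downstream analyses use the
   symmetric components (`morphotraj.procrustes`).
4. **Morphospace** — covariance PCA of shape coordinates, equal-frequency
   95 % ellipses, and extreme-shape models along PCs
   (`morphotraj.morphospace`).
5. **Allometry** — multivariate regression of shape on log centroid size
   (permutation-tested), non-allometric residual coordinates, and the
   **trajectory-angle test**: the angle θ = arccos⟨β̂₁/‖β̂₁‖, β̂₂/‖β̂₂‖⟩
   between two groups' regression vectors, tested against the null of
   independent uniform directions on the unit sphere in the effective
   shape-space dimension, where (cos θ + 1)/2 ~ Beta((d−1)/2, (d−1)/2)
   (`morphotraj.allometry`).
6. **Group comparison** — Procrustes distances between group mean shapes
   with pairwise label-permutation p-values, on raw and size-corrected
   tracks; CVA ordination; Kruskal–Wallis rank tests with a mean-rank
   post hoc (`morphotraj.groups`).
7. **Phylogenetic signal** — squared-change parsimony tree length of
   species-mean shape scores, with the tip-permutation test (exhaustive
   enumeration of all 24 assignments on a 4-species tree)
   (`morphotraj.phylo`).

Because the original specimen coordinates were never deposited, the package
ships a first-class **synthetic-data generator** (`morphotraj.simulate`)
that reproduces the study design — published group sizes, species-specific
symmetric mean shapes, a shared ontogenetic allometry direction with a
controllable between-species angle, isotropic landmark noise, missing
landmarks in the fossil species, and optional Brownian-motion structure
among species means — so every stage can be validated against known ground
truth.

## Worked example

```python
import numpy as np
from morphotraj import (bear_like_params, simulate_ontogeny, estimate_missing,
                        gpa_with_object_symmetry, pca, regress_shape_on_size,
                        ontogenetic_trajectories)

params = bear_like_params("cranium", seed=1)
dataset = simulate_ontogeny(params)
dataset = estimate_missing(dataset)              # TPS completion of fossils
result, sym = gpa_with_object_symmetry(dataset)  # GPA + symmetric components

coords = sym.flattened()
space = pca(coords)
print(f"PC1-3 variance: {space.percent_variance[:3].sum():.1f}%")

pooled = regress_shape_on_size(coords, result.log_centroid_sizes,
                               n_permutations=999, seed=1)
print(f"allometry: {pooled.percent_predicted:.1f}% predicted, "
      f"p = {pooled.permutation_p:.3g}")

species = dataset.metadata()["species"].to_numpy()
mask = np.isin(species, ("arctos", "spelaeus"))
regs, angles = ontogenetic_trajectories(
    coords[mask], result.log_centroid_sizes[mask], species[mask],
    pairs=[("arctos", "spelaeus")], dimension=54, seed=1)
test = angles[("arctos", "spelaeus")]
print(f"trajectory angle arctos/spelaeus: {test.angle_degrees:.1f} deg, "
      f"p = {test.p_value:.2g}")
```

prints

```
PC1-3 variance: 82.7%
allometry: 34.9% predicted, p = 0.001
trajectory angle arctos/spelaeus: 39.7 deg, p = 3.5e-12
```

The 253 simulated crania (the published group sizes) carry a generating
trajectory angle of 40° between the brown-bear and cave-bear lineages; the
estimated angle of 39.7° is far smaller than expected for two random
directions in the 54-dimensional symmetric shape space, so trajectory
similarity is detected with high confidence.  The allometric regression
explains ~35 % of shape variation, and size correction shrinks the
juvenile–adult contrasts, reproducing the qualitative fingerprint of
size-driven ontogenetic shape change.

The same chain is available from the shell:

```bash
morphotraj simulate --structure cranium --seed 1 --out data/
morphotraj complete --in data/cranium.tps --template cranium36 --out data/completed.tps
morphotraj gpa --in data/completed.tps --template cranium36 --symmetry --out data/aligned.csv
morphotraj run --config study.yaml
```

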