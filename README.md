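# crnsmote

Cluster-constrained reduced-noise SMOTE resampling for imbalanced tabular
classification.

Standard classifiers trained on skewed class distributions — liver-disease
records with 416 healthy vs 167 diseased patients, blood-donation logs with a
3:1 majority, three-way maternal-health-risk grades — favor the majority class
and miss the rare cases that matter. SMOTE fixes the imbalance by
interpolating synthetic minority samples between nearest neighbors, but it
also amplifies noise: an outlying or mislabeled minority point spawns a whole
halo of synthetic look-alikes. Hybrid pipelines therefore follow SMOTE with a
cleanup pass, classically DBSCAN noise removal at a fixed radius ε. The
problem this package addresses is that a fixed small ε often *shatters* a
class into many small dense clusters, which is exactly wrong for
classification — the samples of one category should occupy one or two
concentrated clusters.

## The method

`crn_smote` runs three stages on a dataset X with classes C₁…C_m and majority
count N_Cmax:

1. **SMOTE** every class up to N_Cmax: a synthetic sample is
   x_syn = x + β·(x_nn − x), with x a random minority sample, x_nn a random
   one of its K_SMOTE Euclidean nearest same-class neighbors, and
   β ~ U[0, 1).
2. **Constrained noise removal**, per non-majority class: run
   DBSCAN(ε, N) starting from a small radius ε₀ = 0.1 (on min-max-normalized
   features) and grow ε by δ = 0.05 until the class's surviving (non-noise)
   points form c clusters with 0 < c ≤ N_cluster, where N_cluster ∈ {1, 2}.
   Only then are the noise points dropped. The majority class is never
   filtered.
3. **SMOTE again** on the concatenation [X_Cmax, ∪ᵢ X_DBSCAN,Cᵢ] to restore
   every class to N_Cmax.

The fixed-radius baseline (`rn_smote`, ε from the K-distance heuristic), the
`smote_tomek` and `smote_enn` hybrids, chance-corrected metrics (Cohen's κ,
MCC, macro F1/precision/recall) and a stratified k-fold harness that
resamples **only the training folds** are included for head-to-head
comparison.

## Worked example

```python
from crnsmote import CrnConfig, crn_smote, make_maternal_like

data = make_maternal_like(seed=0)
print("class counts before:", data.class_counts())

result = crn_smote(data, CrnConfig(n_cluster=1, k_smote=5, seed=0))
print("class counts after: ", result.data.class_counts())
for label, audit in result.per_class.items():
    print(
        f"{label}: eps {audit.eps_trajectory[0]:.2f} -> {audit.final_eps:.2f}, "
        f"clusters {audit.cluster_trajectory[0]} -> {audit.n_clusters}, "
        f"removed {audit.n_removed}, regenerated {audit.n_regenerated}"
    )
```

prints

```
class counts before: {'c1': 406, 'c2': 336, 'c3': 272}
class counts after:  {'c1': 406, 'c2': 406, 'c3': 406}
c2: eps 0.10 -> 0.15, clusters 6 -> 1, removed 27, regenerated 27
c3: eps 0.10 -> 0.20, clusters 4 -> 1, removed 8, regenerated 8
```

The fixture is a 1014-row, three-class dataset (406/336/272) whose diffuse
minority classes fragment under a fixed ε = 0.1 — class c2 splits into six
clusters. The constrained loop grows ε until each class coheres into a single
cluster, removes only the points that are still noise at that radius (27 and
8), and the final SMOTE pass restores all three classes to 406 samples. The
majority class c1 passes through untouched.

The same pipelines are available from a shell:

```sh
crnsmote simulate --shape ilpd --seed 3 raw.csv
crnsmote balance --method crn1 --k-smote 5 --seed 1 raw.csv balanced.csv
crnsmote compare --dataset raw.csv --n-folds 10
```

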