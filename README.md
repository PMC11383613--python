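# striomap

Within-individual mapping of striatum-to-cortex functional coupling.

Precision resting-state fMRI in deeply sampled individuals shows that the
caudate contains side-by-side zones, each coupled to a distinct
higher-order association network (FPN-A, FPN-B, LANG, DN-B, DN-A) —
mirroring the juxtaposed network clusters of the cerebral cortex, down to
their hemispheric asymmetries (LANG-linked zones left-lateralized,
FPN-B-linked zones right-lateralized). `striomap` implements that
analysis as a tested, desk-scale pipeline for methodologists who want to
study, stress, or extend it:

* **winner-takes-all parcellation** — each striatal voxel `v` is assigned
  `argmax_n #{ i ∈ top_k(z_v) : label(i) = n }`, where `z_v` is the
  run-averaged Fisher-z correlation of `v` with all cortical vertices
  (both hemispheres pooled), `top_k` keeps the k = 400 strongest vertices,
  and `label` is a per-vertex 15-network map;
* **blur control** — a thresholded vote variant (drop vertices with
  `z < θ` inside the top 400; a voxel with no supra-threshold vertex is
  unassigned) swept over θ = 0.01, 0.05 … 0.40 on raw and smoothed data,
  separating genuine coupling from cortical signal bleed and dropout;
* **model-free seed maps** with a recapitulation score
  `selectivity = mean z(target network) − max_other mean z(other)`,
  computed split-half so seeds and maps never share data;
* **laterality** — per-hemisphere network proportions and the index
  `(pL − pR)/(pL + pR)`;
* **a synthetic phantom** (multi-run BOLD-like surface + volume data with
  fully known coupling truth, nuisance structure, cortical bleed, ventral
  dropout, and planted asymmetries) that makes every stage verifiable
  without any data download.

See `docs/methods.md` for the model, its assumptions, and what the
phantom does and does not emulate.

## Worked example

```python
import numpy as np
from striomap import PhantomSpec, simulate_bundle, build_conn_matrix, parcellate
from striomap.pipeline import preprocess_bundle
from striomap.geometry import ASSOCIATION_NETWORKS, NETWORK_NAMES, CAUDATE

spec = PhantomSpec(rng_seed=7)           # 2,000 vertices/hemi, 4 runs x 410 frames
bundle = simulate_bundle(spec)
smoothed, _, tsnr = preprocess_bundle(bundle)   # regress -> band-pass -> smooth
conn = build_conn_matrix(smoothed)              # voxels x vertices Fisher-z
parc = parcellate(conn, bundle.truth.vertex_labels)  # winner-takes-all, k=400

caudate = np.flatnonzero(bundle.volume.substructure_of() == CAUDATE)
acc = np.mean(parc.winners[caudate] == bundle.truth.voxel_coupling[caudate])
found = sorted(set(parc.winners[caudate]) & set(ASSOCIATION_NETWORKS))
print(f"caudate accuracy: {acc:.3f}")
print("association networks recovered:", [NETWORK_NAMES[n] for n in found])
```

Output:

```
caudate accuracy: 1.000
association networks recovered: ['FPN-A', 'FPN-B', 'LANG', 'DN-B', 'DN-A']
```

The accuracy is the fraction of caudate voxels assigned their true
network; the recovered list shows that all five association networks
emerge as caudate zones — the megacluster. The same pipeline is available
from the shell (`striomap all --config cfg.yaml --out results/` writes
the parcellation volume, blur sweep, seed selectivity, laterality tables,
and a markdown report, all stamped with the config hash).

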