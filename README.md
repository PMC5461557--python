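# punctakit

Quantification tools for synaptic-puncta and perineuronal-net (PNN)
histology: 3D spot detection in anisotropic confocal stacks,
friends-of-friends clustering of puncta positions, object-level marker
colocalization, laminar intensity profiles, and control-hemisphere-normalized
group statistics — plus a synthetic-data module that generates every input
with known ground truth, so the whole pipeline is testable end to end.

It is aimed at labs quantifying postsynaptic-marker puncta (PSD-95,
gephyrin) and PNN/cell-marker overlap (WFA, parvalbumin, ...) from confocal
z-stacks, where treated and untreated hemispheres of the same animal are
compared.

## The core computations

**Friends-of-friends (FOF) clustering.** FOF has a single free parameter,
the linking length *b*: two puncta at Euclidean distance *d ≤ b* (physical
micrometres, never voxel indices) are linked, and a cluster is a connected
component of the link graph; components below `min_cluster_size` (default 2)
are non-clustered. The summary statistic is the fraction of puncta within
clusters, plus the cluster-size histogram. *b* = 2 µm is the conventional
choice at confocal resolution: much shorter and almost nothing clusters,
much longer and almost everything collapses into a few clusters. Two
implementations — an O(n²) reference and a spatial-hash/union-find variant
with O(n) memory — are guaranteed to produce identical partitions.

**Spot detection.** A display-style gamma transform
(`out = M·(in/M)^(1/γ)`, default γ = 1.79), an anisotropy-corrected
Laplacian-of-Gaussian at per-axis scale `σ = diameter/(2√3)/voxel_size`
(spherical in physical space), 3D local maxima with a physical minimum
separation, and a 0–100 *quality* score defined as the LoG peak response
normalized to the strongest response in the stack (threshold default 80).
Sub-voxel localization by quadratic peak interpolation.

**Colocalization.** An object of marker A counts as overlapping marker B if
a B centroid lies within the match radius (default 10 µm ≈ a soma radius);
both directional percentages are reported, with mean ± SEM over replicate
sections and a two-group p-value.

**Group comparison.** Site values → per-animal hemisphere means → treated
value divided by the same animal's control-hemisphere mean (removing
inter-animal staining/expression variability) → Shapiro-Wilk normality gate
→ Student's t test if both groups pass, Mann-Whitney U otherwise (exact
null distribution for small tie-free samples).

## Worked example

```sh
python examples/cluster_puncta.py
```

```
Thomas (clustered): 555 puncta, 62 clusters
  fraction clustered: 0.995
  size histogram: {2: 1, 3: 2, 4: 5, 5: 3, 6: 6, 7: 6, 8: 9, 9: 7, 10: 5, ...}
Poisson (random): 484 puncta, 35 clusters
  fraction clustered: 0.155
  size histogram: {2: 30, 3: 5}
```

A Thomas (parent–offspring) field keeps essentially all puncta inside
clusters at *b* = 2 µm, while a Poisson field of the same total density
leaves most puncta non-clustered — the fraction-clustered statistic cleanly
separates clustered from random spatial organization at matched density.

The other examples follow the same pattern, one capability each:
`detect_rendered_stack.py` (render → re-detect round trip; 25/25 recovered,
~10 nm localization error), `colocalization_table.py` (70.0 ± 2.9 % vs
90.0 ± 2.9 %, p = 0.01), `laminar_profile.py` (background-normalized plateau
at 5.0× Layer-I background), and `treatment_experiment.py` (a simulated
halving of puncta density is recovered as a normalized treated mean of
0.496 vs 1.033 in shams, t test p ≈ 2·10⁻⁷).

There is also a thin CLI (`punctakit simulate|detect|cluster|coloc|profile|
compare|run`) for file-based workflows; `punctakit run --config config.yaml
--out-dir out/` executes the full simulate → measure → normalize → compare
pipeline and writes every stage's outputs plus a deterministic
`summary.json`.

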