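"""Friends-of-friends clustering of simulated puncta fields.

Simulates a clustered (Thomas) and an intensity-matched random (Poisson)
3D puncta field, clusters both at the 2 um linking length, and prints the
fraction of puncta within clusters and the cluster-size histogram.
"""

import punctakit as pk

volume = pk.VolumeSpec(100.0, 100.0, 10.0)  # one confocal site, um
params = pk.FOFParams(linking_length_um=2.0, min_cluster_size=2)

thomas = pk.simulate_thomas_points(
    pk.ThomasParams(parent_intensity=0.0005, mean_offspring=10.0, offspring_sigma_um=0.5, seed=1),
    volume,
)
poisson = pk.simulate_poisson_points(0.005, volume, seed=2)  # same expected density

for name, field in (("Thomas (clustered)", thomas), ("Poisson (random)", poisson)):
    assignment = pk.fof_grid(field, params)
    stats = pk.cluster_stats(assignment)
    print(f"{name}: {stats.n_total} puncta, {assignment.n_clusters} clusters")
    print(f"  fraction clustered: {stats.fraction_clustered:.3f}")
    print(f"  size histogram: {dict(sorted(stats.size_histogram.items()))}")

print(
    "\nA clustered field keeps most puncta inside clusters at b = 2 um, while a\n"
    "random field of the same density leaves most puncta non-clustered; the\n"
    "fraction-clustered statistic separates the two regimes."
)
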