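"""Bidirectional object colocalization in the conventional reporting format.

Builds three replicate sections per simulated species group with different
constructed overlap fractions between two markers (think WFA-stained nets vs
parvalbumin-positive cells), then prints the mean +/- SEM percentage table
with the two-group p-value.
"""

import punctakit as pk

volume = pk.VolumeSpec(400.0, 400.0, 40.0)
radius = 10.0  # um, about a soma radius

tables = {"rat": [], "mouse": []}
for rep, overlap in enumerate((0.70, 0.75, 0.65)):
    a, b = pk.simulate_coloc_objects(20, 30, overlap, radius, volume, seed=rep)
    tables["rat"].append(pk.match_objects(a, b, radius))
for rep, overlap in enumerate((0.90, 0.85, 0.95)):
    a, b = pk.simulate_coloc_objects(20, 30, overlap, radius, volume, seed=100 + rep)
    tables["mouse"].append(pk.match_objects(a, b, radius))

one = tables["rat"][0]
print(f"single section (rat, overlap 0.70): "
      f"%A over B = {one.pct_a_over_b:.1f}, %B over A = {one.pct_b_over_a:.1f}")

report = pk.format_coloc_table(tables, direction="pct_a_over_b")
print("\n% of marker-A objects with a marker-B partner within 10 um:")
print(report.round(2).to_string())
print(
    "\nEach row is mean +/- SEM over replicate sections; the p-value comes from\n"
    "the normality-gated two-group test (t test if both groups pass Shapiro-Wilk,\n"
    "Mann-Whitney U otherwise)."
)
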