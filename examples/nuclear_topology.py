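"""Quantify probe topology in simulated 3D-FISH nuclei, two conditions.

Generates 30 nuclei per condition: a control-like preset (probe pairs near
the envelope and overlapping) and a case-like preset (pairs interior and
separated), then prints the colocalization contingency test, the radial
shell occupancy, and the probe-to-envelope distance comparison.
"""

import panelfish as pf
from panelfish.topology import (
    call_all_pairs,
    colocalization_table,
    distance_stats,
    radial_profile,
)

nuclei_c, probes_c, _ = pf.generate_nuclei(pf.control_like_nuclei_config(), seed=1)
nuclei_h, probes_h, _ = pf.generate_nuclei(pf.case_like_nuclei_config(), seed=2)
calls = {
    "control_like": call_all_pairs(nuclei_c, probes_c),
    "case_like": call_all_pairs(nuclei_h, probes_h),
}

table = colocalization_table(calls)
print("colocalized / separated per condition (%):")
print(table.percent.round(1).to_string())
print(f"chi-square p = {table.chi2_p:.3g}, Fisher exact p = {table.fisher_p:.3g}")
print("-> the two conditions differ sharply in how often the locus probe "
      "overlaps its subtelomeric anchor.")

prof = radial_profile(calls)
outer = prof.occupancy[[8, 9, 10]].sum(axis=1).round(2)
print("\nfraction of cluster probes in the outer three equal-volume shells "
      "(zones 8-10, the peripheral 30% of nuclear volume):")
print(outer.xs("cluster_probe", level="channel").to_string())

dist = distance_stats(
    {cond: [c.envelope_distance_cluster for c in cs] for cond, cs in calls.items()},
    design="two_group_rank",
)
print("\ncluster-probe distance to the nuclear envelope (μm, mean ± SEM):")
for cond, row in dist.descriptives.iterrows():
    print(f"  {cond}: {row['mean']:.2f} ± {row['sem']:.2f} (n={int(row['n'])})")
print(f"Mann-Whitney p = {dist.p_value:.3g}")
print("-> larger distances in the case-like condition mean the locus has "
      "detached from the nuclear periphery.")
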