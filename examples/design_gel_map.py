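"""Generate a counterbalanced gel-loading map for a 2x2 factorial design.

16 subjects in four groups (wild-type/transgenic x drug/vehicle) on 9-lane
gels with a ladder in lane 1 leave 8 usable lanes, so each technical
replicate needs two gels; every gel carries two subjects of every group and
same-group subjects are never adjacent.
"""

from blotkit import DesignSpec, Sample, count_adjacency_violations, generate_gel_map

samples = [
    Sample(f"s{g * 4 + i + 1}", group)
    for g, group in enumerate(["WT-Drug", "WT-Veh", "TG-Drug", "TG-Veh"])
    for i in range(4)
]

spec = DesignSpec(samples=samples, lanes_per_gel=9, n_replicates=3, seed=42)
gelmap = generate_gel_map(spec)
per_gel, total = count_adjacency_violations(gelmap)

print(f"{gelmap.n_gels_per_replicate} gels per replicate, "
      f"{spec.n_replicates} replicates, {total} same-group adjacencies\n")
for rep in (1,):
    for gel in range(1, gelmap.n_gels_per_replicate + 1):
        row = []
        for lane in gelmap.gel_lanes(rep, gel):
            c = lane.content
            row.append(c if isinstance(c, str) else f"{c.subject_id}({c.group})")
        print(f"replicate {rep}, gel {gel}: " + " | ".join(row))
print("\nEach gel holds every group; a group effect can no longer be an"
      " artifact of one gel or one region of a gel.")
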