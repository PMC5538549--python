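"""Runs of homozygosity and the minimal shared candidate interval.

Simulates SNP-array genotypes for 7 affected children of a consanguineous
pedigree who share one autozygous segment, detects each individual's runs
of homozygosity, intersects them into the minimal candidate interval, and
scores markers with a windowed homozygosity LOD.
"""

from retmap import detect_roh_all, interval_length_kb, lod_profile, minimal_overlap_roh
from retmap.simulate import CohortSpec, gen_genotypes

spec = CohortSpec(seed=7, error_rate=0.0, missing_rate=0.01)
genotypes, marker_map, truth = gen_genotypes(spec)
seg = truth["segment"]
print(f"true autozygous segment: {seg.chrom}:{seg.start}-{seg.end} "
      f"({interval_length_kb(seg)} kb)")

affected = genotypes[genotypes["role"] == "affected"]
segments = detect_roh_all(affected, marker_map, min_markers=25, min_length_kb=500)
for ind, segs in segments.items():
    print(f"  {ind}: {len(segs)} qualifying run(s)")

candidate = minimal_overlap_roh(segments, anchor=seg)
iv = candidate.interval
print(f"\nminimal overlap of all affecteds: {iv.chrom}:{iv.start}-{iv.end} "
      f"({interval_length_kb(iv)} kb)")
print(f"haplotype-inconsistent markers inside it: "
      f"{len(candidate.inconsistent_markers)}")

prof = lod_profile(genotypes, marker_map, eps=0.01, window=11)
peak = prof.loc[prof["lod"].idxmax()]
print(f"\nwindowed homozygosity LOD peak: {peak['marker_id']} at "
      f"{int(peak['pos'])} (LOD={peak['lod']:.1f})")
print("inside the true segment:", seg.contains(int(peak["pos"])))
print("\nA sustained run of shared homozygosity, not any single marker, "
      "localises the recessive locus; the windowed LOD sums the evidence "
      "over adjacent markers.")
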