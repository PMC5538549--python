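"""Intron-retention quantification from splice-junction reads.

Simulates allele-tagged junction reads over the demonstration gene for the
three genotype groups (homozygous affected, heterozygous parent, wild-type
control), pools counts per group, estimates per-intron retention with 95%
Wilson intervals, tests group differences (Fisher exact + Holm) and checks
the cis-association of retention with the mutant allele (binomial test).
"""

from retmap import (
    JunctionCounts,
    allelic_association,
    compare_groups,
    count_junctions,
    retention_table,
)
from retmap.simulate import ReadSimConfig, demo_gene, gen_junction_reads

model, region, variant = demo_gene(0)
cfg = ReadSimConfig(gene=model, seed=11, fragments_per_sample_per_intron=400)
reads, truth = gen_junction_reads(cfg)
print(f"simulated {len(reads)} junction-informative reads "
      f"({len(model.introns)} introns x 32 samples)")

per_sample, per_group = count_junctions(reads, model)
table = retention_table(per_group)
focal = table[table["intron"] == 6]
print("\nfocal intron 6, pooled per genotype group:")
for _, r in focal.iterrows():
    print(f"  {r['group']:9s} spanning={r['spanning']:5d} spliced={r['spliced']:5d}"
          f"  R={100 * r['retention']:5.1f}%"
          f"  95% CI ({100 * r['ci_low']:.1f}, {100 * r['ci_high']:.1f})")
print("  (simulated truth: affected 66%, parent 12%, control 7%)")

counts = {
    r["group"]: JunctionCounts(6, int(r["spanning"]), int(r["spliced"]), r["group"])
    for _, r in focal.iterrows()
}
print("\npairwise Fisher exact tests, Holm-adjusted:")
for c in compare_groups(counts):
    print(f"  {c.group_a} vs {c.group_b}: p={c.p_raw:.3g}  p_holm={c.p_adjusted:.3g}")

het = reads[reads["group"] == "parent"]
assoc = allelic_association(het, variant["alt"], variant["ref"])
print(f"\nheterozygote reads covering the variant: "
      f"{assoc.mutant_reads} mutant / {assoc.reference_reads} reference "
      f"-> mutant fraction {100 * assoc.mutant_fraction:.0f}% "
      f"(binomial p vs 50%: {assoc.p_value:.3g})")
print("A mutant fraction above 50% shows the retained transcripts arise "
      "preferentially from the mutant allele: the variant acts in cis.")
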