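"""Orthogonal splicing and expression quantification (RT-PCR + qPCR).

Simulates per-sample fluorescent fragment areas for the spliced and
unspliced amplicons at the study group distributions (85/38/24% unspliced,
20 samples per group), summarises groups with two-tailed unpaired t-tests
under Holm adjustment, and computes relative transcript abundance by the
comparative-Ct (2^-ddCt) method.
"""

from retmap import ddct_relative, group_summary
from retmap.simulate import SpliceQuantSimConfig, gen_splice_quant

records, truth = gen_splice_quant(SpliceQuantSimConfig(seed=3, n_per_group=20))
summaries, tests = group_summary(records)
print("percent unspliced RT-PCR product, mean +/- SD per group:")
for s in summaries:
    mu = truth["fraction_unspliced"][s.group][0] * 100
    print(f"  {s.group:9s} {s.mean_percent_unspliced:5.1f} +/- "
          f"{s.sd_percent_unspliced:4.1f}%  (n={s.n}, truth {mu:.0f}%)")

print("\npairwise two-tailed t-tests, Holm-adjusted:")
for t in tests:
    print(f"  {t.group_a} vs {t.group_b}: p={t.p_raw:.3g}  p_holm={t.p_adjusted:.3g}")

print("\nrelative target expression by 2^-ddCt (reference: control):")
for r in ddct_relative(records, "control"):
    print(f"  {r.group:9s} {100 * r.relative:5.1f}%  "
          f"95% CI ({100 * r.ci_low:.0f}%, {100 * r.ci_high:.0f}%)")
print("\nReduced expression in mutation carriers is consistent with decay "
      "of the intron-retaining transcript; the area ratio is a relative "
      "splicing measure, not an absolute one.")
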