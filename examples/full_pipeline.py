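"""The complete discovery analysis on a synthetic cohort.

Writes a demo bundle (genotypes, VCF, gene model, junction reads, RT-PCR
and qPCR tables plus a truth sidecar) and runs every stage: ROH mapping ->
variant triage -> intron retention -> consequence -> splice quantification,
producing one machine-readable report.
"""

import json
import tempfile
from pathlib import Path

from retmap.pipeline import make_demo, run_pipeline

outdir = Path(tempfile.mkdtemp(prefix="retmap_demo_"))
cfg = make_demo(outdir, seed=7)
report = run_pipeline(cfg)

ci = report["candidate_interval"]
print(f"candidate interval : {ci['chrom']}:{ci['start']}-{ci['end']}")
print(f"LOD peak           : {ci['lod_peak']:.1f} at {ci['lod_peak_pos']}")
print(f"rare noncoding in interval: {report['triage']['rare_noncoding_in_interval']}"
      f" (rare coding: {report['triage']['rare_coding_in_interval']})")
print(f"top retained intron (affected): "
      f"{report['retention']['top_retained_intron_affected']}")
for g, v in report["retention"]["by_group"].items():
    print(f"  {g:9s} retention {100 * v['retention']:5.1f}%")
assoc = report["retention"]["allelic_association"]
print(f"allelic association: mutant fraction {100 * assoc['mutant_fraction']:.0f}% "
      f"(p={assoc['p_value']:.3g})")
cons = report["consequence"]
print(f"consequence        : {cons['mutant_protein_len']} aa truncation "
      f"(wild type {cons['wildtype_protein_len']} aa), "
      f"NMD={cons['nmd_predicted']}")
print(f"\nfull report: {cfg.outdir}/report.json")
print("Every number above is recomputed from the seeded synthetic inputs; "
      "rerunning with the same seed reproduces it byte for byte.")
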