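"""Protein consequence of retaining the focal intron, and NMD prediction.

Translates the demonstration gene's CDS with intron 6 retained: the
intronic reading frame hits a premature stop after 52 translated intronic
bases, truncating the 566-residue protein to 366 residues with 17 aberrant
C-terminal residues, and the stop lies far upstream of the remaining final
exon junction, so nonsense-mediated decay is predicted.
"""

from retmap import GenomicInterval, amplicon_lengths, retained_intron_orf
from retmap.simulate import demo_gene

model, region, _ = demo_gene(0)
cons = retained_intron_orf(model, region, intron=6, rule_nt=50)
print(f"intron 6 length          : {model.introns[5].length_bp} bp")
print(f"CDS before intron 6      : {model.cds_before_intron(6)} nt")
print(f"premature stop           : {cons.has_premature_stop} "
      f"(after {cons.stop_offset_bp} bp of the intron)")
print(f"mutant protein length    : {cons.mutant_protein_len} aa "
      f"(wild type {cons.wildtype_protein_len} aa)")
print(f"aberrant residues        : {cons.aberrant_residues}")
print(f"NMD predicted (50-nt rule): {cons.nmd_predicted}")

# RT-PCR amplicon design across the focal intron
fwd = GenomicInterval("21", *sorted((model.transcript_to_genomic(1046),
                                     model.transcript_to_genomic(1065))))
rev = GenomicInterval("21", *sorted((model.transcript_to_genomic(1147),
                                     model.transcript_to_genomic(1166))))
spliced, unspliced = amplicon_lengths(model, 6, fwd, rev)
print(f"\nRT-PCR products for a primer pair flanking intron 6: "
      f"spliced {spliced} bp, unspliced {unspliced} bp")
print("The unspliced product exceeds the spliced one by exactly the intron "
      "length, so the two splice outcomes separate cleanly on a gel.")
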