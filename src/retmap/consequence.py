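"""Protein-level consequences of retaining an intron.

Translating a transcript that retains an intron inside its CDS usually runs
into a premature termination codon (PTC) within the intron.  This module
reports the truncated protein length, the number of aberrant residues
introduced by intronic sequence, the position of the stop within the
intron, and a nonsense-mediated decay (NMD) prediction under the 50-nt
exon-junction rule: a PTC more than 50 nt upstream of the final exon–exon
junction of the (mutant, intron-retaining) transcript marks the transcript
for degradation.

Counting conventions, chosen to be self-consistent:

* ``stop_offset_bp`` is the number of retained-intron bases translated into
  protein before the stop terminates translation; the stop codon itself
  begins at intron base ``stop_offset_bp + 1``.
* ``aberrant_residues`` counts residues whose codon's *first* base is
  intronic; the chimeric codon straddling the exon–intron junction is not
  counted as aberrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq

from .models import GeneModel, GenomicInterval, RegionSequence

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class RetainedIntronConsequence:
    intron: int
    has_premature_stop: bool
    stop_offset_bp: int | None       # translated intronic bases before the stop
    mutant_protein_len: int
    wildtype_protein_len: int
    aberrant_residues: int | None
    nmd_predicted: bool


def _check_wildtype_cds(cds: str) -> None:
    if len(cds) % 3 != 0:
        raise ValueError("wild-type CDS length is not a multiple of 3")
    if not cds.startswith("ATG"):
        raise ValueError("wild-type CDS does not start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError("wild-type CDS does not end with a stop codon")
    internal = {cds[i : i + 3] for i in range(0, len(cds) - 3, 3)}
    if internal & STOP_CODONS:
        raise ValueError("wild-type CDS contains an internal stop codon")


def retained_intron_orf(
    model: GeneModel,
    region: RegionSequence,
    intron: int,
    rule_nt: int = 50,
) -> RetainedIntronConsequence:
    """Translate the CDS with intron ``intron`` retained and call the outcome.

    The intron must lie inside the CDS.  If translation reaches the end of
    the mutant coding sequence without a stop (a frame-preserving, stop-free
    intron followed by the normal reading frame), ``has_premature_stop`` is
    False and the mutant protein is the wild type plus an in-frame
    insertion.
    """
    cds = model.cds_sequence(region)
    _check_wildtype_cds(cds)
    wildtype_len = len(cds) // 3 - 1

    cds_before = model.cds_before_intron(intron)
    if cds_before <= 0 or cds_before >= len(cds):
        raise ValueError(f"intron {intron} does not lie inside the CDS")
    intron_seq = model.intron_sequence(region, intron)
    mutant_cds = cds[:cds_before] + intron_seq + cds[cds_before:]

    peptide = str(Seq(mutant_cds[: len(mutant_cds) - len(mutant_cds) % 3]).translate())
    stop_at = peptide.find("*")  # 0-based residue index of the stop
    if stop_at == -1:
        return RetainedIntronConsequence(
            intron=intron,
            has_premature_stop=False,
            stop_offset_bp=None,
            mutant_protein_len=len(peptide),
            wildtype_protein_len=wildtype_len,
            aberrant_residues=None,
            nmd_predicted=False,
        )
    mutant_len = stop_at
    premature = mutant_len < wildtype_len
    # translated intronic bases before the stop (None if the stop falls
    # downstream of the retained intron, i.e. a frame-shifted exonic stop)
    translated_intronic = 3 * mutant_len - cds_before
    stop_offset = translated_intronic if 0 <= translated_intronic <= len(intron_seq) - 3 else None
    aberrant = (
        mutant_len - math.ceil(cds_before / 3) if stop_offset is not None else None
    )
    nmd = nmd_predict(
        stop_tx_pos=model.utr5_len + 3 * (mutant_len + 1),
        junctions_tx=mutant_transcript_junctions(model, intron),
        rule_nt=rule_nt,
    )
    return RetainedIntronConsequence(
        intron=intron,
        has_premature_stop=premature,
        stop_offset_bp=stop_offset,
        mutant_protein_len=mutant_len,
        wildtype_protein_len=wildtype_len,
        aberrant_residues=aberrant,
        nmd_predicted=premature and nmd,
    )


def mutant_transcript_junctions(model: GeneModel, retained_intron: int) -> list[int]:
    """Exon–exon junction coordinates of the intron-retaining transcript.

    Retaining intron ``i`` removes the junction between exons ``i`` and
    ``i+1`` and shifts all downstream junctions by the intron length.
    Coordinates are 1-based positions of the last base before each junction.
    """
    ilen = model.introns[retained_intron - 1].length_bp
    out = []
    for j, tx in enumerate(model.tx_junctions(), start=1):
        if j == retained_intron:
            continue
        out.append(tx + ilen if j > retained_intron else tx)
    return out


def nmd_predict(stop_tx_pos: int, junctions_tx: list[int], rule_nt: int = 50) -> bool:
    """50-nt rule: NMD iff the stop lies > ``rule_nt`` nt upstream of the
    final exon–exon junction (strict inequality).

    ``stop_tx_pos`` is the transcript coordinate of the stop codon's last
    base in the same coordinate frame as ``junctions_tx``.
    """
    if not junctions_tx:
        return False
    return max(junctions_tx) - stop_tx_pos > rule_nt


def amplicon_lengths(
    model: GeneModel,
    intron: int,
    forward_primer: GenomicInterval,
    reverse_primer: GenomicInterval,
) -> tuple[int, int]:
    """Spliced and unspliced RT-PCR product lengths for primers flanking an intron.

    Primers must lie entirely within the two exons flanking the intron (one
    in each).  Returns ``(spliced_bp, unspliced_bp)``; the unspliced product
    exceeds the spliced one by exactly the intron length.
    """
    model._check_intron(intron)
    up_exon, down_exon = model.exons[intron - 1], model.exons[intron]

    def _within(primer: GenomicInterval, exon: GenomicInterval) -> bool:
        return exon.start <= primer.start and primer.end <= exon.end

    exon_of = {}
    for name, primer in (("forward", forward_primer), ("reverse", reverse_primer)):
        if _within(primer, up_exon):
            exon_of[name] = "up"
        elif _within(primer, down_exon):
            exon_of[name] = "down"
        else:
            raise ValueError(
                f"{name} primer does not lie within an exon flanking intron {intron}"
            )
    if len(set(exon_of.values())) != 2:
        raise ValueError("primers must flank the intron (one per flanking exon)")
    tx_ends = [
        model.genomic_to_transcript(p)
        for primer in (forward_primer, reverse_primer)
        for p in (primer.start, primer.end)
    ]
    spliced = max(tx_ends) - min(tx_ends) + 1
    return spliced, spliced + model.introns[intron - 1].length_bp
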