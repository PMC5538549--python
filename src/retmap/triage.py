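"""Variant classification and rare-variant triage within a candidate interval.

Variants are classified against one or more gene models into
nonsynonymous_coding / synonymous_coding / canonical_splice / utr /
intronic / intergenic, with precedence coding > canonical_splice > UTR >
intronic > intergenic and, for multiple transcripts, the most severe
category.  Canonical splice sites are the two intronic bases adjacent to an
exon.  Rarity follows the population-database rule: a variant is common if
its allele frequency is >= the threshold (default 1%) in *any* database;
unobserved frequencies count as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .models import GeneModel, GenomicInterval, RegionSequence

CATEGORIES = (
    "nonsynonymous_coding",
    "synonymous_coding",
    "canonical_splice",
    "utr",
    "intronic",
    "intergenic",
)
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}

NONCODING_CATEGORIES = ("intronic", "intergenic")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    database_afs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if any(f < 0 or f > 1 for f in self.database_afs):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class TriageCall:
    category: str
    rarity: str                       # 'rare' | 'common'
    in_interval: bool
    splice_distance: int | None      # signed bp; +donor side, -acceptor side


def _splice_distance(model: GeneModel, pos: int, intron_no: int) -> int:
    """Signed distance of an intronic base to its nearest splice junction.

    Positive counting downstream from the donor (+1 is the first intronic
    base), negative counting upstream from the acceptor (-1 is the last),
    transcript orientation; the smaller magnitude wins.
    """
    iv = model.introns[intron_no - 1]
    if model.strand == "+":
        from_donor = pos - iv.start + 1
        to_acceptor = iv.end - pos + 1
    else:
        from_donor = iv.end - pos + 1
        to_acceptor = pos - iv.start + 1
    return from_donor if from_donor <= to_acceptor else -to_acceptor


def _classify_base(
    pos: int, model: GeneModel, region: RegionSequence | None, alt: str
) -> tuple[str, int | None]:
    """Category (and splice distance, for intronic bases) of one genomic base."""
    if not model.span.contains(pos):
        return "intergenic", None
    intron_no = model.intron_number_of(pos)
    if intron_no is not None:
        d = _splice_distance(model, pos, intron_no)
        if abs(d) <= 2:
            return "canonical_splice", d
        return "intronic", d
    # exonic
    try:
        c = model.genomic_to_cds(pos)
    except ValueError:
        return "utr", None
    if region is None or len(alt) != 1:
        # indels and unsequenced models: coding but frame/codon unknown;
        # call non-synonymous (the severe choice)
        return "nonsynonymous_coding", None
    cds = model.cds_sequence(region)
    codon_idx = (c - 1) // 3
    within = (c - 1) % 3
    codon = list(cds[codon_idx * 3 : codon_idx * 3 + 3])
    alt_tx = alt if model.strand == "+" else str(Seq(alt).reverse_complement())
    codon_mut = codon.copy()
    codon_mut[within] = alt_tx
    aa_ref = str(Seq("".join(codon)).translate())
    aa_alt = str(Seq("".join(codon_mut)).translate())
    if aa_ref == aa_alt:
        return "synonymous_coding", None
    return "nonsynonymous_coding", None


def classify_variant(
    v: VariantRecord,
    models: list[tuple[GeneModel, RegionSequence | None]],
) -> TriageCall:
    """Classify a variant against a set of gene models (most severe wins).

    Multi-base events are classified by every affected reference base and
    take the most severe touched category.
    """
    affected = range(v.pos, v.pos + max(1, len(v.ref)))
    best: tuple[str, int | None] = ("intergenic", None)
    for model, region in models:
        if model.chrom != v.chrom:
            continue
        for pos in affected:
            cat, d = _classify_base(pos, model, region, v.alt)
            if _SEVERITY[cat] < _SEVERITY[best[0]]:
                best = (cat, d)
    return TriageCall(
        category=best[0], rarity=rare_filter(v), in_interval=False,
        splice_distance=best[1],
    )


def rare_filter(v: VariantRecord, threshold: float = 0.01) -> str:
    """'common' iff the allele frequency is >= threshold in ANY database."""
    if any(f < 0 for f in v.database_afs):
        raise ValueError("negative allele frequency")
    return "common" if any(f >= threshold for f in v.database_afs) else "rare"


def _records_from_table(variants: pd.DataFrame) -> list[VariantRecord]:
    af_cols = [c for c in variants.columns if c.startswith("AF_")]
    recs = []
    for _, r in variants.iterrows():
        afs = tuple(float(r[c]) for c in af_cols if pd.notna(r[c]))
        recs.append(
            VariantRecord(str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"], afs)
        )
    return recs


def triage_table(
    variants: pd.DataFrame,
    models: list[tuple[GeneModel, RegionSequence | None]],
    interval: GenomicInterval,
    af_threshold: float = 0.01,
) -> pd.DataFrame:
    """Classify every variant in a table; adds category/rarity/in_interval."""
    rows = []
    for rec in _records_from_table(variants):
        call = classify_variant(rec, models)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "category": call.category,
                "rarity": rare_filter(rec, af_threshold),
                "in_interval": interval.chrom == rec.chrom
                and interval.contains(rec.pos),
                "splice_distance": call.splice_distance,
            }
        )
    return pd.DataFrame.from_records(
        rows,
        columns=["chrom", "pos", "ref", "alt", "category", "rarity",
                 "in_interval", "splice_distance"],
    )


def triage_summary(
    variants: pd.DataFrame,
    models: list[tuple[GeneModel, RegionSequence | None]],
    interval: GenomicInterval,
    af_threshold: float = 0.01,
) -> dict:
    """Category x rarity contingency inside the interval, with the
    rare-noncoding rollup (intronic + intergenic; UTR reported separately)."""
    table = triage_table(variants, models, interval, af_threshold)
    inside = table[table["in_interval"].astype(bool)]
    counts = {
        cat: {
            "rare": int(((inside["category"] == cat) & (inside["rarity"] == "rare")).sum()),
            "common": int(((inside["category"] == cat) & (inside["rarity"] == "common")).sum()),
        }
        for cat in CATEGORIES
    }
    rare_noncoding = sum(counts[c]["rare"] for c in NONCODING_CATEGORIES)
    return {
        "interval": {"chrom": interval.chrom, "start": interval.start,
                     "end": interval.end},
        "counts": counts,
        "rare_noncoding_in_interval": rare_noncoding,
        "rare_coding_in_interval": counts["nonsynonymous_coding"]["rare"]
        + counts["synonymous_coding"]["rare"],
        "rare_canonical_splice_in_interval": counts["canonical_splice"]["rare"],
        "n_variants_total": int(len(table)),
        "n_in_interval": int(len(inside)),
        "table": table,
    }
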