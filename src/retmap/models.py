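"""Gene models, genomic intervals and coordinate arithmetic.

Everything downstream (read classification, variant triage, consequence
prediction) is expressed against a :class:`GeneModel`: an ordered list of
exons on a genomic strand with annotated translation start/stop.  Internal
coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted at the parsing boundary.

Intron numbering follows *transcript* order: intron ``i`` separates exon
``i`` from exon ``i+1``.  On a minus-strand gene, intron ``i`` therefore has
*higher* genomic coordinates than exon ``i+1`` — the convention required for
HGVS-style intronic offsets such as ``c.1047-9`` to resolve correctly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise ValueError("genomic coordinates are 1-based; start < 1")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


def interval_length_kb(iv: GenomicInterval) -> int:
    """Interval span in kilobases, rounded half-up to the nearest integer.

    Computed as ``(end - start) / 1000``.  Whether one counts the span as the
    coordinate difference or the inclusive base count (difference + 1) is
    immaterial at kb rounding for any realistically sized interval; the
    difference convention is used.
    """
    return int(math.floor((iv.end - iv.start) / 1000.0 + 0.5))


@dataclass(frozen=True)
class HgvsIntronicPosition:
    """An HGVS-style intronic coordinate such as c.1047-9.

    ``cds_anchor`` is the CDS coordinate of the nearest exonic base; a
    negative ``offset`` walks upstream from an acceptor, a positive offset
    walks downstream from a donor, both in transcript orientation.
    """

    cds_anchor: int
    offset: int

    def __post_init__(self) -> None:
        if self.cds_anchor < 1:
            raise ValueError("cds_anchor must be >= 1")
        if self.offset == 0:
            raise ValueError("intronic offset must be non-zero")


@dataclass(frozen=True)
class RegionSequence:
    """Plus-strand genomic sequence for a contiguous region.

    ``start`` is the 1-based genomic coordinate of ``seq[0]``.
    """

    chrom: str
    start: int
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base(self, pos: int) -> str:
        if not (self.start <= pos <= self.end):
            raise KeyError(f"position {pos} outside region {self.start}-{self.end}")
        return self.seq[pos - self.start]

    def subseq(self, start: int, end: int) -> str:
        if start > end:
            raise ValueError("subseq start > end")
        if start < self.start or end > self.end:
            raise KeyError(f"{start}-{end} outside region {self.start}-{self.end}")
        return self.seq[start - self.start : end - self.start + 1]

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class GeneModel:
    """Exon/CDS structure of one transcript on a genomic strand.

    ``exons`` are in transcript order: ascending genomic coordinate on '+',
    descending on '-'.  ``cds_start`` / ``cds_end`` are the genomic positions
    of the first base of the start codon and the last base of the stop codon
    (so on '-', ``cds_start > cds_end`` numerically).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    introns: list[GenomicInterval] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene model strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        genomic_sorted = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic_sorted, genomic_sorted[1:]):
            if a.end >= b.start:
                raise ValueError("exons overlap")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if [(e.start, e.end) for e in self.exons] != [
            (e.start, e.end) for e in expected
        ]:
            raise ValueError("exons are not in transcript order for the strand")
        introns = []
        for up, down in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                introns.append(GenomicInterval(self.chrom, up.end + 1, down.start - 1))
            else:
                introns.append(GenomicInterval(self.chrom, down.end + 1, up.start - 1))
        self.introns = introns
        for name, pos in (("cds_start", self.cds_start), ("cds_end", self.cds_end)):
            if not any(e.contains(pos) for e in self.exons):
                raise ValueError(f"{name} ({pos}) does not fall inside an exon")
        if self.genomic_to_transcript(self.cds_start) >= self.genomic_to_transcript(
            self.cds_end
        ):
            raise ValueError("cds_start must precede cds_end in transcript order")

    # ------------------------------------------------------------------ #
    # coordinate conversion

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tx_length(self) -> int:
        return sum(e.length_bp for e in self.exons)

    exonic_length = tx_length

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    def exon_number_of(self, pos: int) -> int | None:
        """1-based transcript-order exon number containing pos, or None."""
        for i, e in enumerate(self.exons, start=1):
            if e.contains(pos):
                return i
        return None

    def intron_number_of(self, pos: int) -> int | None:
        for i, iv in enumerate(self.introns, start=1):
            if iv.contains(pos):
                return i
        return None

    def genomic_to_transcript(self, pos: int) -> int:
        """1-based spliced-transcript coordinate of an exonic genomic base."""
        offset = 0
        for e in self.exons:
            if e.contains(pos):
                if self.strand == "+":
                    return offset + (pos - e.start + 1)
                return offset + (e.end - pos + 1)
            offset += e.length_bp
        raise ValueError(f"position {pos} is not exonic in {self.transcript_id}")

    def transcript_to_genomic(self, t: int) -> int:
        if t < 1 or t > self.tx_length:
            raise ValueError(f"transcript coordinate {t} outside 1..{self.tx_length}")
        offset = 0
        for e in self.exons:
            if t <= offset + e.length_bp:
                within = t - offset
                if self.strand == "+":
                    return e.start + within - 1
                return e.end - within + 1
            offset += e.length_bp
        raise AssertionError("unreachable")

    @property
    def utr5_len(self) -> int:
        return self.genomic_to_transcript(self.cds_start) - 1

    @property
    def cds_len(self) -> int:
        return (
            self.genomic_to_transcript(self.cds_end)
            - self.genomic_to_transcript(self.cds_start)
            + 1
        )

    def cds_to_genomic(self, c: int) -> int:
        if c < 1 or c > self.cds_len:
            raise ValueError(f"CDS coordinate {c} outside 1..{self.cds_len}")
        return self.transcript_to_genomic(self.utr5_len + c)

    def genomic_to_cds(self, pos: int) -> int:
        c = self.genomic_to_transcript(pos) - self.utr5_len
        if c < 1 or c > self.cds_len:
            raise ValueError(f"position {pos} is exonic but outside the CDS")
        return c

    def cds_before_intron(self, i: int) -> int:
        """Number of CDS nucleotides upstream of intron ``i`` (transcript order)."""
        self._check_intron(i)
        tx_junction = sum(e.length_bp for e in self.exons[:i])  # last base of exon i
        return max(0, min(tx_junction - self.utr5_len, self.cds_len))

    def tx_junctions(self) -> list[int]:
        """Spliced-transcript coordinates of the last base of each non-final exon."""
        out, acc = [], 0
        for e in self.exons[:-1]:
            acc += e.length_bp
            out.append(acc)
        return out

    def _check_intron(self, i: int) -> None:
        if not (1 <= i <= len(self.introns)):
            raise ValueError(
                f"intron {i} out of range (transcript has {len(self.introns)} introns)"
            )

    # ------------------------------------------------------------------ #
    # sequence extraction (transcript sense)

    def exon_sequence(self, region: RegionSequence, i: int) -> str:
        e = self.exons[i - 1]
        s = region.subseq(e.start, e.end)
        return s if self.strand == "+" else revcomp(s)

    def intron_sequence(self, region: RegionSequence, i: int) -> str:
        self._check_intron(i)
        iv = self.introns[i - 1]
        s = region.subseq(iv.start, iv.end)
        return s if self.strand == "+" else revcomp(s)

    def spliced_sequence(self, region: RegionSequence) -> str:
        return "".join(
            self.exon_sequence(region, i) for i in range(1, self.n_exons + 1)
        )

    def cds_sequence(self, region: RegionSequence) -> str:
        tx = self.spliced_sequence(region)
        return tx[self.utr5_len : self.utr5_len + self.cds_len]

    # ------------------------------------------------------------------ #
    # serialization

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [[e.start, e.end] for e in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            transcript_id=d["transcript_id"],
            chrom=d["chrom"],
            strand=d["strand"],
            exons=[
                GenomicInterval(d["chrom"], s, e, d["strand"]) for s, e in d["exons"]
            ],
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GeneModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def resolve_hgvs_intronic(
    pos: HgvsIntronicPosition, model: GeneModel
) -> tuple[GenomicInterval, int]:
    """Resolve an intronic HGVS coordinate to a genomic base and intron number.

    Walks ``|offset|`` bases from the anchor's genomic position in the
    transcript's 5'→3' pre-mRNA direction (downstream for positive offsets,
    upstream for negative), respecting strand.  The landing base must lie in
    an intron of the model, which also enforces that the anchor sits at the
    appropriate exon boundary and that the offset does not overshoot the
    adjacent intron.
    """
    g_anchor = model.cds_to_genomic(pos.cds_anchor)
    sign = 1 if model.strand == "+" else -1
    g = g_anchor + sign * pos.offset
    intron_no = model.intron_number_of(g)
    if intron_no is None:
        raise ValueError(
            f"c.{pos.cds_anchor}{pos.offset:+d} does not resolve to an intronic base "
            f"(landed at {model.chrom}:{g})"
        )
    if abs(pos.offset) > model.introns[intron_no - 1].length_bp:
        raise ValueError("offset exceeds adjacent intron length")
    return GenomicInterval(model.chrom, g, g, model.strand), intron_no


# ---------------------------------------------------------------------- #
# file formats


def _parse_bed12(line: str) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError("BED12 line has fewer than 12 fields")
    chrom, chrom_start, chrom_end = f[0], int(f[1]), int(f[2])
    name, strand = f[3], f[5]
    thick_start, thick_end = int(f[6]), int(f[7])
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError("blockCount disagrees with blockSizes/blockStarts")
    if starts != sorted(starts):
        raise ValueError("BED12 blockStarts must be sorted ascending")
    if starts[0] != 0 or chrom_start + starts[-1] + sizes[-1] != chrom_end:
        raise ValueError("BED12 blocks do not span chromStart..chromEnd")
    exons_asc = [
        GenomicInterval(chrom, chrom_start + s + 1, chrom_start + s + sz, strand)
        for s, sz in zip(starts, sizes)
    ]
    if strand == "+":
        cds_start, cds_end = thick_start + 1, thick_end
        exons = exons_asc
    else:
        cds_start, cds_end = thick_end, thick_start + 1
        exons = exons_asc[::-1]
    return GeneModel(name, chrom, strand, exons, cds_start, cds_end)


def _parse_gff_lite(lines: list[str]) -> list[GeneModel]:
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    for ln in lines:
        ln = ln.rstrip("\n")
        if not ln or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) != 6:
            raise ValueError(f"GFF-lite line must have 6 fields: {ln!r}")
        seqid, feature, start, end, strand, tx = f
        if feature not in {"exon", "CDS"}:
            raise ValueError(f"unknown feature {feature!r}")
        rec = per_tx.setdefault(tx, {"chrom": seqid, "strand": strand, "exons": [], "cds": []})
        if rec["chrom"] != seqid or rec["strand"] != strand:
            raise ValueError(f"inconsistent chrom/strand for transcript {tx}")
        key = "exons" if feature == "exon" else "cds"
        rec[key].append((int(start), int(end)))
        if tx not in order:
            order.append(tx)
    out = []
    for tx in order:
        rec = per_tx[tx]
        if not rec["exons"] or not rec["cds"]:
            raise ValueError(f"transcript {tx} lacks exon or CDS rows")
        exons_asc = sorted(rec["exons"])
        strand = rec["strand"]
        exons = [
            GenomicInterval(rec["chrom"], s, e, strand)
            for s, e in (exons_asc if strand == "+" else exons_asc[::-1])
        ]
        lo = min(s for s, _ in rec["cds"])
        hi = max(e for _, e in rec["cds"])
        cds_start, cds_end = (lo, hi) if strand == "+" else (hi, lo)
        out.append(GeneModel(tx, rec["chrom"], strand, exons, cds_start, cds_end))
    return out


def load_gene_model(path, fmt: str = "auto") -> GeneModel:
    """Load a single-transcript gene model from BED12 or GFF-lite TSV.

    GFF-lite is a 6-column TSV: seqid, feature in {exon, CDS}, start, end
    (1-based inclusive), strand, transcript_id.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty gene model file")
    if fmt == "auto":
        fmt = "gff" if lines[0].split("\t")[1] in {"exon", "CDS"} else "bed12"
    if fmt == "bed12":
        models = [_parse_bed12(ln) for ln in lines]
    elif fmt in {"gff", "gff-lite"}:
        models = _parse_gff_lite(lines)
    else:
        raise ValueError(f"unknown gene model format {fmt!r}")
    if len(models) != 1:
        raise ValueError(f"{path}: expected one transcript, found {len(models)}")
    return models[0]


def write_gene_model_bed12(model: GeneModel, path) -> None:
    exons_asc = sorted(model.exons, key=lambda e: e.start)
    chrom_start = exons_asc[0].start - 1
    chrom_end = exons_asc[-1].end
    thick_start = min(model.cds_start, model.cds_end) - 1
    thick_end = max(model.cds_start, model.cds_end)
    sizes = ",".join(str(e.length_bp) for e in exons_asc)
    starts = ",".join(str(e.start - 1 - chrom_start) for e in exons_asc)
    with open(path, "w") as fh:
        fh.write(
            "\t".join(
                str(x)
                for x in (
                    model.chrom, chrom_start, chrom_end, model.transcript_id, 0,
                    model.strand, thick_start, thick_end, "0", len(exons_asc),
                    sizes, starts,
                )
            )
            + "\n"
        )


def write_gene_model_gff_lite(model: GeneModel, path) -> None:
    cds_lo = min(model.cds_start, model.cds_end)
    cds_hi = max(model.cds_start, model.cds_end)
    with open(path, "w") as fh:
        for e in sorted(model.exons, key=lambda x: x.start):
            fh.write(
                f"{model.chrom}\texon\t{e.start}\t{e.end}\t{model.strand}\t{model.transcript_id}\n"
            )
            lo, hi = max(e.start, cds_lo), min(e.end, cds_hi)
            if lo <= hi:
                fh.write(
                    f"{model.chrom}\tCDS\t{lo}\t{hi}\t{model.strand}\t{model.transcript_id}\n"
                )
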