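"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the data structure of a consanguineous recessive
disease study: an autozygous segment shared by affected individuals around a
disease locus, a mix of rare/common coding and noncoding variants inside and
outside the run of homozygosity, allele-tagged RNA-seq reads over a
multi-exon gene with one poorly spliced intron, RT-PCR fragment areas for
spliced/unspliced amplicons, and qPCR Ct values.

Every generator takes an explicit seed (no hidden global RNG state) and
returns its latent truth alongside the emitted tables, so downstream
estimators can be tested by parameter recovery.

Default parameters reproduce the study conditions: the focal intron is
retained in 66% of junction-informative evidence per mutant allele in
homozygotes, 7% per wild-type allele, and the heterozygote mutant-allele
rate is solved so the pooled heterozygote proportion is 12%; RT-PCR
fraction-unspliced group means/SDs default to 85±5%, 38±13% and 24±10% for
affected/parent/control, and the qPCR generator defaults to 56% relative
target expression in heterozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    GeneModel,
    GenomicInterval,
    HgvsIntronicPosition,
    RegionSequence,
    resolve_hgvs_intronic,
    revcomp,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

# retention probability per allele, by allele class
RETENTION_MUTANT_HOM = 0.66   # per mutant allele in homozygotes (pooled 66%)
RETENTION_WILDTYPE = 0.07     # per wild-type allele (pooled control 7%)
RETENTION_HET_POOLED = 0.12   # pooled heterozygous-parent proportion
# pooled heterozygote = mean of allele rates under equal allelic output
RETENTION_MUTANT_HET = 2 * RETENTION_HET_POOLED - RETENTION_WILDTYPE  # 0.17

GROUP_ALLELES = {
    "affected": ("mut", "mut"),
    "parent": ("wt", "mut"),
    "control": ("wt", "wt"),
}


# ====================================================================== #
# demonstration gene: an 8-exon minus-strand gene whose intron 6 carries
# a near-acceptor variant, laid out so that the published coordinate
# arithmetic is reproduced exactly:
#   c.1047-9 resolves to g.33,582,064 (T>C on the plus strand),
#   intron 6 is 109 bp, translation of the retained intron adds 17
#   aberrant residues and stops after 52 intronic bases (366 vs 566 aa).

_EXON_LENS = (200, 150, 180, 160, 170, 246, 300, 400)  # transcript order
_INTRON_LENS = (500, 400, 350, 300, 250, 109, 600)
_UTR5_LEN = 60
_CDS_LEN = 1701          # 566 residues + stop
_UTR3_LEN = 45
_GENE_TOP = 33_585_070   # genomic coordinate of transcript base 1
_FOCAL_INTRON = 6
_STOP_OFFSET_IN_INTRON = 52   # translated intronic bases before the stop
_VARIANT_INTRON_OFFSET = -9   # c.1047-9


def _layout_exons() -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    exons, introns = [], []
    hi = _GENE_TOP
    for i, elen in enumerate(_EXON_LENS):
        exons.append(GenomicInterval("21", hi - elen + 1, hi, "-"))
        hi -= elen
        if i < len(_INTRON_LENS):
            ilen = _INTRON_LENS[i]
            introns.append(GenomicInterval("21", hi - ilen + 1, hi, "-"))
            hi -= ilen
    return exons, introns


def _random_codon(rng: np.random.Generator, forbid_prefix: str | None = None) -> str:
    while True:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c in STOP_CODONS:
            continue
        if forbid_prefix and c.startswith(forbid_prefix):
            continue
        return c


def demo_gene(seed: int = 0) -> tuple[GeneModel, RegionSequence, dict]:
    """Build the demonstration gene model, its region sequence and variant.

    Returns ``(model, region, variant)`` where ``variant`` carries the
    genomic position, plus-strand ref/alt bases, transcript-sense ref/alt,
    the HGVS description and the focal intron number.
    """
    rng = np.random.default_rng([int(seed), 0xD09])
    exons, _ = _layout_exons()
    # transcript-sense pieces
    utr5 = "".join(rng.choice(list("ACGT"), size=_UTR5_LEN))
    n_codons = _CDS_LEN // 3
    codons = ["ATG"]
    for k in range(2, n_codons):
        # codon 349 straddles the intron-6 junction in the retained
        # transcript: its first two bases + intron base 'G' must not form a
        # stop, so forbid a 'TA' prefix there.
        codons.append(_random_codon(rng, forbid_prefix="TA" if k == 349 else None))
    codons.append("TAA")
    cds = "".join(codons)
    assert len(cds) == _CDS_LEN
    utr3 = "".join(rng.choice(list("ACGT"), size=_UTR3_LEN))

    introns_seq = []
    for i, ilen in enumerate(_INTRON_LENS, start=1):
        if i == _FOCAL_INTRON:
            # GT ... in-frame non-stop codons ... TAA stop at bases 53-55 ... AG
            # reading frame inside the intron: codon boundaries at bases 2-4,
            # 5-7, ..., 50-52 (the junction codon consumes intron base 1).
            body = ["G", "T"]
            # codon at bases 2-4 starts with the T at base 2
            first = "T" + "".join(rng.choice(list("ACGT"), size=2))
            while first in STOP_CODONS:
                first = "T" + "".join(rng.choice(list("ACGT"), size=2))
            body.extend(first[1:])
            for _ in range(15):  # codons at bases 5-7 ... 47-49
                body.append(_random_codon(rng))
            body.append(_random_codon(rng))  # bases 50-52
            body.append("TAA")  # stop at bases 53-55
            seq = "".join(body)
            tail = "".join(rng.choice(list("ACGT"), size=ilen - len(seq) - 2))
            seq = seq + tail + "AG"
            seq = list(seq)
            seq[ilen + _VARIANT_INTRON_OFFSET] = "A"  # transcript-sense ref at -9
            introns_seq.append("".join(seq))
        else:
            mid = "".join(rng.choice(list("ACGT"), size=ilen - 4))
            introns_seq.append("GT" + mid + "AG")
        assert len(introns_seq[-1]) == ilen

    tx_exonic = utr5 + cds + utr3
    pre_mrna, pos = [], 0
    for i, elen in enumerate(_EXON_LENS):
        pre_mrna.append(tx_exonic[pos : pos + elen])
        pos += elen
        if i < len(_INTRON_LENS):
            pre_mrna.append(introns_seq[i])
    pre = "".join(pre_mrna)

    region = RegionSequence("21", _GENE_TOP - len(pre) + 1, revcomp(pre))
    def tx_to_genomic(t: int) -> int:
        off = 0
        for e in exons:  # transcript order, minus strand
            if t <= off + e.length_bp:
                return e.end - (t - off) + 1
            off += e.length_bp
        raise ValueError(t)

    cds_start = tx_to_genomic(_UTR5_LEN + 1)        # genomic pos of the A of ATG
    cds_end = tx_to_genomic(_UTR5_LEN + _CDS_LEN)   # last base of the stop codon
    model = GeneModel("DEMO-TX1", "21", "-", exons, cds_start, cds_end)

    hgvs = HgvsIntronicPosition(cds_anchor=1047, offset=_VARIANT_INTRON_OFFSET)
    var_iv, intron_no = resolve_hgvs_intronic(hgvs, model)
    variant = {
        "chrom": "21",
        "pos": var_iv.start,
        "ref": region.base(var_iv.start),   # plus strand: T
        "alt": "C",
        "tx_ref": "A",
        "tx_alt": "G",
        "hgvs": "c.1047-9A>G",
        "intron": intron_no,
    }
    return model, region, variant


def demo_gene_plus(seed: int = 0) -> tuple[GeneModel, RegionSequence]:
    """A small 3-exon plus-strand gene outside the run of homozygosity.

    Used as a second transcript for triage (it hosts the fixture's rare
    coding variants outside the candidate interval) and for plus-strand
    coordinate tests.
    """
    rng = np.random.default_rng([int(seed), 0xD10])
    start = 30_550_001
    exon_lens = (200, 300, 300)
    intron_lens = (200, 150)
    utr5, cds_len, utr3 = 50, 600, 150
    exons, lo = [], start
    introns = []
    for i, elen in enumerate(exon_lens):
        exons.append(GenomicInterval("21", lo, lo + elen - 1, "+"))
        lo += elen
        if i < len(intron_lens):
            introns.append(GenomicInterval("21", lo, lo + intron_lens[i] - 1, "+"))
            lo += intron_lens[i]
    n_codons = cds_len // 3
    cds = "ATG" + "".join(_random_codon(rng) for _ in range(n_codons - 2)) + "TAA"
    tx_exonic = (
        "".join(rng.choice(list("ACGT"), size=utr5))
        + cds
        + "".join(rng.choice(list("ACGT"), size=utr3))
    )
    pieces, pos = [], 0
    for i, elen in enumerate(exon_lens):
        pieces.append(tx_exonic[pos : pos + elen])
        pos += elen
        if i < len(intron_lens):
            mid = "".join(rng.choice(list("ACGT"), size=intron_lens[i] - 4))
            pieces.append("GT" + mid + "AG")
    region = RegionSequence("21", start, "".join(pieces))
    cds_start = start + utr5

    def tx_to_genomic(t: int) -> int:
        off = 0
        for e in exons:
            if t <= off + e.length_bp:
                return e.start + (t - off) - 1
            off += e.length_bp
        raise ValueError(t)

    cds_end = tx_to_genomic(utr5 + cds_len)
    model = GeneModel("DEMO-TX2", "21", "+", exons, cds_start, cds_end)
    return model, region


# ====================================================================== #
# SNP genotypes


@dataclass
class CohortSpec:
    """Cohort layout and marker map for the genotype generator.

    Affected individuals are homozygous for one founder haplotype across
    ``autozygous_segment``; parents and controls are drawn under
    Hardy–Weinberg everywhere.  ``error_rate`` flips an autozygous
    homozygous call to a heterozygous call (genotyping error);
    ``missing_rate`` masks calls as low-quality.
    """

    n_affected: int = 7
    n_parents: int = 15
    n_controls: int = 10
    marker_count: int = 1000
    map_start: int = 30_000_000
    map_end: int = 40_000_000
    chrom: str = "21"
    allele_freq: float | np.ndarray = 0.5   # frequency of allele B per marker
    error_rate: float = 0.0
    missing_rate: float = 0.0
    autozygous_segment: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("21", 33_364_965, 34_029_433)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        q = np.asarray(self.allele_freq, dtype=float)
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("marker allele frequencies must lie in (0, 1)")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (
            self.map_start <= self.autozygous_segment.start
            and self.autozygous_segment.end <= self.map_end
        ):
            raise ValueError("autozygous segment lies outside the marker map")


def gen_genotypes(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a genotype table and return it with its latent truth.

    Returns ``(genotypes, marker_map, truth)``: a calls DataFrame
    (individuals x markers, values in {AA, AB, BB, NN}), the marker map
    (marker_id, chrom, pos, freq_b), and a truth dict with the autozygous
    segment and per-affected truth intervals.
    """
    rng = np.random.default_rng([int(spec.seed), 0x9E07])
    m = spec.marker_count
    pos = np.sort(
        rng.choice(
            np.arange(spec.map_start, spec.map_end + 1), size=m, replace=False
        )
    )
    q = np.broadcast_to(np.asarray(spec.allele_freq, dtype=float), (m,)).copy()
    marker_map = pd.DataFrame(
        {
            "marker_id": [f"rs{k:06d}" for k in range(m)],
            "chrom": spec.chrom,
            "pos": pos,
            "freq_b": q,
        }
    )
    seg = spec.autozygous_segment
    in_seg = (pos >= seg.start) & (pos <= seg.end)
    # founder haplotype across the segment: allele drawn at each marker
    founder = np.where(rng.random(m) < q, "B", "A")

    ids, roles = [], []
    for k in range(spec.n_affected):
        ids.append(f"AFF{k+1:02d}"); roles.append("affected")
    for k in range(spec.n_parents):
        ids.append(f"PAR{k+1:02d}"); roles.append("parent")
    for k in range(spec.n_controls):
        ids.append(f"CTL{k+1:02d}"); roles.append("control")

    def hw_calls() -> np.ndarray:
        a1 = rng.random(m) < q
        a2 = rng.random(m) < q
        g = np.full(m, "AB", dtype="<U2")
        g[a1 & a2] = "BB"
        g[~a1 & ~a2] = "AA"
        return g

    rows = {}
    for ind, role in zip(ids, roles):
        g = hw_calls()
        if role == "affected":
            g[in_seg] = np.where(founder[in_seg] == "B", "BB", "AA")
            if spec.error_rate > 0:
                err = in_seg & (rng.random(m) < spec.error_rate)
                g[err] = "AB"
        if spec.missing_rate > 0:
            g[rng.random(m) < spec.missing_rate] = "NN"
        rows[ind] = g

    genotypes = pd.DataFrame(rows, index=marker_map["marker_id"]).T
    genotypes.insert(0, "role", roles)
    truth = {
        "segment": seg,
        "founder_allele": founder,
        "segment_marker_ids": marker_map.loc[in_seg, "marker_id"].tolist(),
    }
    return genotypes, marker_map, truth


def write_genotypes_tsv(genotypes: pd.DataFrame, marker_map: pd.DataFrame,
                        geno_path, map_path) -> None:
    genotypes.to_csv(geno_path, sep="\t", index_label="individual_id")
    marker_map.to_csv(map_path, sep="\t", index=False)


def read_genotypes_tsv(geno_path, map_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    genotypes = pd.read_csv(geno_path, sep="\t", index_col="individual_id")
    marker_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    return genotypes, marker_map


# ====================================================================== #
# variant fixture (VCF)

AF_DB_KEYS = ("AF_DB1", "AF_DB2", "AF_DB3", "AF_DB4")


@dataclass
class VariantFixtureConfig:
    """Composition of the synthetic variant fixture.

    Defaults place exactly 18 rare intronic and 20 rare intergenic variants
    inside the run of homozygosity (one of the intronic ones being the focal
    near-acceptor variant), no rare coding or canonical-splice variants
    inside it, plus common variants inside and rare coding variants outside.
    """

    n_rare_intronic: int = 18
    n_rare_intergenic: int = 20
    n_common_inside: int = 30
    n_rare_coding_outside: int = 5
    n_common_outside: int = 40
    roh: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("21", 33_364_965, 34_029_433)
    )
    rare_af_max: float = 0.005
    common_af_min: float = 0.02
    include_focal_variant: bool = True


def demo_models(seed: int = 0) -> list[tuple[GeneModel, RegionSequence]]:
    """Both demonstration transcripts with their region sequences."""
    m1, r1, _ = demo_gene(seed)
    m2, r2 = demo_gene_plus(seed)
    return [(m1, r1), (m2, r2)]


def gen_variant_fixture(
    seed: int,
    config: VariantFixtureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a variant table with truth labels.

    Returns ``(variants, truth)``; ``variants`` has VCF-like columns plus
    one allele-frequency column per database, ``truth`` the intended
    category/rarity labels used by generator-recovery tests.  Positions are
    drawn over the two demonstration transcripts: rare noncoding variants
    inside the candidate interval around the focal gene, rare coding
    variants in the second gene outside it.
    """
    cfg = config or VariantFixtureConfig()
    gene, region, focal = demo_gene(seed=0)
    gene2, region2 = demo_gene_plus(seed=0)
    rng = np.random.default_rng([int(seed), 0x7AC])

    intronic_pool: list[int] = []
    for iv in gene.introns:
        # exclude the 2 canonical splice bases at each intron end
        intronic_pool.extend(range(iv.start + 2, iv.end - 1))
    intronic_pool = [p for p in intronic_pool if cfg.roh.contains(p)]

    gene_span = gene.span
    # keep a margin from the ROH edges so that a marker-resolution estimate
    # of the interval still contains every placed variant
    margin = min(50_000, (cfg.roh.end - cfg.roh.start) // 10)
    intergenic_pool = [
        int(p)
        for p in rng.choice(
            np.arange(cfg.roh.start + margin, cfg.roh.end - margin + 1),
            size=4000, replace=False,
        )
        if not (gene_span.start - 1000 <= p <= gene_span.end + 1000)
    ]
    # coding positions of the second (outside-interval) gene
    cds2_lo = min(gene2.cds_start, gene2.cds_end)
    cds2_hi = max(gene2.cds_start, gene2.cds_end)
    coding_pool_outside = [
        p for e in gene2.exons for p in range(e.start, e.end + 1)
        if cds2_lo <= p <= cds2_hi
    ]
    outside_pool = list(range(30_600_000, 30_700_000))

    if cfg.n_rare_intronic > len(intronic_pool):
        raise ValueError("requested more intronic variants than available positions")

    def rare_afs(rng) -> dict[str, float]:
        afs = {}
        for k in AF_DB_KEYS:
            if rng.random() < 0.5:
                afs[k] = round(float(rng.uniform(0, cfg.rare_af_max)), 6)
        return afs

    def common_afs(rng) -> dict[str, float]:
        afs = {k: round(float(rng.uniform(0, cfg.rare_af_max)), 6) for k in AF_DB_KEYS}
        hot = rng.choice(len(AF_DB_KEYS), size=rng.integers(1, 4), replace=False)
        for h in hot:
            afs[AF_DB_KEYS[h]] = round(float(rng.uniform(cfg.common_af_min, 0.4)), 6)
        return afs

    def draw_snv(pos: int) -> tuple[str, str]:
        if region.covers(pos):
            ref = region.base(pos)
        elif region2.covers(pos):
            ref = region2.base(pos)
        else:
            ref = str(rng.choice(list("ACGT")))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return ref, alt

    records = []

    def add(pos, afs, label):
        ref, alt = draw_snv(pos)
        records.append({"chrom": "21", "pos": int(pos), "ref": ref, "alt": alt,
                        "truth_label": label, **afs})

    n_intronic = cfg.n_rare_intronic
    chosen_intronic = list(
        rng.choice(intronic_pool, size=n_intronic, replace=False)
    )
    if cfg.include_focal_variant and n_intronic > 0:
        chosen_intronic[0] = focal["pos"]
        chosen_intronic = [focal["pos"]] + [
            p for p in chosen_intronic[1:] if p != focal["pos"]
        ]
        while len(chosen_intronic) < n_intronic:
            extra = int(rng.choice(intronic_pool))
            if extra not in chosen_intronic:
                chosen_intronic.append(extra)
    for i, p in enumerate(chosen_intronic):
        if cfg.include_focal_variant and i == 0:
            records.append({"chrom": "21", "pos": focal["pos"], "ref": focal["ref"],
                            "alt": focal["alt"], "truth_label": "rare_intronic",
                            **rare_afs(rng)})
        else:
            add(p, rare_afs(rng), "rare_intronic")
    for p in rng.choice(intergenic_pool[:2000], size=cfg.n_rare_intergenic, replace=False):
        add(p, rare_afs(rng), "rare_intergenic")
    for p in rng.choice(intergenic_pool[2000:], size=cfg.n_common_inside, replace=False):
        add(p, common_afs(rng), "common_inside")
    for p in rng.choice(coding_pool_outside, size=cfg.n_rare_coding_outside, replace=False):
        add(p, rare_afs(rng), "rare_coding_outside")
    for p in rng.choice(outside_pool, size=cfg.n_common_outside, replace=False):
        add(p, common_afs(rng), "common_outside")

    variants = pd.DataFrame.from_records(records)
    if len(variants):
        variants = variants.drop_duplicates(subset=["chrom", "pos"])
        variants = variants.sort_values("pos", kind="stable").reset_index(drop=True)
    truth = variants[["chrom", "pos", "truth_label"]].copy() if len(variants) else \
        pd.DataFrame(columns=["chrom", "pos", "truth_label"])
    if "truth_label" in variants.columns:
        variants = variants.drop(columns=["truth_label"])
    return variants, truth


def write_vcf(variants: pd.DataFrame, path) -> None:
    """Write the variant table as an uncompressed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=21,length=46709983>\n')
        for k in AF_DB_KEYS:
            fh.write(
                f'##INFO=<ID={k},Number=1,Type=Float,'
                f'Description="Allele frequency in database {k[-1]}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in variants.iterrows():
            info = ";".join(
                f"{k}={r[k]:.6f}"
                for k in AF_DB_KEYS
                if k in r and pd.notna(r[k])
            ) or "."
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t{info}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into the internal variant table (pysam-backed)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            }
            for k in AF_DB_KEYS:
                if k in rec.info:
                    v = rec.info[k]
                    row[k] = float(v[0] if isinstance(v, tuple) else v)
            rows.append(row)
    return pd.DataFrame.from_records(
        rows, columns=["chrom", "pos", "ref", "alt", *AF_DB_KEYS]
    )


# ====================================================================== #
# junction reads


@dataclass
class ReadSimConfig:
    """Configuration for the allele-aware junction-read simulator.

    ``retention`` maps genotype group -> per-allele retention probability of
    the focal intron, as ``(wt_allele_r, mut_allele_r)`` matching the
    group's allele pair in :data:`GROUP_ALLELES`.  Reads are emitted as
    junction-informative placements (boundary-spanning for retained
    molecules, exact exon–exon splices for spliced molecules); optional
    uninformative background reads can be added with
    ``uninformative_fraction``.
    """

    gene: GeneModel
    focal_intron: int = _FOCAL_INTRON
    retention: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "affected": (RETENTION_MUTANT_HOM, RETENTION_MUTANT_HOM),
            "parent": (RETENTION_WILDTYPE, RETENTION_MUTANT_HET),
            "control": (RETENTION_WILDTYPE, RETENTION_WILDTYPE),
        }
    )
    baseline_retention: float = 0.02
    variant_pos: int | None = None
    variant_ref: str = "T"
    variant_alt: str = "C"
    read_length: int = 100
    min_anchor: int = 6
    fragments_per_sample_per_intron: int = 400
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"affected": 7, "parent": 15, "control": 10}
    )
    introns: list[int] | None = None   # None = simulate every intron
    uninformative_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (rw, rm) in self.retention.items():
            if not (0 <= rw <= 1 and 0 <= rm <= 1):
                raise ValueError(f"retention probabilities for {g} must lie in [0,1]")
        if not (0 <= self.baseline_retention <= 1):
            raise ValueError("baseline retention must lie in [0,1]")
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read length must be at least twice the minimum anchor")
        if self.variant_pos is None:
            _, _, focal = demo_gene(seed=0)
            if self.gene.transcript_id == "DEMO-TX1":
                self.variant_pos = focal["pos"]


def _spanning_starts(intron: GenomicInterval, L: int, a: int) -> list[int]:
    """Leftmost-start positions of contiguous L-mers spanning either
    intron boundary with >= a aligned bases on both sides."""
    out = []
    # genomic-left boundary: between intron.start-1 (exon) and intron.start
    b = intron.start - 1
    out.extend(range(b - L + 1 + a, b - a + 2))  # s <= b-a+1 and s+L-1 >= b+a
    # genomic-right boundary: between intron.end and intron.end+1 (exon)
    b2 = intron.end
    out.extend(range(b2 - L + 1 + a, b2 - a + 2))
    return sorted(set(out))


def gen_junction_reads(cfg: ReadSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate allele-tagged junction reads over the gene model.

    Returns ``(reads, truth)``.  ``reads`` columns: read_id, chrom, pos,
    cigar (``<n>M`` or ``<a>M<ilen>N<b>M``), allele_base_at_variant ('.'
    when the read does not cover the variant position), sample_id, group,
    intron (the intron the fragment was simulated at).  ``truth`` maps each
    group to its per-allele and pooled focal-intron retention.
    """
    rng = np.random.default_rng([int(cfg.seed), 0x5EAD])
    gene = cfg.gene
    L = cfg.read_length
    a = cfg.min_anchor
    rows = []
    rid = 0
    for group, n_samples in cfg.samples_per_group.items():
        alleles = GROUP_ALLELES[group]
        rw, rm = cfg.retention[group]
        r_by_allele = {"wt": rw, "mut": rm}
        for s in range(n_samples):
            sample = f"{group[:3].upper()}{s+1:02d}"
            for intron_no, intron in enumerate(gene.introns, start=1):
                if cfg.introns is not None and intron_no not in cfg.introns:
                    continue
                focal = intron_no == cfg.focal_intron
                n_frag = cfg.fragments_per_sample_per_intron
                for _ in range(n_frag):
                    allele = alleles[int(rng.integers(0, 2))]
                    r = r_by_allele[allele] if focal else cfg.baseline_retention
                    retained = rng.random() < r
                    if cfg.uninformative_fraction and rng.random() < cfg.uninformative_fraction:
                        # background: contiguous read wholly inside the
                        # intron (retained) or wholly exonic (spliced)
                        if retained and intron.length_bp >= L + 2 * a:
                            s0 = int(rng.integers(intron.start + 1, intron.end - L))
                        else:
                            e = gene.exons[intron_no - 1]
                            s0 = int(rng.integers(e.start, max(e.start + 1, e.end - L)))
                        cigar = f"{L}M"
                        base = "."
                        rows.append((f"r{rid}", gene.chrom, s0, cigar, base,
                                     sample, group, intron_no))
                        rid += 1
                        continue
                    if retained:
                        starts = _spanning_starts(intron, L, a)
                        s0 = int(starts[rng.integers(0, len(starts))])
                        cigar = f"{L}M"
                        covers = s0 <= (cfg.variant_pos or -1) <= s0 + L - 1 and focal
                        base = (
                            (cfg.variant_alt if allele == "mut" else cfg.variant_ref)
                            if covers
                            else "."
                        )
                    else:
                        left = int(rng.integers(a, L - a + 1))
                        s0 = intron.start - left
                        cigar = f"{left}M{intron.length_bp}N{L - left}M"
                        base = "."
                    rows.append((f"r{rid}", gene.chrom, s0, cigar, base,
                                 sample, group, intron_no))
                    rid += 1
    reads = pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "pos", "cigar", "allele_base_at_variant",
                 "sample_id", "group", "intron"],
    )
    truth = {
        g: {
            "r_wt_allele": cfg.retention[g][0],
            "r_mut_allele": cfg.retention[g][1],
            "r_pooled": (cfg.retention[g][0] + cfg.retention[g][1]) / 2,
        }
        for g in cfg.samples_per_group
    }
    return reads, truth


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "allele_base_at_variant": str},
        keep_default_na=False, na_values=[],
    )


def write_reads_sam(reads: pd.DataFrame, path, chrom_len: int = 46_709_983) -> None:
    """Emit reads as a minimal single-end SAM file."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        chroms = sorted(reads["chrom"].unique())
        for c in chroms:
            fh.write(f"@SQ\tSN:{c}\tLN:{chrom_len}\n")
        for _, r in reads.iterrows():
            n_m = sum(
                int(x[:-1]) for x in _split_cigar(r["cigar"]) if x.endswith("M")
            )
            fh.write(
                f"{r['read_id']}\t0\t{r['chrom']}\t{int(r['pos'])}\t60\t{r['cigar']}"
                f"\t*\t0\t0\t{'N' * n_m}\t*\tRG:Z:{r['sample_id']}\n"
            )


def _split_cigar(cigar: str) -> list[str]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            out.append(num + ch)
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return out


# ====================================================================== #
# RT-PCR / qPCR


@dataclass
class SpliceQuantSimConfig:
    """Per-group truth for the fragment-area and Ct generators.

    ``fraction_unspliced`` maps group -> (mean, sd) of the true per-sample
    fraction of unspliced product; defaults follow the affected/parent/
    control study values 0.85/0.05, 0.38/0.13, 0.24/0.10.  ``relative_expression``
    maps group -> target expression relative to the reference group
    (default: heterozygous parents at 56% of wild-type).
    """

    fraction_unspliced: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "affected": (0.85, 0.05),
            "parent": (0.38, 0.13),
            "control": (0.24, 0.10),
        }
    )
    n_per_group: dict[str, int] | int = 20
    total_area_mean: float = 1000.0
    total_area_cv: float = 0.3
    relative_expression: dict[str, float] = field(
        default_factory=lambda: {"affected": 0.56, "parent": 0.56, "control": 1.0}
    )
    reference_group: str = "control"
    ct_reference_mean: float = 15.0
    ct_noise_sd: float = 0.15
    delta_ct_reference: float = 8.0
    seed: int = 3

    def __post_init__(self) -> None:
        if self.total_area_mean <= 0 or self.total_area_cv < 0:
            raise ValueError("area scale parameters must be positive")
        for g, rel in self.relative_expression.items():
            if rel <= 0:
                raise ValueError(f"relative expression for {g} must be > 0")


def gen_splice_quant(cfg: SpliceQuantSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate per-sample fragment areas and qPCR Ct values.

    Returns ``(records, truth)``; ``records`` columns: sample_id, group,
    area_unspliced, area_spliced, ct_target, ct_reference.
    """
    rng = np.random.default_rng([int(cfg.seed), 0xC7])
    rows = []
    for group, (mu, sd) in cfg.fraction_unspliced.items():
        n = cfg.n_per_group if isinstance(cfg.n_per_group, int) else cfg.n_per_group[group]
        frac = np.clip(rng.normal(mu, sd, size=n), 0.0, 1.0)
        if cfg.total_area_cv > 0:
            sigma = np.sqrt(np.log1p(cfg.total_area_cv**2))
            total = cfg.total_area_mean * rng.lognormal(-sigma**2 / 2, sigma, size=n)
        else:
            total = np.full(n, cfg.total_area_mean)
        dct = cfg.delta_ct_reference - np.log2(cfg.relative_expression[group])
        ct_ref = rng.normal(cfg.ct_reference_mean, cfg.ct_noise_sd, size=n)
        ct_tgt = ct_ref + dct + rng.normal(0, cfg.ct_noise_sd, size=n)
        for k in range(n):
            rows.append(
                {
                    "sample_id": f"{group[:3].upper()}{k+1:02d}",
                    "group": group,
                    "area_unspliced": round(float(frac[k] * total[k]), 4),
                    "area_spliced": round(float((1 - frac[k]) * total[k]), 4),
                    "ct_target": round(float(ct_tgt[k]), 4),
                    "ct_reference": round(float(ct_ref[k]), 4),
                }
            )
    records = pd.DataFrame.from_records(rows)
    truth = {
        "fraction_unspliced": dict(cfg.fraction_unspliced),
        "relative_expression": dict(cfg.relative_expression),
        "reference_group": cfg.reference_group,
    }
    return records, truth


def write_splice_quant_tsv(records: pd.DataFrame, area_path, ct_path) -> None:
    records[["sample_id", "group", "area_unspliced", "area_spliced"]].to_csv(
        area_path, sep="\t", index=False
    )
    records[["sample_id", "group", "ct_target", "ct_reference"]].to_csv(
        ct_path, sep="\t", index=False
    )
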