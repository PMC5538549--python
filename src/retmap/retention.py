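"""Intron-retention quantification from splice-junction evidence.

The estimator counts, per intron, reads that span an intron–exon boundary
(evidence of a retained intron in the mRNA) versus reads carrying the exact
exon–exon splice across that intron (evidence of splicing), pools counts
across the samples of each genotype group, and reports the retention
proportion R = spanning / (spanning + spliced) with a Wilson score 95%
interval.  Group differences use two-sided Fisher exact tests with Holm
step-down adjustment over the pairwise family; *cis* allelic association at
a heterozygous variant inside the intron uses an exact binomial test of the
mutant-base read fraction against 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .models import GeneModel


@dataclass
class JunctionCounts:
    intron: int
    spanning: int
    spliced: int
    scope: str  # sample id or group label

    def __post_init__(self) -> None:
        if self.spanning < 0 or self.spliced < 0:
            raise ValueError("counts must be non-negative")

    @property
    def informative(self) -> int:
        return self.spanning + self.spliced


@dataclass
class RetentionEstimate:
    proportion: float
    ci_low: float
    ci_high: float
    spanning: int
    spliced: int


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    table: list[list[int]]
    p_raw: float
    p_adjusted: float | None = None


@dataclass
class AllelicAssociation:
    mutant_reads: int
    reference_reads: int
    other_reads: int
    mutant_fraction: float
    p_value: float


@dataclass
class ExpressionEstimate:
    fragments: int
    exonic_length_bp: int
    total_mapped: int
    fpkm: float


# ---------------------------------------------------------------------- #
# read classification


def parse_cigar_blocks(pos: int, cigar: str) -> list[tuple[int, int]]:
    """Aligned genomic blocks (1-based inclusive) of a simplified CIGAR.

    Supports M (aligned) and N (splice gap) operations.
    """
    blocks: list[tuple[int, int]] = []
    cur = pos
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        if not num or ch not in "MN":
            raise ValueError(f"malformed gap specification {cigar!r}")
        n = int(num)
        num = ""
        if n <= 0:
            raise ValueError(f"malformed gap specification {cigar!r}")
        if ch == "M":
            blocks.append((cur, cur + n - 1))
        cur += n
    if num or not blocks:
        raise ValueError(f"malformed gap specification {cigar!r}")
    # merge abutting M blocks (a zero-length gap is not a splice)
    merged = [blocks[0]]
    for b in blocks[1:]:
        if b[0] == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    return merged


def classify_read(
    pos: int,
    cigar: str,
    model: GeneModel,
    intron: int,
    min_anchor: int = 6,
) -> str:
    """Classify one alignment for one intron: spanning / spliced / uninformative.

    *spanning*: the alignment covers >= ``min_anchor`` contiguous aligned
    bases on both sides of the intron's donor or acceptor boundary with no
    splice gap at that boundary.  *spliced*: the alignment contains a gap
    whose genomic coordinates exactly equal the intron, with >= ``min_anchor``
    aligned bases on both flanking exons.  Everything else — including reads
    wholly inside the intron — is uninformative.
    """
    model._check_intron(intron)
    blocks = parse_cigar_blocks(pos, cigar)
    return _classify_blocks(blocks, model.introns[intron - 1], min_anchor)


def _classify_blocks(blocks, iv, min_anchor: int) -> str:
    # spliced: a gap exactly matching the intron, anchored on both exons
    for (a_start, a_end), (b_start, b_end) in zip(blocks, blocks[1:]):
        if a_end == iv.start - 1 and b_start == iv.end + 1:
            if (a_end - a_start + 1) >= min_anchor and (b_end - b_start + 1) >= min_anchor:
                return "spliced"
    # spanning: contiguous coverage across either genomic boundary
    for b_start, b_end in blocks:
        left_ok = b_start <= iv.start - min_anchor and b_end >= iv.start + min_anchor - 1
        right_ok = b_start <= iv.end - min_anchor + 1 and b_end >= iv.end + min_anchor
        if left_ok or right_ok:
            return "spanning"
    return "uninformative"


def count_junctions(
    reads: pd.DataFrame,
    model: GeneModel,
    groups: dict[str, str] | None = None,
    min_anchor: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count junction-informative reads per intron x sample and pooled per group.

    ``reads`` needs columns read_id, chrom, pos, cigar, sample_id and either
    a ``group`` column or a ``groups`` mapping sample_id -> group.  Each read
    is counted at most once per intron (a read spanning both boundaries of a
    short retained intron counts one spanning observation).

    Returns ``(per_sample, per_group)`` DataFrames with columns
    (intron, sample_id|group, spanning, spliced).
    """
    if groups is None:
        if "group" not in reads.columns:
            raise ValueError("need a 'group' column or a sample->group mapping")
        groups = dict(zip(reads["sample_id"], reads["group"]))
    unlabelled = set(reads["sample_id"]) - set(groups)
    if unlabelled:
        raise ValueError(f"samples with no group label: {sorted(unlabelled)}")

    counts: dict[tuple[int, str], list[int]] = {}
    sub = reads[reads["chrom"].astype(str) == model.chrom]
    introns = list(enumerate(model.introns, start=1))
    for pos, cigar, sample in zip(sub["pos"], sub["cigar"], sub["sample_id"]):
        blocks = parse_cigar_blocks(int(pos), cigar)
        for intron_no, iv in introns:
            cls = _classify_blocks(blocks, iv, min_anchor)
            if cls == "uninformative":
                continue
            c = counts.setdefault((intron_no, sample), [0, 0])
            c[0 if cls == "spanning" else 1] += 1

    rows = [
        {"intron": i, "sample_id": s, "spanning": c[0], "spliced": c[1]}
        for (i, s), c in sorted(counts.items())
    ]
    per_sample = pd.DataFrame(rows, columns=["intron", "sample_id", "spanning", "spliced"])
    if len(per_sample):
        per_sample["group"] = per_sample["sample_id"].map(groups)
        per_group = (
            per_sample.groupby(["intron", "group"], as_index=False)[["spanning", "spliced"]]
            .sum()
        )
    else:
        per_group = pd.DataFrame(columns=["intron", "group", "spanning", "spliced"])
    return per_sample, per_group


# ---------------------------------------------------------------------- #
# estimation and testing


def retention_estimate(
    counts: JunctionCounts, ci_method: str = "wilson"
) -> RetentionEstimate:
    """Retention proportion with a 95% CI (Wilson score by default;
    ``ci_method='beta'`` gives Clopper–Pearson)."""
    n = counts.informative
    if n == 0:
        raise ValueError("no informative reads: retention undefined")
    r = counts.spanning / n
    lo, hi = proportion_confint(counts.spanning, n, alpha=0.05, method=ci_method)
    return RetentionEstimate(r, float(lo), float(hi), counts.spanning, counts.spliced)


def retention_table(per_group: pd.DataFrame, ci_method: str = "wilson") -> pd.DataFrame:
    """Per-intron x per-group retention estimates from pooled counts."""
    rows = []
    for _, r in per_group.iterrows():
        est = retention_estimate(
            JunctionCounts(int(r["intron"]), int(r["spanning"]), int(r["spliced"]),
                           str(r["group"])),
            ci_method,
        )
        rows.append(
            {
                "intron": int(r["intron"]),
                "group": str(r["group"]),
                "spanning": est.spanning,
                "spliced": est.spliced,
                "retention": est.proportion,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["intron", "group", "spanning", "spliced", "retention",
                       "ci_low", "ci_high"]
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (family-wise error control)."""
    if not p_values:
        return []
    adj = multipletests(p_values, method="holm")[1]
    return [float(x) for x in adj]


def compare_groups(counts_by_group: dict[str, JunctionCounts]) -> list[GroupComparison]:
    """All pairwise two-sided Fisher exact tests with Holm adjustment."""
    for g, c in counts_by_group.items():
        if c.informative == 0:
            raise ValueError(f"group {g!r} has no informative reads")
    pairs = list(combinations(sorted(counts_by_group), 2))
    out = []
    for a, b in pairs:
        ca, cb = counts_by_group[a], counts_by_group[b]
        table = [[ca.spanning, ca.spliced], [cb.spanning, cb.spliced]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        out.append(GroupComparison(a, b, table, p))
    adj = holm_adjust([c.p_raw for c in out])
    for c, a in zip(out, adj):
        c.p_adjusted = a
    return out


def allelic_association(
    reads: pd.DataFrame, mutant_base: str, reference_base: str,
    base_column: str = "allele_base_at_variant",
) -> AllelicAssociation:
    """Exact binomial test of the mutant-base fraction against 0.5.

    ``reads`` must carry the observed base at the variant position; reads
    not covering the position ('.' or missing) are ignored, and covering
    reads showing neither allele are excluded but reported.
    """
    bases = reads[base_column].astype(str)
    covering = bases[~bases.isin({".", "", "nan"})]
    n_mut = int((covering == mutant_base).sum())
    n_ref = int((covering == reference_base).sum())
    n_other = int(len(covering) - n_mut - n_ref)
    if n_mut + n_ref == 0:
        raise ValueError("no reads covering the variant position")
    p = float(stats.binomtest(n_mut, n_mut + n_ref, 0.5, alternative="two-sided").pvalue)
    return AllelicAssociation(
        mutant_reads=n_mut,
        reference_reads=n_ref,
        other_reads=n_other,
        mutant_fraction=n_mut / (n_mut + n_ref),
        p_value=p,
    )


def fpkm(fragments: int, exonic_length_bp: int, total_mapped: int) -> ExpressionEstimate:
    """Fragments per kilobase of exonic length per million mapped fragments."""
    if exonic_length_bp <= 0 or total_mapped <= 0:
        raise ValueError("exonic length and total mapped fragments must be positive")
    if fragments < 0:
        raise ValueError("fragment count must be non-negative")
    value = fragments / ((exonic_length_bp / 1000.0) * (total_mapped / 1e6))
    return ExpressionEstimate(fragments, exonic_length_bp, total_mapped, value)
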