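"""Runs of homozygosity, minimal shared intervals and homozygosity LOD.

Autozygosity mapping for a recessive trait: each affected individual of a
consanguineous pedigree is expected to be homozygous by descent across a
segment surrounding the disease locus.  This module detects per-individual
runs of homozygosity (ROH) from array-style genotype calls, intersects the
runs of all affecteds into a minimal candidate interval with a
haplotype-consistency check, and scores markers with a simplified
singlepoint homozygosity LOD (a Lander–Botstein-style statistic, not a
multipoint pedigree likelihood — recombination is not modelled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import GenomicInterval, interval_length_kb

HOM_CALLS = {"AA", "BB"}
MISSING = "NN"


@dataclass
class ROHSegment:
    """One maximal run of homozygous calls for one individual."""

    individual: str
    interval: GenomicInterval
    n_markers: int
    marker_ids: list[str]
    alleles: dict[str, str]  # marker_id -> homozygous allele ('A' or 'B')


@dataclass
class LodResult:
    marker_id: str
    lod: float
    contributions: dict[str, float]


def detect_roh(
    calls: pd.Series,
    marker_map: pd.DataFrame,
    min_markers: int = 25,
    min_length_kb: int = 500,
    max_missing_run: int = 2,
    max_het: int = 0,
    individual: str = "",
) -> list[ROHSegment]:
    """Detect maximal qualifying runs of homozygosity for one individual.

    ``calls`` is indexed by marker_id with values in {AA, AB, BB, NN};
    ``marker_map`` supplies chrom/pos per marker and must be sorted by
    position within each chromosome.  Heterozygous calls break a run
    (``max_het`` > 0 relaxes this); up to ``max_missing_run`` *consecutive*
    missing calls are skipped without breaking the run, but missing markers
    never count toward ``min_markers``.  Runs shorter than ``min_markers``
    supporting markers or ``min_length_kb`` are dropped.
    """
    out: list[ROHSegment] = []
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"marker map not sorted by position on {chrom}")
        ids = sub["marker_id"].tolist()
        g = [calls.get(mid, MISSING) for mid in ids]

        run_markers: list[int] = []   # indices of hom markers in current run
        het_used = 0
        missing_streak = 0

        def flush() -> None:
            nonlocal run_markers, het_used
            if run_markers:
                seg = _make_segment(individual, chrom, run_markers, ids, pos, g)
                if (
                    seg.n_markers >= min_markers
                    and interval_length_kb(seg.interval) >= min_length_kb
                ):
                    out.append(seg)
            run_markers = []
            het_used = 0

        for k, call in enumerate(g):
            if call in HOM_CALLS:
                run_markers.append(k)
                missing_streak = 0
            elif call == MISSING:
                missing_streak += 1
                if run_markers and missing_streak > max_missing_run:
                    flush()
                    missing_streak = 0
            else:  # heterozygous
                if run_markers and het_used < max_het:
                    het_used += 1
                else:
                    flush()
                missing_streak = 0
        flush()
    return out


def _make_segment(individual, chrom, run_markers, ids, pos, g) -> ROHSegment:
    first, last = run_markers[0], run_markers[-1]
    marker_ids = [ids[k] for k in run_markers]
    alleles = {ids[k]: g[k][0] for k in run_markers}
    return ROHSegment(
        individual=individual,
        interval=GenomicInterval(chrom, int(pos[first]), int(pos[last])),
        n_markers=len(run_markers),
        marker_ids=marker_ids,
        alleles=alleles,
    )


def detect_roh_all(genotypes: pd.DataFrame, marker_map: pd.DataFrame,
                   **kwargs) -> dict[str, list[ROHSegment]]:
    """Run :func:`detect_roh` for every individual in a genotype table."""
    calls = genotypes.drop(columns=["role"], errors="ignore")
    return {
        ind: detect_roh(calls.loc[ind], marker_map, individual=ind, **kwargs)
        for ind in calls.index
    }


@dataclass
class CandidateInterval:
    interval: GenomicInterval
    per_individual: dict[str, GenomicInterval]
    inconsistent_markers: list[str]


def minimal_overlap_roh(
    segments_by_affected: dict[str, list[ROHSegment]],
    anchor: GenomicInterval,
) -> CandidateInterval:
    """Intersect anchor-overlapping ROH segments across affecteds.

    Every affected must contribute at least one segment overlapping the
    anchor (e.g. the linkage peak); otherwise a ``ValueError`` names the
    individuals lacking one.  Markers at which two affecteds are homozygous
    for *different* alleles are flagged as haplotype-inconsistent.
    """
    chosen: dict[str, ROHSegment] = {}
    missing = []
    for ind, segs in segments_by_affected.items():
        overlapping = [s for s in segs if s.interval.overlaps(anchor)]
        if not overlapping:
            missing.append(ind)
            continue
        # largest anchor overlap wins
        chosen[ind] = max(
            overlapping,
            key=lambda s: s.interval.intersect(anchor).length_bp,
        )
    if missing:
        raise ValueError(
            "no ROH overlapping the anchor for: " + ", ".join(sorted(missing))
        )
    inter: GenomicInterval | None = None
    for seg in chosen.values():
        inter = seg.interval if inter is None else inter.intersect(seg.interval)
        if inter is None:
            raise ValueError("anchor-overlapping segments have empty intersection")
    allele_sets: dict[str, set[str]] = {}
    for seg in chosen.values():
        for mid, allele in seg.alleles.items():
            allele_sets.setdefault(mid, set()).add(allele)
    inconsistent = sorted(m for m, s in allele_sets.items() if len(s) > 1)
    return CandidateInterval(
        interval=inter,
        per_individual={i: s.interval for i, s in chosen.items()},
        inconsistent_markers=inconsistent,
    )


def lod_contribution(call: str, q_b: float, eps: float) -> float:
    """Singlepoint homozygosity LOD contribution of one affected's call.

    Under autozygosity the individual is homozygous for an allele drawn at
    the population frequency, up to a genotyping-error rate ``eps`` that
    produces an apparent heterozygote; under random mating genotypes follow
    Hardy–Weinberg.  log10 of the likelihood ratio:

        hom for allele a:  ((1 - eps) * q_a) / q_a**2
        het:               eps / (2 * q_a * q_b)

    Missing calls contribute 0.
    """
    if not (0 < q_b < 1):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if not (0 < eps < 0.5):
        raise ValueError("error rate must lie strictly in (0, 0.5)")
    q_a = 1.0 - q_b
    if call == "AA":
        return math.log10(((1 - eps) * q_a) / (q_a * q_a))
    if call == "BB":
        return math.log10(((1 - eps) * q_b) / (q_b * q_b))
    if call == MISSING:
        return 0.0
    return math.log10(eps / (2 * q_a * q_b))


def homozygosity_lod(
    calls_by_individual: dict[str, str], q_b: float, eps: float,
    marker_id: str = "",
) -> LodResult:
    """Sum LOD contributions over affecteds at one marker."""
    contrib = {
        ind: lod_contribution(c, q_b, eps) for ind, c in calls_by_individual.items()
    }
    return LodResult(marker_id=marker_id, lod=sum(contrib.values()),
                     contributions=contrib)


def lod_profile(
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    eps: float = 0.01,
    window: int = 1,
    affected_role: str = "affected",
) -> pd.DataFrame:
    """Per-marker homozygosity LOD across affecteds, optionally smoothed.

    ``window`` > 1 returns a centred rolling sum over that many markers —
    autozygosity is a *run* phenomenon, and summing adjacent singlepoint
    scores discriminates a sustained shared segment from isolated
    chance homozygosity.  Returns a DataFrame (marker_id, chrom, pos, lod).
    """
    if "role" in genotypes.columns:
        aff = genotypes[genotypes["role"] == affected_role].drop(columns=["role"])
    else:
        aff = genotypes
    lods = []
    for _, mk in marker_map.iterrows():
        mid = mk["marker_id"]
        calls = {ind: aff.at[ind, mid] for ind in aff.index}
        lods.append(homozygosity_lod(calls, float(mk["freq_b"]), eps, mid).lod)
    prof = marker_map[["marker_id", "chrom", "pos"]].copy()
    lod = pd.Series(lods, index=prof.index, dtype=float)
    if window > 1:
        lod = lod.rolling(window, center=True, min_periods=1).sum()
    prof["lod"] = lod
    return prof
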