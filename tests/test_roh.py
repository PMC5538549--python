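"""ROH detection, minimal overlap and homozygosity LOD."""

import math

import numpy as np
import pandas as pd
import pytest

from retmap.models import GenomicInterval
from retmap.roh import (
    HOM_CALLS,
    LodResult,
    ROHSegment,
    detect_roh,
    detect_roh_all,
    homozygosity_lod,
    lod_contribution,
    lod_profile,
    minimal_overlap_roh,
)
from retmap.simulate import CohortSpec, gen_genotypes


def _marker_map(positions, chrom="c"):
    return pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(len(positions))],
         "chrom": chrom, "pos": positions, "freq_b": 0.5}
    )


def _series(calls):
    return pd.Series(list(calls), index=[f"m{i}" for i in range(len(calls))])


def brute_force_runs(calls, positions, min_markers, min_length_kb, max_missing_run):
    """Independent O(n^2) enumeration of maximal qualifying homozygous runs.

    A run is a set of homozygous-call markers i..j (by index over hom
    markers) such that no heterozygous call and no stretch of more than
    max_missing_run consecutive missing calls separates them, and it cannot
    be extended on either side.
    """
    n = len(calls)
    hom = [k for k in range(n) if calls[k] in HOM_CALLS]

    def connected(a, b):
        """hom markers a<b (indices into calls) can belong to one run"""
        streak = 0
        for k in range(a + 1, b):
            if calls[k] == "NN":
                streak += 1
                if streak > max_missing_run:
                    return False
            elif calls[k] in HOM_CALLS:
                streak = 0
            else:
                return False
        return True

    runs = []
    for ai, a in enumerate(hom):
        for bi in range(ai, len(hom)):
            b = hom[bi]
            members = [h for h in hom if a <= h <= b]
            if not all(connected(members[i], members[i + 1])
                       for i in range(len(members) - 1)):
                continue
            # maximality
            if ai > 0 and connected(hom[ai - 1], a):
                continue
            if bi < len(hom) - 1 and connected(b, hom[bi + 1]):
                continue
            if len(members) < min_markers:
                continue
            length_kb = int(math.floor((positions[b] - positions[a]) / 1000 + 0.5))
            if length_kb < min_length_kb:
                continue
            runs.append((positions[a], positions[b], len(members)))
    return sorted(set(runs))


class TestDetectRoh:
    def test_spec_thresholds_on_five_marker_example(self):
        calls = _series(["AA", "AA", "AA", "BB", "BB"])
        mmap = _marker_map([10_000, 20_000, 30_000, 40_000, 50_000])
        # one run over all 5 markers (AA->BB switch does not break a run of
        # homozygosity), 40 kb long
        segs = detect_roh(calls, mmap, min_markers=3, min_length_kb=20,
                          max_missing_run=0)
        assert len(segs) == 1
        assert segs[0].n_markers == 5
        assert (segs[0].interval.start, segs[0].interval.end) == (10_000, 50_000)
        # too strict a length threshold drops it
        assert detect_roh(calls, mmap, min_markers=3, min_length_kb=100) == []

    def test_all_heterozygous_gives_empty_list(self):
        calls = _series(["AB"] * 10)
        mmap = _marker_map(list(range(0, 100_000, 10_000)))
        assert detect_roh(calls, mmap, min_markers=1, min_length_kb=0) == []

    def test_het_breaks_run_missing_does_not(self):
        calls = _series(["AA", "NN", "AA", "AB", "BB", "BB"])
        mmap = _marker_map([1_000, 11_000, 21_000, 31_000, 41_000, 51_000])
        segs = detect_roh(calls, mmap, min_markers=2, min_length_kb=0,
                          max_missing_run=1)
        assert [(s.interval.start, s.interval.end, s.n_markers) for s in segs] == [
            (1_000, 21_000, 2), (41_000, 51_000, 2)
        ]

    def test_long_missing_stretch_breaks_run(self):
        calls = _series(["AA", "NN", "NN", "NN", "AA"])
        mmap = _marker_map([1_000, 11_000, 21_000, 31_000, 41_000])
        segs = detect_roh(calls, mmap, min_markers=1, min_length_kb=0,
                          max_missing_run=2)
        assert len(segs) == 2

    def test_unsorted_markers_rejected(self):
        calls = _series(["AA", "AA"])
        mmap = _marker_map([100, 50])
        with pytest.raises(ValueError, match="sorted"):
            detect_roh(calls, mmap)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        calls = list(rng.choice(["AA", "BB", "AB", "NN"], size=n,
                                p=[0.35, 0.35, 0.2, 0.1]))
        positions = np.sort(rng.choice(np.arange(1, 2_000_000), size=n,
                                       replace=False))
        mmap = _marker_map(list(positions))
        min_markers, min_kb, max_miss = 3, 50, 1
        segs = detect_roh(_series(calls), mmap, min_markers=min_markers,
                          min_length_kb=min_kb, max_missing_run=max_miss)
        got = sorted((s.interval.start, s.interval.end, s.n_markers) for s in segs)
        expected = brute_force_runs(calls, positions, min_markers, min_kb, max_miss)
        assert got == expected

    def test_recovers_truth_segments_exactly_without_error(self):
        spec = CohortSpec(n_affected=3, n_parents=0, n_controls=0,
                          marker_count=500, error_rate=0.0, missing_rate=0.0,
                          seed=21)
        geno, mmap, truth = gen_genotypes(spec)
        seg = truth["segment"]
        segs = detect_roh_all(geno, mmap, min_markers=10, min_length_kb=100)
        for ind, slist in segs.items():
            covering = [s for s in slist if s.interval.overlaps(seg)]
            assert len(covering) == 1
            # detected run contains every truth-segment marker
            assert set(truth["segment_marker_ids"]) <= set(covering[0].marker_ids)


class TestMinimalOverlap:
    def _seg(self, ind, start, end, alleles=None):
        n = 30
        return ROHSegment(ind, GenomicInterval("c", start, end), n,
                          [f"m{k}" for k in range(n)], alleles or {})

    def test_two_segment_intersection(self):
        anchor = GenomicInterval("c", 200, 1000)
        cand = minimal_overlap_roh(
            {"a": [self._seg("a", 100, 900)], "b": [self._seg("b", 300, 1200)]},
            anchor,
        )
        assert (cand.interval.start, cand.interval.end) == (300, 900)

    def test_three_identical_segments_no_inconsistency(self):
        anchor = GenomicInterval("c", 100, 900)
        alleles = {"m1": "A", "m2": "B"}
        cand = minimal_overlap_roh(
            {i: [self._seg(i, 100, 900, dict(alleles))] for i in "abc"}, anchor
        )
        assert (cand.interval.start, cand.interval.end) == (100, 900)
        assert cand.inconsistent_markers == []

    def test_discordant_alleles_flagged(self):
        anchor = GenomicInterval("c", 100, 900)
        cand = minimal_overlap_roh(
            {
                "a": [self._seg("a", 100, 900, {"m1": "A"})],
                "b": [self._seg("b", 100, 900, {"m1": "B"})],
            },
            anchor,
        )
        assert cand.inconsistent_markers == ["m1"]

    def test_missing_individual_reported_by_name(self):
        anchor = GenomicInterval("c", 5000, 6000)
        with pytest.raises(ValueError, match="ind_b"):
            minimal_overlap_roh(
                {"ind_a": [self._seg("ind_a", 4000, 7000)],
                 "ind_b": [self._seg("ind_b", 100, 900)]},
                anchor,
            )

    def test_order_independent_and_idempotent(self):
        anchor = GenomicInterval("c", 200, 1000)
        segs = {"a": [self._seg("a", 100, 900)], "b": [self._seg("b", 300, 1200)],
                "c": [self._seg("c", 250, 950)]}
        c1 = minimal_overlap_roh(segs, anchor)
        c2 = minimal_overlap_roh(dict(reversed(list(segs.items()))), anchor)
        assert (c1.interval.start, c1.interval.end) == (c2.interval.start,
                                                        c2.interval.end)
        # feeding the result interval back as each individual's segment
        again = minimal_overlap_roh(
            {i: [ROHSegment(i, c1.interval, 30, [], {})] for i in "abc"}, anchor
        )
        assert (again.interval.start, again.interval.end) == (
            c1.interval.start, c1.interval.end)

    def test_truth_segment_contained_in_recovered_interval(self):
        spec = CohortSpec(n_affected=5, n_parents=0, n_controls=0,
                          marker_count=800, error_rate=0.0, missing_rate=0.0,
                          seed=33)
        geno, mmap, truth = gen_genotypes(spec)
        segs = detect_roh_all(geno, mmap, min_markers=10, min_length_kb=100)
        anchor = truth["segment"]
        cand = minimal_overlap_roh(segs, anchor)
        # the recovered interval is contained in every individual's segment
        for iv in cand.per_individual.values():
            assert iv.start <= cand.interval.start <= cand.interval.end <= iv.end
        # and the disease locus (segment centre) lies inside it
        centre = (anchor.start + anchor.end) // 2
        assert cand.interval.contains(centre)


class TestHomozygosityLod:
    def test_hand_evaluated_homozygote_contribution(self):
        # P(hom_a | autozygous) / P(hom_a | random) = 0.99*0.1 / 0.01
        got = lod_contribution("AA", q_b=0.9, eps=0.01)  # q_a = 0.1
        assert got == pytest.approx(math.log10(0.99 * 0.1 / 0.01), abs=1e-12)
        assert got == pytest.approx(0.9956, abs=2e-4)

    def test_het_contribution_negative_for_common_alleles(self):
        got = lod_contribution("AB", q_b=0.5, eps=0.01)
        assert got == pytest.approx(math.log10(0.01 / (2 * 0.25)), abs=1e-12)
        assert got < 0

    def test_seven_homozygotes_approach_seven_log10_two(self):
        eps = 1e-6
        calls = {f"i{k}": "AA" for k in range(7)}
        res = homozygosity_lod(calls, q_b=0.5, eps=eps)
        assert res.lod == pytest.approx(7 * math.log10(2), abs=1e-4)

    def test_additive_over_individuals(self):
        calls = {"a": "AA", "b": "BB", "c": "AB", "d": "NN"}
        res = homozygosity_lod(calls, q_b=0.3, eps=0.02)
        assert res.lod == pytest.approx(sum(res.contributions.values()), abs=1e-12)
        for sub in ("a", "b", "c"):
            solo = homozygosity_lod({sub: calls[sub]}, q_b=0.3, eps=0.02)
            assert solo.lod == pytest.approx(res.contributions[sub], abs=1e-12)

    def test_strictly_decreasing_in_allele_frequency_for_homozygotes(self):
        lods = [homozygosity_lod({f"i{k}": "BB" for k in range(5)}, q, 0.01).lod
                for q in (0.1, 0.2, 0.4, 0.6, 0.8)]
        assert all(a > b for a, b in zip(lods, lods[1:]))

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            lod_contribution("AA", q_b=0.0, eps=0.01)
        with pytest.raises(ValueError):
            lod_contribution("AA", q_b=1.0, eps=0.01)

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_windowed_lod_peak_falls_in_truth_segment(self, seed):
        """A run of shared homozygosity produces the genome-wide maximum of
        the windowed LOD profile inside the truth segment."""
        spec = CohortSpec(n_affected=7, n_parents=0, n_controls=0,
                          marker_count=600, error_rate=0.01, missing_rate=0.01,
                          seed=seed)
        geno, mmap, truth = gen_genotypes(spec)
        prof = lod_profile(geno, mmap, eps=0.01, window=11)
        peak = prof.loc[prof["lod"].idxmax()]
        assert truth["segment"].contains(int(peak["pos"]))
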