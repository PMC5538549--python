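"""Junction-read classification, retention estimation, exact tests, FPKM."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from retmap.models import GenomicInterval
from retmap.retention import (
    JunctionCounts,
    allelic_association,
    classify_read,
    compare_groups,
    count_junctions,
    fpkm,
    holm_adjust,
    parse_cigar_blocks,
    retention_estimate,
    retention_table,
)
from retmap.simulate import ReadSimConfig, gen_junction_reads


# ---------------------------------------------------------------------- #
# independent oracles


def fisher_two_sided_oracle(table):
    """Two-sided Fisher exact p by full enumeration of 2x2 tables with the
    observed margins, summing hypergeometric probabilities <= P(observed)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def binomial_two_sided_oracle(k, n):
    """Two-sided exact binomial p vs 0.5 by full pmf enumeration.

    The pmf is evaluated in log space (log-gamma), which is exact to
    floating precision for all n used here.
    """
    from scipy.special import gammaln

    x = np.arange(n + 1)
    logpmf = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1) - n * np.log(2)
    pmf = np.exp(logpmf)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()))


def holm_oracle(ps):
    """Step-down definition with monotonicity enforcement."""
    order = sorted(range(len(ps)), key=lambda i: ps[i])
    m = len(ps)
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * ps[i]))
        adj[i] = running
    return adj


# ---------------------------------------------------------------------- #


class TestClassifyRead:
    def test_exact_splice_across_focal_intron(self, demo):
        model, _, _ = demo
        iv = model.introns[5]
        pos = iv.start - 47
        cigar = f"47M{iv.length_bp}N53M"
        assert classify_read(pos, cigar, model, 6) == "spliced"

    def test_contiguous_read_across_acceptor_is_spanning(self, demo):
        model, _, _ = demo
        iv = model.introns[5]
        # 60 intronic + 40 exonic bases over the genomic-left boundary
        pos = iv.start - 40
        assert classify_read(pos, "100M", model, 6) == "spanning"

    def test_short_overhang_is_uninformative(self, demo):
        model, _, _ = demo
        iv = model.introns[5]
        # read ends 3 bp past the boundary: anchor < 6 on the intron side
        pos = iv.start + 3 - 100
        assert classify_read(pos, "100M", model, 6, min_anchor=6) == "uninformative"

    def test_read_wholly_inside_intron_is_uninformative(self, demo):
        model, _, _ = demo
        iv = model.introns[0]  # 500 bp
        assert classify_read(iv.start + 10, "100M", model, 1) == "uninformative"

    def test_gap_not_matching_intron_is_not_spliced(self, demo):
        model, _, _ = demo
        iv = model.introns[5]
        cigar = f"47M{iv.length_bp - 1}N53M"
        assert classify_read(iv.start - 47, cigar, model, 6) != "spliced"

    def test_malformed_gap_spec_rejected(self, demo):
        model, _, _ = demo
        for bad in ("M100", "100", "50M10X40M", ""):
            with pytest.raises(ValueError):
                parse_cigar_blocks(100, bad)

    def test_read_spanning_both_boundaries_counts_once(self, demo):
        model, _, _ = demo
        iv = model.introns[5]  # 109 bp < 150-bp read
        reads = pd.DataFrame(
            [{"read_id": "r0", "chrom": "21", "pos": iv.start - 20,
              "cigar": "150M", "sample_id": "s1", "group": "g"}]
        )
        _, per_group = count_junctions(reads, model)
        focal = per_group[per_group["intron"] == 6]
        assert focal["spanning"].sum() == 1

    def test_empty_read_set_gives_empty_table(self, demo):
        model, _, _ = demo
        reads = pd.DataFrame(columns=["read_id", "chrom", "pos", "cigar",
                                      "sample_id", "group"])
        per_sample, per_group = count_junctions(reads, model)
        assert len(per_sample) == 0 and len(per_group) == 0

    def test_unlabelled_sample_rejected(self, demo):
        model, _, _ = demo
        reads = pd.DataFrame(
            [{"read_id": "r0", "chrom": "21", "pos": 1, "cigar": "100M",
              "sample_id": "s1"}]
        )
        with pytest.raises(ValueError, match="group"):
            count_junctions(reads, model, groups={"other": "g"})


class TestRetentionEstimate:
    def test_pooled_proportion(self):
        est = retention_estimate(JunctionCounts(6, 66, 34, "affected"))
        assert est.proportion == pytest.approx(0.66)
        assert est.ci_low <= est.proportion <= est.ci_high

    def test_zero_spanning(self):
        est = retention_estimate(JunctionCounts(1, 0, 50, "s"))
        assert est.proportion == 0.0
        assert est.ci_low == 0.0

    def test_wilson_interval_hand_computed(self):
        """Wilson score CI for 7/100 at z=1.96, evaluated from the formula."""
        est = retention_estimate(JunctionCounts(1, 7, 93, "s"))
        z = 1.959963984540054
        p, n = 0.07, 100
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        assert est.ci_low == pytest.approx(centre - half, abs=1e-9)
        assert est.ci_high == pytest.approx(centre + half, abs=1e-9)
        assert est.ci_low == pytest.approx(0.034, abs=5e-3)
        assert est.ci_high == pytest.approx(0.138, abs=5e-3)

    def test_zero_informative_reads_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            retention_estimate(JunctionCounts(1, 0, 0, "s"))


class TestCompareGroups:
    def test_balanced_table_p_one(self):
        cmp = compare_groups({
            "a": JunctionCounts(6, 5, 5, "a"), "b": JunctionCounts(6, 5, 5, "b")
        })
        assert cmp[0].p_raw == pytest.approx(1.0)

    def test_fisher_p_matches_enumeration_oracle(self):
        table = [[8, 2], [1, 9]]
        cmp = compare_groups({
            "a": JunctionCounts(6, 8, 2, "a"), "b": JunctionCounts(6, 1, 9, "b")
        })
        assert cmp[0].p_raw == pytest.approx(fisher_two_sided_oracle(table),
                                             rel=1e-9)
        assert cmp[0].p_raw == pytest.approx(0.005477, abs=5e-7)

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 31, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            cmp = compare_groups({
                "x": JunctionCounts(1, int(a), int(b), "x"),
                "y": JunctionCounts(1, int(c), int(d), "y"),
            })
            oracle = fisher_two_sided_oracle([[a, b], [c, d]])
            assert cmp[0].p_raw == pytest.approx(oracle, rel=1e-8, abs=1e-12)

    def test_holm_stepdown_example(self):
        assert holm_adjust([0.01, 0.03, 0.04]) == pytest.approx([0.03, 0.06, 0.06])

    @pytest.mark.parametrize("seed", range(5))
    def test_holm_matches_stepdown_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ps = list(rng.uniform(0, 1, size=rng.integers(1, 8)))
        got = holm_adjust(ps)
        assert got == pytest.approx(holm_oracle(ps), rel=1e-12)
        # monotone in raw-p order and >= raw
        order = np.argsort(ps)
        assert all(got[i] >= ps[i] for i in range(len(ps)))
        assert all(got[order[i]] <= got[order[i + 1]] + 1e-12
                   for i in range(len(ps) - 1))

    def test_single_comparison_adjustment_is_identity(self):
        assert holm_adjust([0.123]) == pytest.approx([0.123])

    def test_group_without_informative_reads_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            compare_groups({
                "a": JunctionCounts(1, 1, 1, "a"), "b": JunctionCounts(1, 0, 0, "b")
            })


class TestAllelicAssociation:
    def _reads(self, bases):
        return pd.DataFrame({"allele_base_at_variant": bases})

    def test_seven_three_split_exact_p(self):
        a = allelic_association(self._reads(["C"] * 7 + ["T"] * 3), "C", "T")
        assert a.mutant_fraction == pytest.approx(0.7)
        assert a.p_value == pytest.approx(0.34375)  # 2 * P(X >= 7 | n=10)
        assert a.p_value == pytest.approx(binomial_two_sided_oracle(7, 10))

    def test_balanced_split_p_one(self):
        a = allelic_association(self._reads(["C"] * 5 + ["T"] * 5), "C", "T")
        assert a.mutant_fraction == 0.5
        assert a.p_value == pytest.approx(1.0)

    def test_no_covering_reads_is_an_error(self):
        with pytest.raises(ValueError, match="covering"):
            allelic_association(self._reads(["."] * 4), "C", "T")

    def test_other_bases_excluded_and_reported(self):
        a = allelic_association(self._reads(["C", "C", "T", "G", "."]), "C", "T")
        assert (a.mutant_reads, a.reference_reads, a.other_reads) == (2, 1, 1)

    @pytest.mark.parametrize("k,n", [(0, 12), (3, 9), (55, 100), (700, 1400)])
    def test_matches_pmf_enumeration_oracle(self, k, n):
        bases = ["C"] * k + ["T"] * (n - k)
        a = allelic_association(self._reads(bases), "C", "T")
        assert a.p_value == pytest.approx(binomial_two_sided_oracle(k, n),
                                          rel=1e-9)


class TestFpkm:
    def test_direct_formula(self):
        assert fpkm(1000, 2000, 10**7).fpkm == pytest.approx(50.0)

    def test_zero_fragments(self):
        assert fpkm(0, 2000, 10**7).fpkm == 0.0

    def test_doubling_depth_halves_fpkm(self):
        a = fpkm(500, 1500, 2 * 10**6).fpkm
        b = fpkm(500, 1500, 4 * 10**6).fpkm
        assert a == pytest.approx(2 * b)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fpkm(10, 0, 100)
        with pytest.raises(ValueError):
            fpkm(10, 100, 0)


class TestParameterRecovery:
    def test_estimator_recovers_configured_retention_within_two_points(self, demo):
        """>= 10^4 informative reads per group: |R_hat - r| < 0.02."""
        model, _, _ = demo
        cfg = ReadSimConfig(
            gene=model, seed=11, fragments_per_sample_per_intron=1500,
            samples_per_group={"affected": 7, "control": 7},
        )
        reads, truth = gen_junction_reads(cfg)
        _, per_group = count_junctions(reads, model)
        focal = per_group[per_group["intron"] == 6]
        for _, row in focal.iterrows():
            r_hat = row["spanning"] / (row["spanning"] + row["spliced"])
            assert row["spanning"] + row["spliced"] >= 10_000
            assert abs(r_hat - truth[row["group"]]["r_pooled"]) < 0.02

    def test_heterozygote_cis_signal_mutant_fraction_above_half(self, demo):
        """With mutant-allele retention above wild type, reads covering the
        variant come predominantly from the mutant allele."""
        model, _, var = demo
        cfg = ReadSimConfig(
            gene=model, seed=17, fragments_per_sample_per_intron=1200,
            samples_per_group={"parent": 8},
        )
        reads, _ = gen_junction_reads(cfg)
        a = allelic_association(reads, var["alt"], var["ref"])
        assert a.mutant_fraction > 0.5
        assert a.p_value < 0.05

    def test_per_intron_pattern_affected_above_parent_above_control(self, demo):
        """Focal-intron retention orders affected > parent > control while
        non-focal introns sit near baseline for every group."""
        model, _, _ = demo
        cfg = ReadSimConfig(gene=model, seed=23,
                            fragments_per_sample_per_intron=250)
        reads, _ = gen_junction_reads(cfg)
        _, per_group = count_junctions(reads, model)
        table = retention_table(per_group)
        focal = table[table["intron"] == 6].set_index("group")["retention"]
        assert focal["affected"] > focal["parent"] > focal["control"]
        others = table[table["intron"] != 6]
        assert (others["retention"] < 0.06).all()
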