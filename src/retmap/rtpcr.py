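"""RT-PCR fragment-area splicing quantification and ΔΔCt relative expression.

Orthogonal (non-sequencing) validation of a splicing defect: per sample,
the fraction of unspliced RT-PCR product is the fluorescence area of the
unspliced band over the total band area — a relative measure of splicing,
not an absolute one, since amplification efficiency differs between
amplicons.  Group means are compared with two-tailed unpaired t-tests under
Holm step-down adjustment.  Transcript abundance is quantified by the
comparative-Ct method: ΔCt = Ct(target) − Ct(reference assay) per sample,
ΔΔCt between groups, relative expression 2^(−ΔΔCt) with a t-interval on
ΔCt propagated through the exponent (hence asymmetric CIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .retention import holm_adjust


@dataclass
class GroupSummary:
    group: str
    n: int
    mean_percent_unspliced: float
    sd_percent_unspliced: float


@dataclass
class PairwiseT:
    group_a: str
    group_b: str
    t_statistic: float
    p_raw: float
    p_adjusted: float | None = None


@dataclass
class RelativeExpression:
    group: str
    n: int
    delta_delta_ct: float
    relative: float
    ci_low: float
    ci_high: float


def percent_unspliced(area_unspliced: float, area_spliced: float) -> float:
    """100 x unspliced area / total area.  Relative splicing measure only."""
    if area_unspliced < 0 or area_spliced < 0:
        raise ValueError("band areas must be non-negative")
    total = area_unspliced + area_spliced
    if total == 0:
        raise ValueError("both band areas are zero")
    return 100.0 * area_unspliced / total


def group_summary(
    records: pd.DataFrame, equal_var: bool = True
) -> tuple[list[GroupSummary], list[PairwiseT]]:
    """Per-group mean/SD of percent-unspliced and pairwise t-tests.

    ``records`` needs columns sample_id, group, area_unspliced,
    area_spliced.  Sample SD (n-1 denominator).  Groups with fewer than two
    samples are summarised but excluded from testing with a warning.
    Student's pooled-variance t by default; ``equal_var=False`` gives Welch.
    """
    pct = records.apply(
        lambda r: percent_unspliced(r["area_unspliced"], r["area_spliced"]), axis=1
    )
    work = records.assign(percent_unspliced=pct)
    summaries = []
    values = {}
    for group, sub in work.groupby("group", sort=False):
        x = sub["percent_unspliced"].to_numpy(dtype=float)
        summaries.append(
            GroupSummary(
                group=str(group),
                n=len(x),
                mean_percent_unspliced=float(np.mean(x)),
                sd_percent_unspliced=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            )
        )
        if len(x) >= 2:
            values[str(group)] = x
        else:
            warnings.warn(
                f"group {group!r} has fewer than 2 samples; excluded from testing",
                stacklevel=2,
            )
    tests = []
    for a, b in combinations(sorted(values), 2):
        t, p = stats.ttest_ind(values[a], values[b], equal_var=equal_var)
        tests.append(PairwiseT(a, b, float(t), float(p)))
    adj = holm_adjust([t.p_raw for t in tests])
    for t_, a_ in zip(tests, adj):
        t_.p_adjusted = a_
    return summaries, tests


def ddct_relative(
    records: pd.DataFrame,
    reference_group: str,
    alpha: float = 0.05,
) -> list[RelativeExpression]:
    """Relative target expression per group by the comparative-Ct method.

    Per sample ΔCt = ct_target − ct_reference; per group ΔΔCt = mean ΔCt −
    mean ΔCt of ``reference_group``; relative expression = 2^(−ΔΔCt).  The
    CI is a Welch t-interval on the difference of mean ΔCt, exponentiated
    (asymmetric around the point estimate).  The reference group is
    reported with relative expression exactly 1.
    """
    if reference_group not in set(records["group"]):
        raise ValueError(f"reference group {reference_group!r} missing from records")
    dct = (records["ct_target"] - records["ct_reference"]).astype(float)
    work = records.assign(dct=dct)
    ref = work.loc[work["group"] == reference_group, "dct"].to_numpy()
    out = []
    for group, sub in work.groupby("group", sort=False):
        x = sub["dct"].to_numpy()
        if group == reference_group:
            out.append(RelativeExpression(str(group), len(x), 0.0, 1.0, 1.0, 1.0))
            continue
        ddct = float(np.mean(x) - np.mean(ref))
        se = float(np.sqrt(np.var(x, ddof=1) / len(x) + np.var(ref, ddof=1) / len(ref)))
        # Welch–Satterthwaite degrees of freedom
        va, vb = np.var(x, ddof=1) / len(x), np.var(ref, ddof=1) / len(ref)
        df = (va + vb) ** 2 / (
            va**2 / (len(x) - 1) + vb**2 / (len(ref) - 1)
        )
        tcrit = float(stats.t.ppf(1 - alpha / 2, df))
        lo, hi = ddct - tcrit * se, ddct + tcrit * se
        out.append(
            RelativeExpression(
                group=str(group),
                n=len(x),
                delta_delta_ct=ddct,
                relative=float(2.0 ** (-ddct)),
                ci_low=float(2.0 ** (-hi)),
                ci_high=float(2.0 ** (-lo)),
            )
        )
    return out
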