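"""Taxonomic-profile analytics for OTU count tables.

Covers the profile comparisons of the study: aggregation of OTU counts to one
of five ranks (phylum..genus, with an explicit "Unclassified" bucket so reads
are conserved), relative abundances, the two community filters (eliminate
taxa below 1% everywhere; list taxa whose between-sample proportion
difference is >= 1%), shared-taxon sets, and a two-proportion hypothesis test
in the STAMP style: a Yates-corrected G-test against chi-square(1), falling
back to Fisher's exact test whenever any expected cell is small, with a
continuity-corrected asymptotic (Wald) confidence interval for the proportion
difference.

The Fisher branch enumerates the hypergeometric support in exact integer
arithmetic: the two-sided p sums the probabilities of all tables whose exact
probability does not exceed the observed one, which keeps results stable to
machine precision regardless of how the margins factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import RANKS, UNCLASSIFIED, OtuTable


# ---------------------------------------------------------------------------
# rank profiles


@dataclass
class RankProfile:
    """Taxon x sample counts at one taxonomic rank.

    ``totals`` are the per-sample read totals of the *source* table, kept
    separately so filtered profiles keep reporting proportions against the
    original library size instead of silently re-normalizing.
    """

    rank: str
    taxa: list[str]
    samples: list[str]
    counts: np.ndarray
    totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError("profile matrix shape does not match taxa/sample lists")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)
        self.totals = np.asarray(self.totals)

    @property
    def proportions(self) -> np.ndarray:
        totals = self.totals.astype(float)
        if np.any(totals <= 0):
            raise ValidationError("proportions undefined for samples with zero reads")
        return self.counts / totals

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ValidationError(f"unknown sample {sample!r}") from None

    def to_frame(self, proportions: bool = False) -> pd.DataFrame:
        data = self.proportions if proportions else self.counts
        return pd.DataFrame(data, index=self.taxa, columns=self.samples)


@dataclass
class FilterResult:
    """Outcome of the minimum-proportion filter; nothing is silently lost."""

    retained: RankProfile
    removed_taxa: list[str]
    removed_mass: np.ndarray  # reads removed per sample


def aggregate_rank(table: OtuTable, rank: str) -> RankProfile:
    """Sum OTU counts over OTUs sharing the label at ``rank``.

    OTUs unclassified at that rank are pooled under "Unclassified" so the
    per-sample totals equal the source table's library sizes exactly.
    """
    labels = table.rank_labels(rank)  # validates the rank name
    order: list[str] = []
    index: dict[str, int] = {}
    for label in labels:
        if label not in index:
            index[label] = len(order)
            order.append(label)
    counts = np.zeros((len(order), len(table.samples)), dtype=table.counts.dtype)
    for row, label in enumerate(labels):
        counts[index[label]] += table.counts[row]
    return RankProfile(rank=rank, taxa=order, samples=list(table.samples), counts=counts)


def filter_min_proportion(profile: RankProfile, threshold: float = 0.01) -> FilterResult:
    """Drop taxa below ``threshold`` relative abundance in *every* sample.

    A taxon is retained iff its proportion is >= threshold (boundary
    inclusive: only strictly-lower taxa are eliminated) in at least one
    sample.  Retained proportions stay referenced to the original totals.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    props = profile.proportions
    keep = (props >= threshold).any(axis=1)
    retained = RankProfile(
        rank=profile.rank,
        taxa=[t for t, k in zip(profile.taxa, keep) if k],
        samples=list(profile.samples),
        counts=profile.counts[keep],
        totals=profile.totals.copy(),
    )
    removed = profile.counts[~keep]
    return FilterResult(
        retained=retained,
        removed_taxa=[t for t, k in zip(profile.taxa, keep) if not k],
        removed_mass=removed.sum(axis=0),
    )


def dominant_by_difference(
    profile: RankProfile, sample_a: str, sample_b: str, min_diff: float = 0.01
) -> pd.DataFrame:
    """Taxa whose proportion difference between two samples is >= ``min_diff``.

    Returns a frame ``taxon,prop_a,prop_b,diff`` ordered by descending |diff|.
    """
    ia, ib = profile.sample_index(sample_a), profile.sample_index(sample_b)
    props = profile.proportions
    diff = props[:, ia] - props[:, ib]
    mask = np.abs(diff) >= min_diff
    frame = pd.DataFrame(
        {
            "taxon": [t for t, m in zip(profile.taxa, mask) if m],
            "prop_a": props[mask, ia],
            "prop_b": props[mask, ib],
            "diff": diff[mask],
        }
    )
    return frame.reindex(frame["diff"].abs().sort_values(ascending=False, kind="stable").index).reset_index(
        drop=True
    )


def shared_taxa(
    profile: RankProfile, samples: Sequence[str] | None = None, min_proportion: float = 0.01
) -> set[str]:
    """Taxa reaching ``min_proportion`` in every listed sample (default: all)."""
    samples = list(samples) if samples is not None else list(profile.samples)
    if len(samples) < 2:
        raise ValidationError("shared-taxon analysis needs >= 2 samples")
    props = profile.proportions
    cols = [profile.sample_index(s) for s in samples]
    mask = (props[:, cols] >= min_proportion).all(axis=1)
    return {t for t, m in zip(profile.taxa, mask) if m}


# ---------------------------------------------------------------------------
# two-proportion test (G-test with Yates / Fisher hybrid)


@dataclass
class ProportionTestResult:
    taxon: str
    p_value: float
    test_used: str  # "g_yates" or "fisher"
    diff: float  # proportion_a - proportion_b
    ci_low: float
    ci_high: float
    expected_min: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


def fisher_exact_two_sided(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by exact integer enumeration.

    Conditional on the margins, the count in cell (1,1) follows a
    hypergeometric distribution; the two-sided p sums P(X = x) over all x in
    the support whose probability does not exceed the observed table's.
    Probabilities share the common denominator C(N, k), so the comparison is
    done on exact integer numerators C(total_a, x) * C(total_b, k - x).
    """
    k = count_a + count_b
    lo = max(0, k - total_b)
    hi = min(k, total_a)
    # integer numerators over the support, by an exact ratio recurrence
    nums = [math.comb(total_a, lo) * math.comb(total_b, k - lo)]
    for x in range(lo, hi):
        num = nums[-1] * (total_a - x) * (k - x)
        den = (x + 1) * (total_b - k + x + 1)
        nums.append(num // den)
    observed = nums[count_a - lo]
    numerator = sum(n for n in nums if n <= observed)
    return numerator / math.comb(total_a + total_b, k)


def _g_test_yates(table: np.ndarray) -> tuple[float, float]:
    """Yates-corrected G statistic and chi-square(1) p for a 2x2 table."""
    g, p, _, _ = stats.chi2_contingency(table, correction=True, lambda_="log-likelihood")
    return float(g), float(p)


def proportion_diff_ci(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Continuity-corrected asymptotic (Wald) CI for p_a - p_b, clipped to [-1, 1]."""
    p1, p2 = count_a / total_a, count_b / total_b
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(p1 * (1 - p1) / total_a + p2 * (1 - p2) / total_b)
    cc = 0.5 * (1.0 / total_a + 1.0 / total_b)
    half = z * se + cc
    diff = p1 - p2
    return max(-1.0, diff - half), min(1.0, diff + half)


def two_proportion_test(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    fisher_threshold: float = 20.0,
    taxon: str = "",
    ci_level: float = 0.95,
) -> ProportionTestResult:
    """Compare a taxon's relative abundance between two pooled samples.

    Builds the 2x2 table ``[[count_a, total_a - count_a], [count_b,
    total_b - count_b]]`` and tests equality of proportions with a
    Yates-corrected G-test against chi-square(1); whenever any expected cell
    is below ``fisher_threshold`` the two-sided Fisher exact p is reported
    instead (``test_used`` records the switch).  The confidence interval for
    the difference is the asymptotic normal interval with continuity
    correction.
    """
    for name, value in (("count_a", count_a), ("total_a", total_a), ("count_b", count_b), ("total_b", total_b)):
        if value != int(value) or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
    count_a, total_a, count_b, total_b = int(count_a), int(total_a), int(count_b), int(total_b)
    if total_a <= 0 or total_b <= 0:
        raise ValidationError("sample totals must be > 0")
    if count_a > total_a or count_b > total_b:
        raise ValidationError("count exceeds its sample total")

    table = np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]], dtype=float
    )
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    expected_min = float(expected.min())
    if expected_min < fisher_threshold:
        p = fisher_exact_two_sided(count_a, total_a, count_b, total_b)
        used = "fisher"
    else:
        _, p = _g_test_yates(table)
        used = "g_yates"
    ci_low, ci_high = proportion_diff_ci(count_a, total_a, count_b, total_b, ci_level)
    return ProportionTestResult(
        taxon=taxon,
        p_value=p,
        test_used=used,
        diff=count_a / total_a - count_b / total_b,
        ci_low=ci_low,
        ci_high=ci_high,
        expected_min=expected_min,
    )


def profile_proportion_tests(
    profile: RankProfile,
    sample_a: str,
    sample_b: str,
    fisher_threshold: float = 20.0,
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run :func:`two_proportion_test` for each taxon of a profile."""
    ia, ib = profile.sample_index(sample_a), profile.sample_index(sample_b)
    total_a = int(profile.totals[ia])
    total_b = int(profile.totals[ib])
    rows = []
    for t in (taxa if taxa is not None else profile.taxa):
        if t not in profile.taxa:
            raise ValidationError(f"unknown taxon {t!r}")
        r = profile.taxa.index(t)
        res = two_proportion_test(
            int(profile.counts[r, ia]),
            total_a,
            int(profile.counts[r, ib]),
            total_b,
            fisher_threshold=fisher_threshold,
            taxon=t,
        )
        rows.append(
            {
                "taxon": t,
                "p_value": res.p_value,
                "test_used": res.test_used,
                "diff": res.diff,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)
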