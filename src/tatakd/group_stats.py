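"""Group summaries of KD estimates and the food vs non-food Z-test.

Per-promoter KD values (nM) are pooled into group summaries (N, mean M0,
SEM) and two groups are compared with the difference-of-means Z-test

    Z = |M1 - M2| / sqrt(SEM1^2 + SEM2^2),

referred to the standard normal; this is the "Fisher's Z-test" form that
reproduces the published statistics from the published group summaries.
Group-level averages pool promoters, not species means (the published N
for a group average equals the promoter count); a species-weighted
variant is available behind a flag.  The three gene-family tests are
reported uncorrected by default, with an optional Bonferroni factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .promoter_io import Cohort, partition
from .tbp_affinity import AffinityEstimate

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVELS = (0.001, 0.01, 0.05)


@dataclass(frozen=True)
class GroupSummary:
    """N, arithmetic mean M0 and SEM of KD (nM) for a promoter set."""

    label: str
    n: int
    m0: float  # arithmetic mean KD, nM
    sem: float  # standard error of the mean, nM


@dataclass(frozen=True)
class ZTestResult:
    """Z statistic and two-sided normal p-value for a group comparison."""

    z: float
    p_two_sided: float
    significant_at: float | None  # highest conventional level attained
    mean_diff: float  # signed M0(a) - M0(b); Z itself is absolute

    @property
    def stars(self) -> str:
        if self.significant_at is None:
            return ""
        return {0.05: "*", 0.01: "**", 0.001: "***"}[self.significant_at]


def _significance(p: float) -> float | None:
    for level in SIGNIFICANCE_LEVELS:
        if p < level:
            return level
    return None


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Arithmetic mean and SEM (sample SD / sqrt(n)) of KD values in nM."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"cannot summarize empty value list for {label!r}")
    if np.any(arr <= 0):
        raise ValueError(f"KD values must be positive ({label!r})")
    n = int(arr.size)
    m0 = float(arr.mean())
    if n == 1:
        logger.warning("group %r has a single promoter; SEM set to 0", label)
        sem = 0.0
    else:
        sem = float(arr.std(ddof=1) / math.sqrt(n))
    return GroupSummary(label=label, n=n, m0=m0, sem=sem)


def fisher_z_test(a: GroupSummary, b: GroupSummary) -> ZTestResult:
    """Difference-of-means Z-test between two group summaries.

    Symmetric in its arguments; the comparison direction is carried by
    ``mean_diff`` (a.m0 - b.m0), not by the sign of Z.
    """
    pooled = math.hypot(a.sem, b.sem)
    diff = a.m0 - b.m0
    if pooled == 0.0:
        if diff == 0.0:
            raise ZeroDivisionError(
                "Z undefined: both SEMs zero and means equal "
                f"({a.label!r} vs {b.label!r})"
            )
        logger.warning(
            "both SEMs zero with unequal means (%r vs %r): Z = +inf", a.label, b.label
        )
        return ZTestResult(z=math.inf, p_two_sided=0.0,
                           significant_at=0.001, mean_diff=diff)
    z = abs(diff) / pooled
    p = 2.0 * stats.norm.sf(z)
    return ZTestResult(z=z, p_two_sided=p, significant_at=_significance(p),
                       mean_diff=diff)


def published_summaries() -> dict[str, dict[str, GroupSummary]]:
    """Published per-family food/non-food KD summaries shipped with the package.

    Returns ``{family: {group: GroupSummary}}`` with KD in nM; these are
    the reported N/M0/SEM values from which the reference Z statistics
    are recomputable.
    """
    with resources.files("tatakd.data").joinpath(
        "published_group_summaries.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    out: dict[str, dict[str, GroupSummary]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.family, {})[row.group] = GroupSummary(
            label=f"{row.family}/{row.group}",
            n=int(row.n), m0=float(row.m0_nM), sem=float(row.sem_nM),
        )
    return out


@dataclass(frozen=True)
class FamilyReport:
    """Per-family species rows, group summaries and the group test."""

    family: str
    species_rows: pd.DataFrame  # group, species, N, M0_nM, SEM_nM
    group_summaries: dict[str, GroupSummary]  # keyed by group label
    test: ZTestResult | None  # None if only one group present


def _kd_nM(est: AffinityEstimate) -> float:
    return est.kd * 1e9


def build_family_report(
    estimates: Mapping[str, AffinityEstimate],
    cohort: Cohort,
    species_weighted: bool = False,
    bonferroni: int | None = None,
) -> dict[str, FamilyReport]:
    """Aggregate per-promoter estimates into per-family reports.

    For each gene family: one row per (group, species) with N/M0/SEM,
    one overall summary per group, and the food vs non-food Z-test.
    Rows are ordered by group then species alphabetically.  A family
    present in a single group is reported with ``test=None``.  With
    ``species_weighted=True`` group means average species means instead
    of pooling promoters.  ``bonferroni`` multiplies p-values by the
    given number of tests (capped at 1).
    """
    missing = [r.record_id for r in cohort if r.record_id not in estimates]
    if missing:
        raise KeyError(f"records without estimates: {missing}")

    reports: dict[str, FamilyReport] = {}
    for family, fam_cohort in partition(cohort, "gene_family").items():
        rows = []
        group_summaries: dict[str, GroupSummary] = {}
        by_group = partition(fam_cohort, "group")
        for group, g_cohort in by_group.items():
            species_means = []
            for species, s_cohort in partition(g_cohort, "species").items():
                s = summarize(
                    [_kd_nM(estimates[r.record_id]) for r in s_cohort],
                    label=f"{family}/{group}/{species}",
                )
                species_means.append(s.m0)
                rows.append({
                    "family": family, "group": group, "species": species,
                    "N": s.n, "M0_nM": s.m0, "SEM_nM": s.sem,
                })
            if species_weighted:
                group_summaries[group] = summarize(
                    species_means, label=f"{family}/{group}"
                )
            else:
                group_summaries[group] = summarize(
                    [_kd_nM(estimates[r.record_id]) for r in g_cohort],
                    label=f"{family}/{group}",
                )
        test = None
        if len(group_summaries) == 2:
            food = group_summaries["food"]
            nonfood = group_summaries["non_food"]
            test = fisher_z_test(food, nonfood)
            if bonferroni:
                p = min(1.0, test.p_two_sided * bonferroni)
                test = ZTestResult(z=test.z, p_two_sided=p,
                                   significant_at=_significance(p),
                                   mean_diff=test.mean_diff)
        else:
            logger.warning(
                "family %r present in only one group; test not computable", family
            )
        reports[family] = FamilyReport(
            family=family,
            species_rows=pd.DataFrame(
                rows, columns=["family", "group", "species", "N", "M0_nM", "SEM_nM"]
            ),
            group_summaries=group_summaries,
            test=test,
        )
    return reports
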