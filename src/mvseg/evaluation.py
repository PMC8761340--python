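"""Volumetric and spatial scoring: DSC, ICC(2,1), subgroups, rank-sum tests.

Spatial overlap is measured with the Dice similarity coefficient and
volumetric agreement between manual and automatic volumes with the
intraclass correlation coefficient — single measure, absolute agreement,
two-way random effects, i.e. ICC(2,1):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

with MSR/MSC/MSE the row (case), column (rater) and error mean squares of the
two-way ANOVA over an n-case x k-rater table (k = 2: manual, automatic).
Absolute agreement penalizes systematic bias, unlike a Pearson correlation.

Cases are stratified into four volume groups (V1: <= 3 cm^3, V2: 3-7,
V3: 7-15, V4: > 15) and compared across subgroups with the two-sided
Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Sequence as Seq

import numpy as np
from scipy import stats

from mvseg.volume_io import LabelMask, Location


class VolumeGroup(enum.Enum):
    V1 = "V <= 3 cm3"
    V2 = "3 < V <= 7 cm3"
    V3 = "7 < V <= 15 cm3"
    V4 = "V > 15 cm3"


@dataclass
class CaseResult:
    """Per-case evaluation record."""

    case_id: str
    dsc: float
    ref_volume_cm3: float
    pred_volume_cm3: float
    fold: int
    t_stage: str = "T2"
    n_stage: str = "N0"
    location: Location = Location.OROPHARYNX

    def __post_init__(self) -> None:
        if not 0 <= self.dsc <= 1:
            raise ValueError("DSC must lie in [0, 1]")
        if self.ref_volume_cm3 < 0 or self.pred_volume_cm3 < 0:
            raise ValueError("volumes must be non-negative")

    @property
    def volume_group(self) -> VolumeGroup:
        return volume_group(self.ref_volume_cm3)


@dataclass
class SubgroupSummary:
    n: int
    mean: float
    sd: float


@dataclass
class SegmentationReport:
    """Cohort-level summary mirroring a per-subgroup performance table."""

    n_cases: int
    icc_per_fold: dict[int, float]
    icc_mean: float
    icc_sd: float
    dsc_mean: float          # across cases
    dsc_sd: float
    dsc_fold_mean: float     # across fold means
    dsc_fold_sd: float
    subgroups: dict[str, dict[str, SubgroupSummary]]
    wilcoxon: dict[str, dict[tuple[str, str], float]]
    significant: dict[str, list[tuple[str, str]]]
    warnings: list[str] = field(default_factory=list)


def dsc(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``.

    Symmetric and bounded in [0, 1]; two empty masks score 1.0 by convention
    (total function; flagged upstream when it matters).
    """
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.sum((a.data == 1) & (b.data == 1)))
    return 2.0 * inter / (na + nb)


def icc_absolute_agreement(pairs: Seq[tuple[float, float]]) -> float:
    """ICC(2,1) of an (n x 2) table of (reference, predicted) volumes.

    Two-way random effects, single measure, absolute agreement.  Needs at
    least 3 pairs and non-zero total variance.
    """
    table = np.asarray(pairs, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (ref, pred) tuples")
    n, k = table.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    grand = table.mean()
    sst = float(((table - grand) ** 2).sum())
    if sst == 0.0:
        raise ValueError("zero total variance: ICC undefined")
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def volume_group(v: float) -> VolumeGroup:
    """Four-group tumor-volume stratification with closed upper boundaries."""
    if v < 0:
        raise ValueError("volume must be >= 0")
    if v <= 3:
        return VolumeGroup.V1
    if v <= 7:
        return VolumeGroup.V2
    if v <= 15:
        return VolumeGroup.V3
    return VolumeGroup.V4


def wilcoxon_ranksum(x: Seq[float], y: Seq[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration when both groups have at most 20 observations and no
    ties occur; otherwise the normal approximation with midrank tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.pvalue)


def _summary(values: np.ndarray) -> SubgroupSummary:
    return SubgroupSummary(n=len(values), mean=float(np.mean(values)),
                           sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0)


def evaluate_cohort(results: Seq[CaseResult], alpha: float = 0.05) -> SegmentationReport:
    """Aggregate per-case results into the cohort report.

    ICC is computed per fold and summarized as mean ± SD across folds (a fold
    needs >= 3 cases, otherwise it is skipped with a warning).  DSC is
    summarized across cases (primary) and across fold means, overall and per
    subgroup, with all pairwise two-sided rank-sum comparisons per
    stratification.  The output is invariant to the order of ``results``.
    """
    if not results:
        raise ValueError("no results to evaluate")
    results = sorted(results, key=lambda r: r.case_id)
    warnings: list[str] = []

    icc_per_fold: dict[int, float] = {}
    folds = sorted({r.fold for r in results})
    for f in folds:
        sub = [r for r in results if r.fold == f]
        if len(sub) < 3:
            warnings.append(f"fold {f}: fewer than 3 cases, ICC skipped")
            continue
        try:
            icc_per_fold[f] = icc_absolute_agreement(
                [(r.ref_volume_cm3, r.pred_volume_cm3) for r in sub]
            )
        except ValueError as exc:
            warnings.append(f"fold {f}: ICC undefined ({exc})")
    icc_vals = np.array(list(icc_per_fold.values()))
    icc_mean = float(icc_vals.mean()) if icc_vals.size else float("nan")
    icc_sd = float(icc_vals.std(ddof=1)) if icc_vals.size > 1 else 0.0

    dscs = np.array([r.dsc for r in results])
    fold_means = np.array(
        [np.mean([r.dsc for r in results if r.fold == f]) for f in folds]
    )

    stratifiers = {
        "t_stage": lambda r: r.t_stage,
        "n_stage": lambda r: r.n_stage,
        "location": lambda r: r.location.value,
        "volume_group": lambda r: r.volume_group.name,
    }
    subgroups: dict[str, dict[str, SubgroupSummary]] = {}
    wilcoxon: dict[str, dict[tuple[str, str], float]] = {}
    significant: dict[str, list[tuple[str, str]]] = {}
    for name, keyfn in stratifiers.items():
        groups: dict[str, list[float]] = {}
        for r in results:
            groups.setdefault(keyfn(r), []).append(r.dsc)
        subgroups[name] = {
            lvl: _summary(np.asarray(vals)) for lvl, vals in sorted(groups.items())
        }
        wilcoxon[name] = {}
        significant[name] = []
        for a, b in itertools.combinations(sorted(groups), 2):
            p = wilcoxon_ranksum(groups[a], groups[b])
            wilcoxon[name][(a, b)] = p
            if p < alpha:
                significant[name].append((a, b))

    return SegmentationReport(
        n_cases=len(results),
        icc_per_fold=icc_per_fold,
        icc_mean=icc_mean,
        icc_sd=icc_sd,
        dsc_mean=float(dscs.mean()),
        dsc_sd=float(dscs.std(ddof=1)) if dscs.size > 1 else 0.0,
        dsc_fold_mean=float(fold_means.mean()),
        dsc_fold_sd=float(fold_means.std(ddof=1)) if fold_means.size > 1 else 0.0,
        subgroups=subgroups,
        wilcoxon=wilcoxon,
        significant=significant,
        warnings=warnings,
    )


def report_to_text(report: SegmentationReport) -> str:
    """Human-readable rendering of the cohort report."""
    lines = [
        f"Cases: {report.n_cases}",
        f"ICC(2,1) across folds: {report.icc_mean:.2f} +/- {report.icc_sd:.2f}",
        f"DSC across cases:      {report.dsc_mean:.2f} +/- {report.dsc_sd:.2f}",
        f"DSC across folds:      {report.dsc_fold_mean:.2f} +/- {report.dsc_fold_sd:.2f}",
    ]
    for name, table in report.subgroups.items():
        lines.append(f"\n[{name}]")
        for lvl, s in table.items():
            lines.append(f"  {lvl:<14} n={s.n:<4} DSC {s.mean:.2f} +/- {s.sd:.2f}")
        sig = report.significant.get(name) or []
        for (a, b) in sig:
            lines.append(f"  {a} vs {b}: p={report.wilcoxon[name][(a, b)]:.4f} (*)")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines)
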