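"""DSC, ICC(2,1), volume groups, rank-sum tests and cohort aggregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvseg.evaluation import (
    CaseResult,
    VolumeGroup,
    dsc,
    evaluate_cohort,
    icc_absolute_agreement,
    report_to_text,
    volume_group,
    wilcoxon_ranksum,
)
from mvseg.volume_io import LabelMask, Location


def _mask(data):
    return LabelMask(np.asarray(data, dtype=np.uint8), np.eye(4))


def _rand_mask(rng, p=0.3, shape=(6, 6, 6)):
    return _mask(rng.random(shape) < p)


class TestDsc:
    def test_identical_nonempty_masks(self, rng):
        m = _rand_mask(rng)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dsc(_mask(a), _mask(b)) == 0.0

    def test_formula_example(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a.ravel()[:4] = 1          # |a| = 4
        b.ravel()[1:7] = 1         # |b| = 6, overlap 3
        assert dsc(_mask(a), _mask(b)) == pytest.approx(0.6)

    def test_both_empty_defined_as_one(self):
        z = _mask(np.zeros((3, 3, 3)))
        assert dsc(z, z) == 1.0

    def test_matches_set_arithmetic_bruteforce(self, rng):
        for _ in range(200):
            a, b = _rand_mask(rng, rng.random()), _rand_mask(rng, rng.random())
            sa = {tuple(i) for i in np.argwhere(a.data)}
            sb = {tuple(i) for i in np.argwhere(b.data)}
            expect = 1.0 if not sa and not sb else 2 * len(sa & sb) / (len(sa) + len(sb))
            assert dsc(a, b) == pytest.approx(expect, abs=1e-12)
            assert dsc(a, b) == dsc(b, a)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsc(_mask(np.zeros((3, 3, 3))), _mask(np.zeros((4, 4, 4))))


def icc21_oracle(table):
    """From-scratch two-way ANOVA ICC(2,1) via explicit sums of squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    msr = k * sum((r - grand) ** 2 for r in table.mean(axis=1)) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in table.mean(axis=0)) / (k - 1)
    sse = sum(
        (table[i, j] - table[i].mean() - table[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc:
    def test_perfect_agreement(self):
        pairs = [(1.0, 1.0), (5.0, 5.0), (9.0, 9.0), (2.5, 2.5)]
        assert icc_absolute_agreement(pairs) == pytest.approx(1.0)

    def test_constant_offset_penalized_below_correlation(self, rng):
        ref = rng.random(10) * 10
        pairs = list(zip(ref, ref + 20.0))
        icc = icc_absolute_agreement(pairs)
        assert icc < 0.5  # Pearson correlation would be 1.0

    def test_matches_anova_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            ref = rng.random(n) * 30
            pred = ref + rng.normal(0, 1 + ref / 10)
            pairs = list(zip(ref, pred))
            assert icc_absolute_agreement(pairs) == pytest.approx(
                icc21_oracle(pairs), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        ref = rng.random(12) * 20
        pred = ref + rng.normal(0, 3, 12) + 2
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": ["manual", "auto"] * 12,
            "scores": np.column_stack([ref, pred]).ravel(),
        })
        table = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        # single-measure absolute agreement: labelled ICC(A,1) or ICC2
        key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        expected = table.loc[key, "ICC"]
        assert icc_absolute_agreement(list(zip(ref, pred))) == pytest.approx(
            float(expected), abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([(1, 1), (2, 2)])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([(2.0, 2.0)] * 5)


class TestVolumeGroup:
    @pytest.mark.parametrize("v,expected", [
        (0.0, VolumeGroup.V1),
        (3.0, VolumeGroup.V1),       # closed upper boundary
        (3.0001, VolumeGroup.V2),
        (7.0, VolumeGroup.V2),
        (13.9, VolumeGroup.V3),      # the cohort's median reference volume
        (15.0, VolumeGroup.V3),
        (15.000001, VolumeGroup.V4),
        (100.0, VolumeGroup.V4),
    ])
    def test_boundaries(self, v, expected):
        assert volume_group(v) is expected

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partitions_nonnegative_reals(self, v):
        assert volume_group(v) in VolumeGroup

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            volume_group(-0.1)


class TestWilcoxon:
    def test_identical_groups_center_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert wilcoxon_ranksum(x, x) > 0.9

    def test_fully_separated_three_vs_three(self):
        # all C(6,3)=20 rank splits: the observed extreme split has two-sided p
        # 2/20 = 0.1
        assert wilcoxon_ranksum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_symmetry(self, rng):
        x = rng.random(8).tolist()
        y = (rng.random(10) + 0.3).tolist()
        assert wilcoxon_ranksum(x, y) == pytest.approx(wilcoxon_ranksum(y, x))

    def test_exact_matches_enumeration_oracle(self, rng):
        x = sorted(rng.random(4))
        y = sorted(rng.random(5))
        pooled = np.array(x + y)
        ranks = pooled.argsort().argsort() + 1
        obs = ranks[:4].sum()
        count = 0
        total = 0
        for comb in itertools.combinations(range(9), 4):
            w = ranks[list(comb)].sum()
            total += 1
            if abs(w - 4 * 10 / 2) >= abs(obs - 4 * 10 / 2) - 1e-12:
                count += 1
        assert wilcoxon_ranksum(x, y) == pytest.approx(count / total, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


def _cohort(rng, n=40, folds=5, dsc_by_group=None):
    results = []
    locations = list(Location)
    for i in range(n):
        ref = float(rng.uniform(0.5, 25))
        g = volume_group(ref).name
        d = rng.uniform(0.4, 0.8) if dsc_by_group is None else dsc_by_group(g, rng)
        results.append(CaseResult(
            case_id=f"c{i:03d}",
            dsc=float(np.clip(d, 0, 1)),
            ref_volume_cm3=ref,
            pred_volume_cm3=float(max(0.0, ref + rng.normal(0, 2))),
            fold=i % folds,
            t_stage=("T2", "T3", "T4")[i % 3],
            n_stage=("N0", "N1", "N2")[i % 3],
            location=locations[i % 3],
        ))
    return results


class TestEvaluateCohort:
    def test_perfect_cohort_degenerate_summary(self, rng):
        results = [CaseResult(f"c{i}", 1.0, v, v, fold=i % 5,
                              location=Location.OROPHARYNX)
                   for i, v in enumerate(np.linspace(1, 20, 20))]
        report = evaluate_cohort(results)
        assert report.dsc_mean == pytest.approx(1.0)
        assert report.dsc_sd == pytest.approx(0.0)
        assert all(v == pytest.approx(1.0) for v in report.icc_per_fold.values())

    def test_subgroup_counts_partition_total(self, rng):
        report = evaluate_cohort(_cohort(rng))
        for name, table in report.subgroups.items():
            assert sum(s.n for s in table.values()) == report.n_cases

    def test_case_order_invariance(self, rng):
        results = _cohort(rng)
        a = evaluate_cohort(results)
        shuffled = list(results)
        rng.shuffle(shuffled)
        b = evaluate_cohort(shuffled)
        assert a.dsc_mean == b.dsc_mean
        assert a.icc_per_fold == b.icc_per_fold
        assert a.wilcoxon == b.wilcoxon

    def test_size_dependence_detected_by_ranksum(self, rng):
        """Constructed V4 >> V1 DSC separation of 0.3 at n=20 per group is
        flagged significant."""
        def by_group(g, rng):
            base = {"V1": 0.3, "V2": 0.45, "V3": 0.55, "V4": 0.6}[g]
            return base + rng.normal(0, 0.05)

        results = []
        i = 0
        for g, lo, hi in (("V1", 0.5, 3.0), ("V4", 16.0, 25.0)):
            for _ in range(20):
                ref = float(rng.uniform(lo, hi))
                results.append(CaseResult(
                    case_id=f"s{i:03d}", dsc=float(np.clip(by_group(g, rng), 0, 1)),
                    ref_volume_cm3=ref, pred_volume_cm3=ref, fold=i % 5,
                    location=Location.OROPHARYNX))
                i += 1
        report = evaluate_cohort(results)
        assert ("V1", "V4") in report.significant["volume_group"]
        assert report.wilcoxon["volume_group"][("V1", "V4")] < 0.05

    def test_small_fold_skipped_with_warning(self, rng):
        results = _cohort(rng, n=12, folds=6)  # 2 cases per fold
        report = evaluate_cohort(results)
        assert len(report.icc_per_fold) == 0
        assert any("fewer than 3" in w for w in report.warnings)

    def test_text_rendering_mentions_core_numbers(self, rng):
        report = evaluate_cohort(_cohort(rng))
        text = report_to_text(report)
        assert "ICC(2,1)" in text and "DSC" in text
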