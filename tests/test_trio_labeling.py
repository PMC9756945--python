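"""Candidate filters, multi-caller merging and Mendelian labeling."""

import numpy as np
import pytest

from cnvconfirm.calls import CNVCall
from cnvconfirm.depthio import NORMALIZED, DepthMatrix
from cnvconfirm.errors import ValidationError
from cnvconfirm.trio_labeling import (
    ARTIFACT,
    RARE_DEL,
    RARE_DUP,
    LabeledCNV,
    Pedigree,
    RegionScores,
    compute_cohort_frequency,
    filter_candidate_calls,
    label_trio_calls,
    merge_caller_calls,
    split_dataset,
)
from tests.conftest import make_targets


def _call(start=1000, end=3000, sample="ch", chrom="chr2", cnv_type="DEL",
          callers=("xhmm",), num_targets=3, freq=0.005, quality=None):
    return CNVCall(sample, chrom, start, end, cnv_type, frozenset(callers),
                   num_targets, quality or {}, freq)


class TestFilterCandidateCalls:
    def test_single_target_excluded(self):
        assert filter_candidate_calls([_call(num_targets=1)]) == []

    def test_segdup_covered_call_excluded(self):
        call = _call(start=1000, end=2000)
        # 80% of the call inside segmental duplications -> excluded
        segdups = [("chr2", 900, 1500), ("chr2", 1600, 1900)]
        assert filter_candidate_calls([call], segdups) == []
        # 70% covered -> retained (threshold is > 75%)
        assert filter_candidate_calls([call], [("chr2", 1000, 1700)]) == [call]

    def test_overlapping_segdup_track_is_normalized_not_an_error(self):
        call = _call(start=1000, end=2000)
        # overlapping, unsorted segdup entries merge to 1000-1760: 76% > 75%
        segdups = [("chr2", 1400, 1760), ("chr2", 1000, 1500), ("chr2", 1200, 1450)]
        assert filter_candidate_calls([call], segdups) == []

    def test_sex_chromosome_excluded_autosome_kept(self):
        x = _call(chrom="chrX")
        auto = _call(chrom="chr2")
        assert filter_candidate_calls([x, auto]) == [auto]

    def test_common_call_excluded(self):
        assert filter_candidate_calls([_call(freq=0.02)]) == []
        kept = filter_candidate_calls([_call(freq=0.01)])  # boundary: <= 1% kept
        assert len(kept) == 1

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="chr99"):
            filter_candidate_calls([_call(chrom="chr99")])

    def test_idempotent_and_order_preserving(self):
        calls = [_call(start=s, end=s + 1000) for s in (1000, 5000, 9000)]
        once = filter_candidate_calls(calls)
        assert filter_candidate_calls(once) == once
        assert [c.start for c in once] == [1000, 5000, 9000]


def test_compute_cohort_frequency_counts_same_type_carriers():
    a = _call(sample="s1")
    b = _call(sample="s2")  # same interval, same type
    c = _call(sample="s3", cnv_type="DUP")  # same interval, other type
    out = compute_cohort_frequency([a, b, c], cohort_size=100)
    assert out[0].cohort_frequency == pytest.approx(0.02)
    assert out[2].cohort_frequency == pytest.approx(0.01)


class TestMergeCallerCalls:
    def _matrix(self, depths):
        targets = make_targets(len(depths), chrom="chr2", start=0, length=100, gap=0)
        return DepthMatrix(["ch"], targets, [depths], state=NORMALIZED), targets

    def test_identical_duplicates_merge_with_caller_union(self):
        m, t = self._matrix([1.0] * 10)
        a = _call(t[2].start, t[4].end, callers=("A",))
        b = _call(t[2].start, t[4].end, callers=("B",))
        out = merge_caller_calls([a, b], m)
        assert len(out) == 1
        assert out[0].callers == frozenset({"A", "B"})
        assert (out[0].start, out[0].end) == (a.start, a.end)

    def test_breakpoints_resolved_by_depth_contrast(self):
        # true deletion signal (depth 0.5) on targets 3-5 only; candidate
        # calls span 1-5 and 3-8; the union of breakpoints contains the
        # boundaries of the true event, and the contrast score picks them
        depths = np.ones(10)
        depths[3:6] = 0.5
        m, t = self._matrix(list(depths))
        a = _call(t[1].start, t[5].end, callers=("A",))
        b = _call(t[3].start, t[8].end, callers=("B",))
        out = merge_caller_calls([a, b], m)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (t[3].start, t[5].end)
        assert out[0].num_targets == 3

    def test_merged_interval_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        depths = 1.0 + 0.05 * rng.standard_normal(12)
        depths[4:8] = 0.5
        m, t = self._matrix(list(depths))
        a = _call(t[2].start, t[7].end, callers=("A",))
        b = _call(t[4].start, t[9].end, callers=("B",))
        out = merge_caller_calls([a, b], m)

        # brute force over all breakpoint pairs with the same scoring rule
        bps = sorted({a.start, a.end, b.start, b.end})
        best, best_iv = -np.inf, None
        for i, s in enumerate(bps):
            for e in bps[i + 1:]:
                inside = [k for k in range(12) if t[k].start < e and t[k].end > s]
                if not inside:
                    continue
                w = min(len(inside), 5)
                flank = list(range(max(0, inside[0] - w), inside[0])) + list(
                    range(inside[-1] + 1, min(12, inside[-1] + 1 + w))
                )
                score = abs(depths[inside].mean() - 1) - (
                    abs(depths[flank].mean() - 1) if flank else 0
                )
                if score > best + 1e-12:
                    best, best_iv = score, (s, e)
        assert (out[0].start, out[0].end) == best_iv

    def test_del_and_dup_never_merge(self):
        m, t = self._matrix([1.0] * 10)
        dele = _call(t[2].start, t[5].end, cnv_type="DEL", callers=("A",))
        dup = _call(t[3].start, t[6].end, cnv_type="DUP", callers=("B",))
        out = merge_caller_calls([dele, dup], m)
        assert len(out) == 2
        assert {c.cnv_type for c in out} == {"DEL", "DUP"}

    def test_non_overlapping_calls_stay_separate(self):
        m, t = self._matrix([1.0] * 10)
        a = _call(t[0].start, t[2].end, callers=("A",))
        b = _call(t[5].start, t[7].end, callers=("B",))
        assert len(merge_caller_calls([a, b], m)) == 2


class TestLabelTrioCalls:
    HIGH = {"father": RegionScores(default=95.0), "mother": RegionScores(default=95.0)}

    def test_inherited_deletion_labeled_rare_del(self):
        child = _call(1000, 3000, cnv_type="DEL")
        father = _call(1200, 3000, sample="fa", cnv_type="DEL")  # 90% overlap
        out = label_trio_calls([child], [father], [], self.HIGH)
        assert len(out) == 1
        assert out[0].label == RARE_DEL
        assert out[0].evidence == "inherited-from-father"

    def test_child_only_high_nq_single_caller_is_artifact(self):
        child = _call(1000, 3000, cnv_type="DUP", callers=("xhmm",))
        nq = {"father": RegionScores(default=90.0), "mother": RegionScores(default=85.0)}
        out = label_trio_calls([child], [], [], nq, nq_threshold=60)
        assert out[0].label == ARTIFACT

    def test_multi_caller_mendelian_error_excluded(self):
        child = _call(1000, 3000, callers=("xhmm", "canoes"))
        assert label_trio_calls([child], [], [], self.HIGH) == []

    def test_low_parental_nq_excluded_as_possible_false_negative(self):
        child = _call(1000, 3000)
        nq = {
            "father": RegionScores([("chr2", 500, 5000, 10.0)], default=95.0),
            "mother": RegionScores(default=95.0),
        }
        assert label_trio_calls([child], [], [], nq) == []

    def test_partial_overlap_below_threshold_is_ambiguous(self):
        child = _call(1000, 3000)
        father = _call(2800, 5000, sample="fa")  # 10% of child length
        assert label_trio_calls([child], [father], [], self.HIGH) == []

    def test_overlap_exactly_at_threshold_counts_as_inherited(self):
        child = _call(1000, 3000)
        mother = _call(2000, 4000, sample="mo")  # exactly 50%
        out = label_trio_calls([child], [], [mother], self.HIGH)
        assert out[0].label == RARE_DEL
        assert out[0].evidence == "inherited-from-mother"

    def test_labels_partition_no_call_gets_two_labels(self):
        calls = [
            _call(1000, 3000, cnv_type="DEL"),
            _call(50_000, 60_000, cnv_type="DUP", callers=("canoes",)),
        ]
        father = [_call(1000, 3000, sample="fa", cnv_type="DEL")]
        out = label_trio_calls(calls, father, [], self.HIGH)
        assert [l.label for l in out] == [RARE_DEL, ARTIFACT]
        assert len({l.call.key for l in out}) == len(out)


class TestPedigree:
    def test_ped_roundtrip(self, tmp_path):
        ped = Pedigree(trios=[("ch1", "fa1", "mo1"), ("ch2", "fa2", "mo2")])
        path = tmp_path / "cohort.ped"
        ped.to_ped(str(path))
        loaded = Pedigree.from_ped(str(path))
        assert loaded.trios == ped.trios
        assert loaded.family_members("ch1") == {"fa1", "mo1"}
        assert loaded.parents("ch2") == ("fa2", "mo2")

    def test_duplicate_child_rejected(self):
        with pytest.raises(ValidationError):
            Pedigree(trios=[("c", "f", "m"), ("c", "f2", "m2")])


class TestSplitDataset:
    def _labeled(self, n):
        return [
            LabeledCNV(_call(1000 + 10_000 * i, 3000 + 10_000 * i, sample=f"s{i}"), RARE_DEL)
            for i in range(n)
        ]

    def test_sizes_with_remainder_to_train(self):
        train, val, test = split_dataset(self._labeled(10), seed=1)
        assert (len(train), len(val), len(test)) == (6, 2, 2)
        train, val, test = split_dataset(self._labeled(11), seed=1)
        assert (len(train), len(val), len(test)) == (7, 2, 2)

    def test_disjoint_and_exhaustive(self):
        items = self._labeled(17)
        train, val, test = split_dataset(items, seed=3)
        keys = [l.call.key for part in (train, val, test) for l in part]
        assert sorted(keys) == sorted(l.call.key for l in items)
        assert len(set(keys)) == len(keys)

    def test_same_seed_reproducible_and_order_independent(self):
        items = self._labeled(12)
        a = split_dataset(items, seed=7)
        b = split_dataset(list(reversed(items)), seed=7)
        for pa, pb in zip(a, b):
            assert {l.call.key for l in pa} == {l.call.key for l in pb}
        c = split_dataset(items, seed=8)
        assert any(
            {l.call.key for l in pa} != {l.call.key for l in pc}
            for pa, pc in zip(a, c)
        )

    def test_too_few_items_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset(self._labeled(2))
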