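"""WGS-support rule, precision/recall protocol and classification metrics."""

import numpy as np
import pytest

from cnvconfirm.calls import CNVCall
from cnvconfirm.errors import ValidationError
from cnvconfirm.evaluation import (
    StandardSet,
    classification_metrics,
    precision_recall_vs_wgs,
    wgs_supported,
)
from cnvconfirm.model import PredictionRecord
from cnvconfirm.trio_labeling import ARTIFACT, RARE_DEL, RARE_DUP


def _call(start, end, sample="s1", chrom="chr1", cnv_type="DEL", **kw):
    kw.setdefault("num_targets", 2)
    return CNVCall(sample, chrom, start, end, cnv_type, **kw)


def _std(intervals, sample="s1"):
    return StandardSet({sample: intervals})


class TestWgsSupported:
    def test_exactly_half_overlap_is_supported(self):
        call = _call(100, 200)
        assert wgs_supported(call, _std([("chr1", 150, 300, "DEL")]))

    def test_just_below_half_is_unsupported(self):
        call = _call(100, 200)
        assert not wgs_supported(call, _std([("chr1", 151, 300, "DEL")]))

    def test_call_nested_in_larger_standard_interval(self):
        call = _call(100, 200)
        assert wgs_supported(call, _std([("chr1", 0, 10_000, "DEL")]))

    def test_type_must_match(self):
        call = _call(100, 200, cnv_type="DUP")
        assert not wgs_supported(call, _std([("chr1", 0, 10_000, "DEL")]))

    def test_fragmented_standard_accumulates_unless_single_interval(self):
        call = _call(100, 200)
        std = _std([("chr1", 100, 140, "DEL"), ("chr1", 160, 200, "DEL")])
        assert wgs_supported(call, std)  # 80 bp of 100 across two pieces
        assert not wgs_supported(call, std, single_interval=True)

    def test_absent_sample_is_unsupported(self):
        assert not wgs_supported(_call(100, 200, sample="ghost"), _std([]))

    def test_monotone_in_min_fraction(self):
        call = _call(100, 200)
        std = _std([("chr1", 130, 300, "DEL")])  # 70% coverage
        assert wgs_supported(call, std, min_fraction=0.7)
        assert wgs_supported(call, std, min_fraction=0.5)
        assert not wgs_supported(call, std, min_fraction=0.75)

    def test_agrees_with_brute_force_coverage_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(50, 2000))
            call = _call(s, e)
            ivs = []
            for _k in range(rng.integers(0, 4)):
                a = int(rng.integers(0, 11_000))
                ivs.append(("chr1", a, a + int(rng.integers(10, 3000)), "DEL"))
            std = _std(ivs)
            # oracle: per-base coverage count
            base = np.zeros(e - s, dtype=bool)
            for _c, a, b, _t in ivs:
                lo, hi = max(a, s), min(b, e)
                if hi > lo:
                    base[lo - s : hi - s] = True
            assert wgs_supported(call, std) == (base.sum() >= 0.5 * (e - s))


class TestPrecisionRecallVsWgs:
    def test_precision_counts_supported_fraction(self):
        std = _std([("chr1", 0, 1000, "DEL"), ("chr1", 5000, 6000, "DEL")])
        calls = {
            "xhmm": [_call(0, 800), _call(5000, 5800), _call(20_000, 21_000)]
        }
        df = precision_recall_vs_wgs(calls, {"xhmm": calls["xhmm"]}, std)
        before = df[df.stage == "before"].iloc[0]
        assert before.precision == pytest.approx(2 / 3)
        assert before.recall == pytest.approx(1.0)

    def test_ideal_filter_gives_precision_one_and_keeps_recall(self):
        std = _std([("chr1", 0, 1000, "DEL"), ("chr1", 5000, 6000, "DEL")])
        all_calls = [_call(0, 800), _call(5000, 5800), _call(20_000, 21_000)]
        confirmed = [c for c in all_calls if wgs_supported(c, std)]
        df = precision_recall_vs_wgs({"x": all_calls}, {"x": confirmed}, std)
        before = df[df.stage == "before"].iloc[0]
        after = df[df.stage == "after"].iloc[0]
        assert after.precision == pytest.approx(1.0)
        assert after.recall == pytest.approx(before.recall)

    def test_recall_denominator_is_deduplicated_union_across_callers(self):
        # two callers with partially overlapping supported calls; a brute
        # force merge of supported intervals defines the denominator
        std = _std([("chr1", 0, 10_000, "DEL"), ("chr1", 50_000, 60_000, "DEL"),
                    ("chr1", 90_000, 95_000, "DEL")])
        calls = {
            "A": [_call(0, 4000), _call(3000, 8000), _call(50_000, 55_000),
                  _call(200_000, 201_000)],
            "B": [_call(2000, 6000), _call(90_000, 94_000), _call(300_000, 301_000)],
        }
        df = precision_recall_vs_wgs(calls, {k: [] for k in calls}, std)
        # supported calls: A has 3 (two merge into one unit), B has 2 ->
        # units: [0-8000], [50k-55k], [90k-94k] = 3 units
        a = df[(df.caller == "A") & (df.stage == "before")].iloc[0]
        b = df[(df.caller == "B") & (df.stage == "before")].iloc[0]
        assert a.recall == pytest.approx(2 / 3)
        assert b.recall == pytest.approx(2 / 3)
        assert a.precision == pytest.approx(3 / 4)
        assert b.precision == pytest.approx(2 / 3)

    def test_empty_call_set_reports_nan_precision(self):
        std = _std([("chr1", 0, 1000, "DEL")])
        df = precision_recall_vs_wgs({"x": []}, {"x": []}, std)
        assert np.isnan(df.iloc[0].precision)

    def test_confirmed_must_be_subset(self):
        std = _std([("chr1", 0, 1000, "DEL")])
        with pytest.raises(ValidationError):
            precision_recall_vs_wgs(
                {"x": [_call(0, 800)]}, {"x": [_call(5000, 5800)]}, std
            )


def _record(label, probs):
    return PredictionRecord("ref", tuple(probs), label, max(probs))


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        truth = [RARE_DEL, RARE_DUP, ARTIFACT] * 3
        preds = [
            _record(t, {RARE_DEL: (0.8, 0.1, 0.1), RARE_DUP: (0.1, 0.8, 0.1),
                        ARTIFACT: (0.1, 0.1, 0.8)}[t])
            for t in truth
        ]
        rep = classification_metrics(preds, truth)
        assert rep.macro["accuracy"] == 1.0
        assert all(v["precision"] == 1.0 and v["recall"] == 1.0 and v["f1"] == 1.0
                   for v in rep.per_class.values())
        assert np.array_equal(rep.confusion, 3 * np.eye(3, dtype=int))

    def test_single_class_predictor_on_balanced_truth(self):
        truth = [RARE_DEL, RARE_DUP, ARTIFACT] * 2
        preds = [_record(RARE_DEL, (0.9, 0.05, 0.05))] * 6
        rep = classification_metrics(preds, truth)
        assert rep.per_class[RARE_DEL]["recall"] == 1.0
        assert rep.per_class[RARE_DUP]["recall"] == 0.0
        assert rep.per_class[ARTIFACT]["recall"] == 0.0

    def test_hand_computed_confusion_and_metrics(self):
        # 6 items: one DEL->DUP error, one DUP->ARTIFACT, one ARTIFACT->DEL
        truth = [RARE_DEL, RARE_DEL, RARE_DUP, RARE_DUP, ARTIFACT, ARTIFACT]
        pred_labels = [RARE_DEL, RARE_DUP, RARE_DUP, ARTIFACT, ARTIFACT, RARE_DEL]
        probmap = {RARE_DEL: (0.7, 0.2, 0.1), RARE_DUP: (0.2, 0.7, 0.1),
                   ARTIFACT: (0.1, 0.2, 0.7)}
        preds = [_record(p, probmap[p]) for p in pred_labels]
        rep = classification_metrics(preds, truth)
        assert np.array_equal(
            rep.confusion, np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        )
        # every class: precision 1/2, recall 1/2
        for v in rep.per_class.values():
            assert v["precision"] == pytest.approx(0.5)
            assert v["recall"] == pytest.approx(0.5)
            assert v["f1"] == pytest.approx(0.5)
        assert rep.macro["accuracy"] == pytest.approx(0.5)

    def test_confusion_conserves_n(self):
        rng = np.random.default_rng(5)
        classes = [RARE_DEL, RARE_DUP, ARTIFACT]
        truth = [classes[i] for i in rng.integers(0, 3, size=40)]
        preds = []
        for _ in truth:
            p = rng.dirichlet([1, 1, 1])
            preds.append(_record(classes[int(np.argmax(p))], tuple(p)))
        rep = classification_metrics(preds, truth)
        assert rep.confusion.sum() == 40
        for i, cls in enumerate(classes):
            assert rep.confusion[i].sum() == truth.count(cls)

    def test_absent_class_auc_is_nan(self):
        truth = [RARE_DEL, RARE_DUP] * 3
        preds = [_record(t, (0.6, 0.3, 0.1) if t == RARE_DEL else (0.3, 0.6, 0.1))
                 for t in truth]
        rep = classification_metrics(preds, truth)
        assert np.isnan(rep.per_class[ARTIFACT]["auc"])
        assert rep.per_class[RARE_DEL]["auc"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics([], [RARE_DEL])


def test_standard_set_deduplication_merges_same_type_overlaps():
    std = StandardSet({
        "s1": [("chr1", 0, 1000, "DEL"), ("chr1", 500, 2000, "DEL"),
               ("chr1", 500, 2000, "DUP")]
    })
    dd = std.deduplicated()
    assert ("chr1", 0, 2000, "DEL") in dd.intervals["s1"]
    assert ("chr1", 500, 2000, "DUP") in dd.intervals["s1"]
    assert len(dd.intervals["s1"]) == 2


def test_standard_set_tsv_roundtrip(tmp_path):
    std = StandardSet({"s1": [("chr1", 100, 900, "DEL")],
                       "s2": [("chr2", 5, 50, "DUP")]})
    p = tmp_path / "std.tsv"
    std.to_tsv(str(p))
    loaded = StandardSet.from_tsv(str(p))
    assert loaded.intervals == std.intervals


def test_standard_set_from_vcf(tmp_path):
    vcf = tmp_path / "std.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=chr1,length=248956422>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "chr1\t1001\tdel1\tN\t<DEL>\t50\tPASS\tSVTYPE=DEL;END=2000\tGT\t0/1\t0/0\n"
        "chr1\t5001\tdup1\tN\t<DUP>\t50\tPASS\tSVTYPE=DUP;END=7000\tGT\t0/0\t1/1\n"
    )
    std = StandardSet.from_vcf(str(vcf))
    assert std.intervals["s1"] == [("chr1", 1000, 2000, "DEL")]
    assert std.intervals["s2"] == [("chr1", 5000, 7000, "DUP")]
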