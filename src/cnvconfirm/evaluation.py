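"""Scoring predictions against labels and against a WGS-derived standard set.

WGS covers the genome evenly, so high-confidence CNVs called from WGS data
of the same individuals (the union of two complementary WGS callers) serve
as proxy ground truth for exome calls.  An exome call counts as supported
when at least 50% of its length is covered by same-type standard intervals
of the same sample.  Precision is computed per caller (supported / all);
the recall denominator is the deduplicated union, across all callers, of
supported exome calls — the method confirms calls, it cannot create new
ones, so recall is measured against what exome calling recovered at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from ._genome import covered_length, merge_intervals
from .calls import CNVCall
from .errors import ValidationError
from .model import PredictionRecord
from .trio_labeling import CLASS_ORDER

logger = logging.getLogger(__name__)


@dataclass
class StandardSet:
    """Per-sample WGS CNV intervals: {sample: [(chrom, start, end, type)]}."""

    intervals: dict[str, list[tuple[str, int, int, str]]]
    source: str = "union"

    def __post_init__(self) -> None:
        for sample, ivs in self.intervals.items():
            for chrom, s, e, t in ivs:
                if e <= s:
                    raise ValidationError(
                        f"invalid standard interval {sample} {chrom}:{s}-{e}"
                    )
                if t not in ("DEL", "DUP"):
                    raise ValidationError(f"unknown standard CNV type {t!r}")

    def same_type_intervals(
        self, sample: str, chrom: str, cnv_type: str
    ) -> list[tuple[int, int]]:
        return [
            (s, e)
            for (c, s, e, t) in self.intervals.get(sample, [])
            if c == chrom and t == cnv_type
        ]

    def deduplicated(self) -> "StandardSet":
        """Merge same-type overlapping intervals within each sample."""
        out: dict[str, list[tuple[str, int, int, str]]] = {}
        for sample, ivs in self.intervals.items():
            merged: list[tuple[str, int, int, str]] = []
            keys = {(c, t) for (c, _s, _e, t) in ivs}
            for chrom, t in sorted(keys):
                for s, e in merge_intervals(
                    (s, e) for (c, s, e, tt) in ivs if c == chrom and tt == t
                ):
                    merged.append((chrom, s, e, t))
            out[sample] = merged
        return StandardSet(out, source=self.source)

    @classmethod
    def from_tsv(cls, path: str, source: str = "union") -> "StandardSet":
        df = pd.read_csv(path, sep="\t")
        required = {"sample", "chrom", "start", "end", "type"}
        if not required <= set(df.columns):
            raise ValidationError(f"{path}: needs columns {sorted(required)}")
        intervals: dict[str, list[tuple[str, int, int, str]]] = {}
        for row in df.itertuples():
            intervals.setdefault(row.sample, []).append(
                (str(row.chrom), int(row.start), int(row.end), str(row.type))
            )
        return cls(intervals, source=source)

    @classmethod
    def from_vcf(cls, path: str, source: str = "union") -> "StandardSet":
        """Read DEL/DUP records with SVTYPE/END INFO fields; carriers are the
        samples with a non-reference genotype."""
        from cyvcf2 import VCF

        vcf = VCF(path)
        samples = vcf.samples
        intervals: dict[str, list[tuple[str, int, int, str]]] = {}
        for variant in vcf:
            svtype = variant.INFO.get("SVTYPE")
            if svtype not in ("DEL", "DUP"):
                continue
            end = variant.INFO.get("END", variant.end)
            for i, gt in enumerate(variant.gt_types):
                if gt in (1, 3):  # het or hom-alt
                    intervals.setdefault(samples[i], []).append(
                        (variant.CHROM, variant.start, int(end), svtype)
                    )
        return cls(intervals, source=source)

    def to_tsv(self, path: str) -> None:
        rows = [
            {"sample": s, "chrom": c, "start": st, "end": e, "type": t}
            for s, ivs in sorted(self.intervals.items())
            for (c, st, e, t) in ivs
        ]
        pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "type"]).to_csv(
            path, sep="\t", index=False
        )


def wgs_supported(
    call: CNVCall,
    standard: StandardSet,
    min_fraction: float = 0.5,
    single_interval: bool = False,
) -> bool:
    """True iff >= ``min_fraction`` of the call's length has same-type WGS
    support (inclusive boundary: exactly 50% counts).

    By default coverage accumulates over the merged union of same-type
    standard intervals, so a WGS call fragmented into pieces still supports
    the exome call; ``single_interval=True`` requires a single standard
    interval to provide the coverage on its own.
    """
    if call.sample_id not in standard.intervals:
        logger.warning("sample %s absent from standard set", call.sample_id)
        return False
    ivs = standard.same_type_intervals(call.sample_id, call.chrom, call.cnv_type)
    if not ivs:
        return False
    if single_interval:
        cov = max(min(call.end, e) - max(call.start, s) for s, e in ivs)
        cov = max(cov, 0)
    else:
        cov = covered_length(call.start, call.end, ivs)
    return cov >= min_fraction * call.length


def _supported_units(
    calls_by_caller: dict[str, list[CNVCall]],
    standard: StandardSet,
    min_fraction: float,
    single_interval: bool,
) -> dict[tuple[str, str, str], list[tuple[int, int]]]:
    """Recall denominator: merged union over all callers of supported calls,
    grouped by (sample, chrom, type)."""
    pooled: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for calls in calls_by_caller.values():
        for c in calls:
            if wgs_supported(c, standard, min_fraction, single_interval):
                pooled.setdefault((c.sample_id, c.chrom, c.cnv_type), []).append(
                    (c.start, c.end)
                )
    return {k: merge_intervals(v) for k, v in pooled.items()}


def _recall_against_units(
    calls: list[CNVCall],
    units: dict[tuple[str, str, str], list[tuple[int, int]]],
    standard: StandardSet,
    min_fraction: float,
    single_interval: bool,
) -> float:
    total = sum(len(v) for v in units.values())
    if total == 0:
        return float("nan")
    supported = [c for c in calls if wgs_supported(c, standard, min_fraction, single_interval)]
    recovered = 0
    for (sample, chrom, t), ivs in units.items():
        for s, e in ivs:
            if any(
                c.sample_id == sample
                and c.chrom == chrom
                and c.cnv_type == t
                and c.start < e
                and c.end > s
                for c in supported
            ):
                recovered += 1
    return recovered / total


def precision_recall_vs_wgs(
    calls_by_caller: dict[str, list[CNVCall]],
    confirmed_by_caller: dict[str, list[CNVCall]],
    standard: StandardSet,
    min_fraction: float = 0.5,
    single_interval: bool = False,
) -> pd.DataFrame:
    """Per-caller precision/recall/F1 before and after in silico confirmation.

    ``confirmed_by_caller`` holds the subset of each caller's calls the
    classifier kept.  Precision = supported / all within the set; recall uses
    one shared denominator — the deduplicated union over ALL callers of
    WGS-supported calls (built from the *before* sets).
    """
    for caller, confirmed in confirmed_by_caller.items():
        before_keys = {c.key for c in calls_by_caller.get(caller, [])}
        if not {c.key for c in confirmed} <= before_keys:
            raise ValidationError(f"confirmed calls of {caller!r} not a subset")
    units = _supported_units(calls_by_caller, standard, min_fraction, single_interval)
    rows = []
    for caller in sorted(calls_by_caller):
        for stage, calls in (
            ("before", calls_by_caller[caller]),
            ("after", confirmed_by_caller.get(caller, [])),
        ):
            n = len(calls)
            n_sup = sum(
                wgs_supported(c, standard, min_fraction, single_interval) for c in calls
            )
            precision = n_sup / n if n else float("nan")
            recall = _recall_against_units(
                calls, units, standard, min_fraction, single_interval
            )
            if precision + recall > 0:
                f1 = 2 * precision * recall / (precision + recall)
            else:
                f1 = 0.0 if n else float("nan")
            rows.append(
                {
                    "caller": caller,
                    "stage": stage,
                    "n_calls": n,
                    "n_supported": n_sup,
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Per-class and macro precision/recall/F1/AUC plus the confusion matrix."""

    class_order: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))

    def to_json_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "per_class": self.per_class,
            "macro": self.macro,
            "confusion": self.confusion.tolist(),
        }


def classification_metrics(
    predictions: list[PredictionRecord],
    truth: list[str],
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> MetricsReport:
    """Three-class metrics from prediction records and true labels.

    AUC is one-vs-rest per class from the stored probabilities; a class never
    present in the truth gets ``nan`` there.  Rows of the confusion matrix
    are true classes, columns predicted.
    """
    if len(predictions) != len(truth):
        raise ValidationError("predictions and truth differ in length")
    y_true = np.array([class_order.index(t) for t in truth])
    y_pred = np.array([class_order.index(p.predicted_label) for p in predictions])
    probs = np.array([p.probabilities for p in predictions])

    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=range(len(class_order)), zero_division=0
    )
    confusion = _sk_confusion(y_true, y_pred, labels=range(len(class_order)))

    per_class: dict[str, dict[str, float]] = {}
    aucs = []
    for i, cls in enumerate(class_order):
        mask = y_true == i
        if mask.any() and not mask.all():
            auc = float(roc_auc_score(mask.astype(int), probs[:, i]))
        else:
            auc = float("nan")
        aucs.append(auc)
        per_class[cls] = {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "auc": auc,
        }
    macro = {
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
        "auc": float(np.nanmean(aucs)) if not all(np.isnan(aucs)) else float("nan"),
        "accuracy": float((y_true == y_pred).mean()),
    }
    return MetricsReport(tuple(class_order), per_class, macro, confusion)
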