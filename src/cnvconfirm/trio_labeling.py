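"""Training-label construction from offspring-parents trios.

Large-scale experimental confirmation of training CNVs is impractical, so
labels come from Mendelian inheritance: a child call also present in a
parent is almost certainly a real rare deletion/duplication, while a call
present only in the child is a Mendelian error — mostly a false positive in
the child, provided parental false negatives are ruled out (both parents'
NQ, the Phred-scaled no-CNV score, above a stringent threshold) and the call
was not corroborated by multiple callers (multi-caller Mendelian errors are
likely real, often true de novo events, and are excluded from training).

Candidate-level filters applied before labeling keep the problem in the
regime the classifier is built for: rare (cohort frequency <= 1%),
multi-target (>= 2 capture targets), autosomal calls mostly outside
segmental duplications (<= 75% of the call length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._genome import covered_length, is_autosome, validate_chrom
from .calls import CNVCall
from .depthio import NORMALIZED, DepthMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

RARE_DEL = "RARE_DEL"
RARE_DUP = "RARE_DUP"
ARTIFACT = "ARTIFACT"
CLASS_ORDER = (RARE_DEL, RARE_DUP, ARTIFACT)

_TYPE_TO_LABEL = {"DEL": RARE_DEL, "DUP": RARE_DUP}


@dataclass
class Pedigree:
    """Trio structure of the cohort: (child, father, mother) triples."""

    trios: list[tuple[str, str, str]]
    sample_sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_children: set[str] = set()
        for child, father, mother in self.trios:
            if len({child, father, mother}) != 3:
                raise ValidationError(f"trio members not distinct: {child}")
            if child in seen_children:
                raise ValidationError(f"child {child} appears in two trios")
            seen_children.add(child)

    @classmethod
    def from_ped(cls, path: str) -> "Pedigree":
        """Read a 6-column PED file; rows with both parents set define trios."""
        trios, sex = [], {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 6:
                    raise ValidationError(f"{path}: expected 6 PED columns")
                _fam, sid, father, mother, s, _pheno = parts[:6]
                sex[sid] = s
                if father != "0" and mother != "0":
                    trios.append((sid, father, mother))
        return cls(trios=trios, sample_sex=sex)

    def to_ped(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, (child, father, mother) in enumerate(self.trios, 1):
                fam = f"fam{i}"
                fh.write(f"{fam}\t{father}\t0\t0\t1\t1\n")
                fh.write(f"{fam}\t{mother}\t0\t0\t2\t1\n")
                fh.write(f"{fam}\t{child}\t{father}\t{mother}\t0\t2\n")

    def parents(self, child: str) -> tuple[str, str] | None:
        for c, f, m in self.trios:
            if c == child:
                return f, m
        return None

    def family_members(self, sample: str) -> set[str]:
        """All samples sharing a trio with ``sample`` (excluding itself)."""
        members: set[str] = set()
        for trio in self.trios:
            if sample in trio:
                members.update(trio)
        members.discard(sample)
        return members


@dataclass
class LabeledCNV:
    call: CNVCall
    label: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValidationError(f"unknown label {self.label!r}")
        if self.label in (RARE_DEL, RARE_DUP):
            if _TYPE_TO_LABEL[self.call.cnv_type] != self.label:
                raise ValidationError(
                    f"label {self.label} inconsistent with type {self.call.cnv_type}"
                )


class RegionScores:
    """Interval-indexed quality scores for one sample (used for parental NQ).

    A query returns the minimum score over intervals overlapping the region,
    or ``default`` when nothing overlaps — i.e. absence of any low-confidence
    interval counts as confident.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int, float]] = (),
        default: float = 99.0,
    ) -> None:
        self.default = float(default)
        self._by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in intervals:
            self._by_chrom.setdefault(chrom, []).append((start, end, float(score)))

    def score(self, chrom: str, start: int, end: int) -> float:
        hits = [
            s
            for (s0, e0, s) in self._by_chrom.get(chrom, [])
            if s0 < end and e0 > start
        ]
        return min(hits) if hits else self.default


def compute_cohort_frequency(
    calls: Sequence[CNVCall], cohort_size: int, overlap_fraction: float = 0.5
) -> list[CNVCall]:
    """Populate cohort_frequency: fraction of samples with a same-type call
    covering >= ``overlap_fraction`` of the candidate."""
    if cohort_size < 1:
        raise ValidationError("cohort_size must be >= 1")
    out = []
    for c in calls:
        carriers = {
            o.sample_id
            for o in calls
            if o.cnv_type == c.cnv_type
            and o.chrom == c.chrom
            and min(o.end, c.end) - max(o.start, c.start) >= overlap_fraction * c.length
        }
        out.append(c.with_(cohort_frequency=min(1.0, len(carriers) / cohort_size)))
    return out


def filter_candidate_calls(
    calls: Sequence[CNVCall],
    segdups: Sequence[tuple[str, int, int]] = (),
    max_frequency: float = 0.01,
    min_targets: int = 2,
    max_segdup_fraction: float = 0.75,
) -> list[CNVCall]:
    """Keep rare (<= 1%), multi-target, autosomal calls mostly outside
    segmental duplications.  Order preserved; idempotent."""
    segdup_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in segdups:
        validate_chrom(chrom)
        segdup_by_chrom.setdefault(chrom, []).append((s, e))

    kept = []
    for c in calls:
        validate_chrom(c.chrom)
        if c.cohort_frequency > max_frequency:
            continue
        if c.num_targets < min_targets:
            continue
        if not is_autosome(c.chrom):
            continue
        cov = covered_length(c.start, c.end, segdup_by_chrom.get(c.chrom, []))
        if cov / c.length > max_segdup_fraction:
            continue
        kept.append(c)
    return kept


def _group_overlapping(calls: list[CNVCall]) -> list[list[CNVCall]]:
    """Chain-group overlapping calls (already same sample/chrom/type)."""
    calls = sorted(calls, key=lambda c: (c.start, c.end))
    groups: list[list[CNVCall]] = []
    for c in calls:
        if groups and c.start < max(m.end for m in groups[-1]):
            groups[-1].append(c)
        else:
            groups.append([c])
    return groups


def _contrast_score(
    row: np.ndarray, inside: np.ndarray, flank: np.ndarray
) -> float:
    """|mean inside-depth - 1| - |mean flank-depth - 1| on normalized depth."""
    inside_term = abs(float(row[inside].mean()) - 1.0)
    flank_term = abs(float(row[flank].mean()) - 1.0) if flank.size else 0.0
    return inside_term - flank_term


def merge_caller_calls(
    calls: Sequence[CNVCall],
    matrix: DepthMatrix,
    flank_cap: int = 5,
) -> list[CNVCall]:
    """Merge overlapping same-sample same-type calls from different callers.

    Within a group the candidate breakpoints are the union of the member
    calls' breakpoints; the chosen interval maximizes the read-depth contrast
    score (|mean inside - 1| - |mean flank - 1|, flank = up to ``flank_cap``
    targets per side) on the carrier's normalized depth.  Caller sets are
    unioned.  DEL and DUP never merge.
    """
    if matrix.state != NORMALIZED:
        raise ValidationError("merge_caller_calls expects a normalized matrix")
    tchrom: dict[str, list[int]] = {}
    for i, t in enumerate(matrix.targets):
        tchrom.setdefault(t.chrom, []).append(i)

    merged: list[CNVCall] = []
    by_key: dict[tuple[str, str, str], list[CNVCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample_id, c.chrom, c.cnv_type), []).append(c)

    for (sample, chrom, _cnv_type), group_calls in sorted(by_key.items()):
        row = matrix.row(sample)
        idx = np.array(tchrom.get(chrom, []), dtype=int)
        starts = np.array([matrix.targets[i].start for i in idx])
        ends = np.array([matrix.targets[i].end for i in idx])
        for group in _group_overlapping(group_calls):
            if len(group) == 1:
                merged.append(group[0])
                continue
            breakpoints = sorted({c.start for c in group} | {c.end for c in group})
            best: tuple[float, int, int] | None = None
            for ai, s in enumerate(breakpoints):
                for e in breakpoints[ai + 1 :]:
                    inside = idx[(starts < e) & (ends > s)]
                    if inside.size == 0:
                        continue
                    pos_lo = np.searchsorted(idx, inside[0])
                    pos_hi = np.searchsorted(idx, inside[-1])
                    w = min(inside.size, flank_cap)
                    flank = np.concatenate(
                        [idx[max(0, pos_lo - w) : pos_lo], idx[pos_hi + 1 : pos_hi + 1 + w]]
                    )
                    score = _contrast_score(row, inside, flank)
                    if best is None or score > best[0] + 1e-12:
                        best = (score, s, e)
            assert best is not None, "group with no target-overlapping interval"
            _, s, e = best
            n_inside = int(((starts < e) & (ends > s)).sum())
            quality: dict = {}
            for c in group:
                for k, v in c.quality.items():
                    quality[k] = max(quality.get(k, v), v)
            merged.append(
                CNVCall(
                    sample_id=sample,
                    chrom=chrom,
                    start=s,
                    end=e,
                    cnv_type=group[0].cnv_type,
                    callers=frozenset().union(*(c.callers for c in group)),
                    num_targets=max(n_inside, 1),
                    quality=quality,
                    cohort_frequency=max(c.cohort_frequency for c in group),
                )
            )
    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end, c.cnv_type))
    return merged


def _max_overlap_fraction(call: CNVCall, parent_calls: Sequence[CNVCall]) -> float:
    best = 0.0
    for p in parent_calls:
        if p.cnv_type != call.cnv_type or p.chrom != call.chrom:
            continue
        ov = min(p.end, call.end) - max(p.start, call.start)
        best = max(best, ov / call.length)
    return best


def label_trio_calls(
    child_calls: Sequence[CNVCall],
    father_calls: Sequence[CNVCall],
    mother_calls: Sequence[CNVCall],
    parent_nq: dict[str, RegionScores],
    nq_threshold: float = 60.0,
    inheritance_overlap: float = 0.5,
) -> list[LabeledCNV]:
    """Label one trio's filtered, merged child calls.

    * Inherited (same-type parental call covering >= ``inheritance_overlap``
      of the child call) -> RARE_DEL / RARE_DUP.
    * Child-only with zero parental overlap, NQ >= ``nq_threshold`` in BOTH
      parents over the region, and exactly one caller -> ARTIFACT.
    * Everything else (possible de novo, ambiguous partial overlap,
      multi-caller Mendelian errors) is left unlabeled and excluded.

    ``parent_nq`` must carry RegionScores under keys "father" and "mother".
    """
    for key in ("father", "mother"):
        if key not in parent_nq:
            raise ValidationError(f"parent_nq missing {key!r}")
    labeled: list[LabeledCNV] = []
    for call in child_calls:
        ov_f = _max_overlap_fraction(call, father_calls)
        ov_m = _max_overlap_fraction(call, mother_calls)
        if max(ov_f, ov_m) >= inheritance_overlap:
            side = "father" if ov_f >= ov_m else "mother"
            labeled.append(
                LabeledCNV(call, _TYPE_TO_LABEL[call.cnv_type], f"inherited-from-{side}")
            )
        elif ov_f == 0.0 and ov_m == 0.0:
            nq_f = parent_nq["father"].score(call.chrom, call.start, call.end)
            nq_m = parent_nq["mother"].score(call.chrom, call.start, call.end)
            if nq_f >= nq_threshold and nq_m >= nq_threshold and len(call.callers) == 1:
                labeled.append(LabeledCNV(call, ARTIFACT, "mendelian-error-refined"))
        # partial overlap below threshold, low parental NQ or multi-caller
        # Mendelian error: ambiguous, excluded from training
    return labeled


def label_cohort(
    calls_by_sample: dict[str, list[CNVCall]],
    pedigree: Pedigree,
    parent_nq_by_sample: dict[str, RegionScores],
    nq_threshold: float = 60.0,
    inheritance_overlap: float = 0.5,
) -> list[LabeledCNV]:
    """Apply :func:`label_trio_calls` across every trio of the pedigree."""
    labeled: list[LabeledCNV] = []
    for child, father, mother in pedigree.trios:
        if father not in parent_nq_by_sample or mother not in parent_nq_by_sample:
            logger.warning("trio of %s skipped: parent NQ scores missing", child)
            continue
        labeled.extend(
            label_trio_calls(
                calls_by_sample.get(child, []),
                calls_by_sample.get(father, []),
                calls_by_sample.get(mother, []),
                {
                    "father": parent_nq_by_sample[father],
                    "mother": parent_nq_by_sample[mother],
                },
                nq_threshold=nq_threshold,
                inheritance_overlap=inheritance_overlap,
            )
        )
    return labeled


def split_dataset(
    labeled: Sequence[LabeledCNV],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[LabeledCNV], list[LabeledCNV], list[LabeledCNV]]:
    """Random, reproducible train/validation/test partition.

    Items are keyed by the CNV's stable identifier, so membership does not
    depend on input order.  Sizes are floors of the fractions with the
    remainder going to the training split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    if len(labeled) < 3:
        raise ValidationError("need at least 3 labeled items to split")
    items = sorted(labeled, key=lambda lc: lc.call.key)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n = len(items)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    shuffled = [items[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )
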