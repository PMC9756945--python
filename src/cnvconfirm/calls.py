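"""Candidate CNV call records and their TSV dialect.

A call is one candidate interval from an exome read-depth caller, with its
type (DEL/DUP), the set of callers that reported it, the number of capture
targets it spans, caller quality scores (SQ — genotype quality of the call;
NQ — Phred-scaled score that no CNV exists in the region) and its frequency
in the cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

from .errors import ValidationError

DEL = "DEL"
DUP = "DUP"


@dataclass(frozen=True)
class CNVCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    callers: frozenset[str] = frozenset()
    num_targets: int = 1
    quality: dict = field(default_factory=dict, compare=False, hash=False)
    cohort_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"non-positive call interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.cnv_type not in (DEL, DUP):
            raise ValidationError(f"cnv_type must be DEL or DUP, got {self.cnv_type!r}")
        if self.num_targets < 1:
            raise ValidationError("num_targets must be >= 1")
        if not 0.0 <= self.cohort_frequency <= 1.0:
            raise ValidationError("cohort_frequency outside [0, 1]")
        object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        """Stable identifier used for dataset splitting and deduplication."""
        return f"{self.sample_id}|{self.chrom}:{self.start}-{self.end}|{self.cnv_type}"

    def with_(self, **kwargs) -> "CNVCall":
        return replace(self, **kwargs)


_COLUMNS = [
    "sample",
    "chrom",
    "start",
    "end",
    "type",
    "caller",
    "SQ",
    "NQ",
    "num_targets",
    "frequency",
]


def write_calls_tsv(calls: list[CNVCall], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_COLUMNS)
        for c in calls:
            w.writerow(
                [
                    c.sample_id,
                    c.chrom,
                    c.start,
                    c.end,
                    c.cnv_type,
                    ",".join(sorted(c.callers)),
                    c.quality.get("SQ", ""),
                    c.quality.get("NQ", ""),
                    c.num_targets,
                    f"{c.cohort_frequency:.6g}",
                ]
            )


def read_calls_tsv(path: str) -> list[CNVCall]:
    calls: list[CNVCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            quality = {}
            for score in ("SQ", "NQ"):
                if row[score] not in ("", None):
                    quality[score] = float(row[score])
            calls.append(
                CNVCall(
                    sample_id=row["sample"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    cnv_type=row["type"],
                    callers=frozenset(filter(None, row["caller"].split(","))),
                    num_targets=int(row["num_targets"]),
                    quality=quality,
                    cohort_frequency=float(row["frequency"]),
                )
            )
    return calls
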