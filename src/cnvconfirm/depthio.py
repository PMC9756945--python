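"""Per-target read-depth I/O, target splitting and GC/coverage normalization.

The unit of measurement is the exome capture target: a genomic interval with
a GC fraction.  Raw mean depth per target is noisy in two sample-global ways
— GC-content bias and overall sequencing depth — and both are removed here by
a median-based rescaling applied to each sample independently:

    O_t = (RD_t * M / M_x) / M_bar

where ``RD_t`` is the raw depth at target ``t``, ``M_x`` the median depth
over all targets in the same GC bin as ``t``, ``M`` the overall median and
``M_bar`` the overall mean depth of the sample.  A diploid, CNV-free target
thus normalizes to roughly 1, a heterozygous deletion to ~0.5 and a
heterozygous duplication to ~1.5 — the contrast the downstream image encoder
draws.  Local biases (batch effects, target-specific capture efficiency) are
deliberately left in place; they are shared with the reference panel and
cancel visually.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._genome import chrom_sort_key, validate_chrom
from .errors import (
    DegenerateSampleError,
    MissingDataError,
    OrderingError,
    ValidationError,
)

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"


@dataclass(frozen=True)
class CaptureTarget:
    """One exome capture window (0-based, half-open coordinates).

    ``origin_id`` identifies the pre-split target this window derives from;
    windows produced by :func:`split_long_targets` share it with their
    siblings, unsplit targets carry their own id.
    """

    chrom: str
    start: int
    end: int
    gc_fraction: float
    origin_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"non-positive interval {self.chrom}:{self.start}-{self.end}"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValidationError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        if not self.origin_id:
            object.__setattr__(self, "origin_id", self.key)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def _check_sorted(targets: Sequence[CaptureTarget]) -> None:
    for a, b in zip(targets, targets[1:]):
        if (chrom_sort_key(a.chrom), a.start) > (chrom_sort_key(b.chrom), b.start):
            raise OrderingError(
                f"targets not sorted by (chrom, start) at {a.key} -> {b.key}"
            )


def split_long_targets(
    targets: Sequence[CaptureTarget], threshold_bp: int = 1000
) -> list[CaptureTarget]:
    """Replace every target of length >= ``threshold_bp`` by near-equal windows.

    A long target of length L becomes ``n = ceil(L / threshold_bp)`` contiguous
    windows that tile it exactly; window lengths differ by at most 1 bp, with
    the remainder bases given to the leftmost windows.  For the default
    threshold this keeps every window in the 500-1000 bp range, so a CNV
    covering only part of a long capture probe still changes the depth of a
    whole window.  Shorter targets pass through unchanged.
    """
    if threshold_bp < 2:
        raise ValidationError(f"threshold_bp must be >= 2, got {threshold_bp}")
    _check_sorted(targets)
    out: list[CaptureTarget] = []
    for t in targets:
        if t.length < threshold_bp:
            out.append(t)
            continue
        n = math.ceil(t.length / threshold_bp)
        base, rem = divmod(t.length, n)
        pos = t.start
        for i in range(n):
            width = base + (1 if i < rem else 0)
            out.append(
                CaptureTarget(t.chrom, pos, pos + width, t.gc_fraction, origin_id=t.key)
            )
            pos += width
        assert pos == t.end
    return out


def read_targets_bed(
    path: str,
    fasta: str | None = None,
    one_based: bool = False,
) -> list[CaptureTarget]:
    """Read capture targets from BED4+ (chrom, start, end, gc) or BED3 + FASTA.

    With ``one_based=True`` input coordinates are 1-based inclusive and are
    converted to the internal 0-based half-open convention.
    """
    ref = None
    if fasta is not None:
        from pyfaidx import Fasta

        ref = Fasta(fasta)
    targets: list[CaptureTarget] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if one_based:
                start -= 1
            validate_chrom(chrom)
            if len(parts) >= 4:
                gc = float(parts[3])
            elif ref is not None:
                seq = str(ref[chrom][start:end]).upper()
                gc = (seq.count("G") + seq.count("C")) / max(len(seq), 1)
            else:
                raise ValidationError(
                    f"{path}:{lineno}: no GC column and no reference FASTA given"
                )
            targets.append(CaptureTarget(chrom, start, end, gc))
    _check_sorted(targets)
    return targets


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_depth_file(
    path: str, targets: Sequence[CaptureTarget], one_based: bool = False
) -> np.ndarray:
    """Read one sample's per-interval mean depth into target order.

    The file is tab-delimited ``chrom  start  end  depth`` (Mosdepth regions /
    CLAMMS coverage dialect, plain or gzip).  A post-split window takes its
    depth from an exactly matching file row when present, otherwise it
    inherits the depth of its origin (pre-split) interval.  Intervals in the
    file that map to no target are ignored with a warning; a target with
    neither an exact nor an origin row is an error.
    """
    by_interval: dict[str, float] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end, depth = (
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    float(parts[3]),
                )
            except (IndexError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed line: {exc}") from exc
            if one_based:
                start -= 1
            if depth < 0:
                raise ValidationError(f"{path}:{lineno}: negative depth {depth}")
            by_interval[f"{chrom}:{start}-{end}"] = depth

    wanted = {t.key for t in targets} | {t.origin_id for t in targets}
    extra = [k for k in by_interval if k not in wanted]
    if extra:
        logger.warning(
            "%s: %d interval(s) not in the target list ignored (first: %s)",
            path,
            len(extra),
            extra[0],
        )

    row = np.empty(len(targets), dtype=float)
    for i, t in enumerate(targets):
        if t.key in by_interval:
            row[i] = by_interval[t.key]
        elif t.origin_id in by_interval:
            row[i] = by_interval[t.origin_id]
        else:
            raise MissingDataError(f"{path}: no depth for target {t.key}")
    return row


@dataclass
class DepthMatrix:
    """Samples x targets read-depth values, raw or normalized."""

    sample_ids: list[str]
    targets: list[CaptureTarget]
    values: np.ndarray
    state: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.targets)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.targets)})"
            )
        if self.values.size and self.values.min() < 0:
            raise ValidationError("depth values must be non-negative")
        if self.state not in (RAW, NORMALIZED):
            raise ValidationError(f"unknown state {self.state!r}")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.values[self._index[sample_id]]
        except KeyError:
            raise MissingDataError(f"sample {sample_id!r} not in matrix") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def target_index(self) -> dict[str, int]:
        return {t.key: i for i, t in enumerate(self.targets)}

    def to_tsv(self, path: str) -> None:
        """Write as TSV: one header row of target keys, one row per sample."""
        with open(path, "w") as fh:
            cols = "\t".join(
                f"{t.chrom}:{t.start}-{t.end}:{t.gc_fraction:.4f}" for t in self.targets
            )
            fh.write(f"#state={self.state}\nsample\t{cols}\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "DepthMatrix":
        with _open_text(path) as fh:
            state_line = fh.readline().strip()
            state = state_line.split("=", 1)[1] if "=" in state_line else RAW
            header = fh.readline().rstrip("\n").split("\t")[1:]
            targets = []
            for col in header:
                chrom, rest, gc = col.rsplit(":", 2)[0], col.rsplit(":", 2)[1], col.rsplit(":", 2)[2]
                start, end = rest.split("-")
                targets.append(CaptureTarget(chrom, int(start), int(end), float(gc)))
            sample_ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                sample_ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(sample_ids, targets, np.array(rows), state=state)


def build_depth_matrix(
    depth_paths: dict[str, str],
    targets: Sequence[CaptureTarget],
    one_based: bool = False,
) -> DepthMatrix:
    """Assemble a raw DepthMatrix from per-sample depth files."""
    sample_ids = sorted(depth_paths)
    rows = [read_depth_file(depth_paths[s], targets, one_based) for s in sample_ids]
    return DepthMatrix(sample_ids, list(targets), np.vstack(rows), state=RAW)


@dataclass
class GcNormalizationStats:
    """Per-sample medians used by the GC/coverage normalization."""

    per_gc_median: dict[float, float]
    global_median: float
    global_mean: float
    gc_bin_width: float = 0.01
    empty_bins: list[float] = field(default_factory=list)


def gc_bin(gc_fraction: float, width: float) -> float:
    """Left edge of the GC bin containing ``gc_fraction``."""
    return round(math.floor(gc_fraction / width + 1e-9) * width, 10)


def gc_normalize(
    matrix: DepthMatrix, gc_bin_width: float = 0.01
) -> tuple[DepthMatrix, list[GcNormalizationStats]]:
    """Normalize GC bias and overall coverage per sample by the median approach.

    For each sample independently, O_t = (RD_t * M / M_x) / M_bar with M_x the
    median raw depth over targets sharing target t's GC bin, M the overall
    median and M_bar the overall mean.  A GC bin whose median is zero would
    make the ratio undefined; such bins fall back to the global median M
    (ratio 1) with a warning.
    """
    if matrix.state != RAW:
        raise ValidationError("gc_normalize expects a raw matrix")
    if matrix.values.size == 0:
        raise ValidationError("empty depth matrix")
    if not 0 < gc_bin_width <= 1:
        raise ValidationError(f"gc_bin_width {gc_bin_width} outside (0, 1]")

    bins = np.array([gc_bin(t.gc_fraction, gc_bin_width) for t in matrix.targets])
    uniq = np.unique(bins)
    bin_masks = {b: bins == b for b in uniq}

    out = np.empty_like(matrix.values)
    stats: list[GcNormalizationStats] = []
    for i, sid in enumerate(matrix.sample_ids):
        rd = matrix.values[i]
        if not rd.any():
            raise DegenerateSampleError(f"sample {sid!r} has all-zero depth")
        m = float(np.median(rd))
        m_bar = float(np.mean(rd))
        per_gc: dict[float, float] = {}
        empty: list[float] = []
        ratio = np.empty_like(rd)
        for b, mask in bin_masks.items():
            m_x = float(np.median(rd[mask]))
            per_gc[float(b)] = m_x
            if m_x == 0.0:
                empty.append(float(b))
                m_x = m  # ratio 1 fallback; the bin carries no usable signal
            ratio[mask] = m / m_x
        if empty:
            logger.warning(
                "sample %s: %d GC bin(s) with zero median fell back to the "
                "global median",
                sid,
                len(empty),
            )
        out[i] = rd * ratio / m_bar
        stats.append(
            GcNormalizationStats(per_gc, m, m_bar, gc_bin_width, empty_bins=empty)
        )
    normed = DepthMatrix(
        list(matrix.sample_ids), list(matrix.targets), out, state=NORMALIZED
    )
    return normed, stats
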