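"""Chromosome-name handling and interval helpers used across modules."""

from __future__ import annotations

from typing import Iterable

from .errors import ValidationError

_AUTOSOMES = {str(i) for i in range(1, 23)}
_KNOWN = _AUTOSOMES | {"X", "Y", "MT", "M"}


def strip_chr(chrom: str) -> str:
    """Return the chromosome name without a leading ``chr`` prefix."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def validate_chrom(chrom: str) -> str:
    """Validate a chromosome name (1-22, X, Y, MT; with or without ``chr``)."""
    core = strip_chr(chrom).upper()
    if core not in _KNOWN:
        raise ValidationError(f"unknown chromosome name: {chrom!r}")
    return core


def is_autosome(chrom: str) -> bool:
    return strip_chr(chrom).upper() in _AUTOSOMES


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX."""
    core = strip_chr(chrom).upper()
    if core.isdigit():
        return (int(core), "")
    return (1000, core)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly unsorted, possibly overlapping half-open intervals."""
    ivs = sorted((s, e) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def covered_length(start: int, end: int, intervals: Iterable[tuple[int, int]]) -> int:
    """Length of [start, end) covered by the union of ``intervals``."""
    total = 0
    for s, e in merge_intervals(intervals):
        total += max(0, min(end, e) - max(start, s))
    return total
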