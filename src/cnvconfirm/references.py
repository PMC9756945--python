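"""Reference-panel selection by pairwise depth correlation.

A rare CNV only stands out against samples whose genome-wide depth profile
resembles the case everywhere else.  For each case sample we rank all other
samples by the correlation of their normalized depth over autosomal targets
and keep the top k (100 by default).  Family members can be excluded: a rare
inherited CNV present in a parent chosen as reference would erase the very
contrast the image encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from ._genome import is_autosome
from .depthio import NORMALIZED, DepthMatrix
from .errors import MissingDataError, ValidationError


@dataclass
class ReferencePanel:
    """Reference samples for one case, in descending correlation order."""

    case_id: str
    reference_ids: list[str]
    correlations: list[float]

    def __post_init__(self) -> None:
        if self.case_id in self.reference_ids:
            raise ValidationError("case cannot be its own reference")
        if any(b > a + 1e-12 for a, b in zip(self.correlations, self.correlations[1:])):
            raise ValidationError("correlations must be non-increasing")


def select_references(
    matrix: DepthMatrix,
    case_id: str,
    k: int = 100,
    exclude: set[str] | frozenset[str] = frozenset(),
    method: str = "pearson",
) -> ReferencePanel:
    """Pick the up-to-k samples most depth-correlated with the case.

    Correlations are computed over autosomal targets with nonzero variance
    across samples.  The case itself and every member of ``exclude`` are
    never selected.  Ties are broken by sample id so the panel is
    deterministic.
    """
    if matrix.state != NORMALIZED:
        raise ValidationError("select_references expects a normalized matrix")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if case_id not in matrix:
        raise MissingDataError(f"case {case_id!r} not in matrix")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")

    candidates = [
        s for s in matrix.sample_ids if s != case_id and s not in set(exclude)
    ]
    if not candidates:
        raise MissingDataError(f"no candidate references for case {case_id!r}")

    auto = np.array([is_autosome(t.chrom) for t in matrix.targets])
    sub = matrix.values[:, auto]
    usable = auto.copy()
    usable[auto] = sub.std(axis=0) > 0
    if not usable.any():
        raise ValidationError("no autosomal target with nonzero variance")

    case_row = matrix.row(case_id)[usable]
    scored: list[tuple[float, str]] = []
    for s in candidates:
        other = matrix.row(s)[usable]
        if method == "pearson":
            if case_row.std() == 0 or other.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(case_row, other)[0, 1])
        else:
            r = float(_scipy_stats.spearmanr(case_row, other).statistic)
        scored.append((r, s))
    scored.sort(key=lambda rs: (-rs[0], rs[1]))
    top = scored[:k]
    return ReferencePanel(
        case_id=case_id,
        reference_ids=[s for _, s in top],
        correlations=[r for r, _ in top],
    )
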