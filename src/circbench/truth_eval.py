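"""Truth-label circRNA predictions by RNase-R enrichment and summarize them.

RNase R is a 3'->5' exoribonuclease that digests linear RNAs while covalently
closed circles survive.  A candidate back-splice junction predicted from a
total-RNA library is therefore called *true* when its junction reads are
enriched in a matched RNase-R-treated library:

    E = (m - n) / (m + n)

with ``m`` the junction read count in the RNase-R sample and ``n`` the count
in the total-RNA sample.  ``E > 0`` (strictly) defines a true positive; a
candidate absent from the RNase-R predictions has m = 0 and E = -1.  The
true-positive rate (TPR) is the fraction of *all* total-RNA candidates that
are true -- the denominator is the full prediction set, not just the overlap
with the RNase-R set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .seq_io import CircCandidate, PredictionSet

__all__ = [
    "LabeledCandidate",
    "EvalSummary",
    "UndefinedScoreError",
    "filter_min_junction_reads",
    "enrichment_score",
    "label_candidates",
    "summarize",
    "combine_algorithms",
    "top_k_by_reads",
]


class UndefinedScoreError(ValueError):
    """Raised when the enrichment score is requested for m + n == 0."""


@dataclass(slots=True)
class LabeledCandidate:
    """A total-RNA candidate matched against the RNase-R library.

    ``n`` is the total-RNA junction read count, ``m`` the RNase-R count;
    ``is_true`` caches the strict ``E > 0`` rule.
    """

    chrom: str
    start: int
    end: int
    strand: str
    n: int
    m: int
    E: float
    is_true: bool

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(slots=True)
class EvalSummary:
    n_predicted: int
    n_overlap_with_rnaser: int
    n_true: int

    def __post_init__(self) -> None:
        if not (self.n_true <= self.n_overlap_with_rnaser <= self.n_predicted):
            raise ValueError(
                "expected n_true <= n_overlap_with_rnaser <= n_predicted, got "
                f"{self.n_true}/{self.n_overlap_with_rnaser}/{self.n_predicted}"
            )

    @property
    def tpr(self) -> float:
        """n_true / n_predicted as a fraction; NaN for an empty universe."""
        if self.n_predicted == 0:
            return math.nan
        return self.n_true / self.n_predicted

    @property
    def tpr_percent(self) -> float:
        """TPR as a percentage, rounded half-up to 2 decimals (exact arithmetic)."""
        if self.n_predicted == 0:
            return math.nan
        pct = Decimal(self.n_true * 100) / Decimal(self.n_predicted)
        return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def filter_min_junction_reads(preds: PredictionSet, min_reads: int = 2) -> PredictionSet:
    """Keep candidates with junction_reads >= min_reads (inclusive threshold)."""
    if min_reads < 0:
        raise ValueError(f"min_reads must be >= 0, got {min_reads!r}")
    out = PredictionSet(sample_id=preds.sample_id)
    for cand in preds:
        if cand.junction_reads >= min_reads:
            out.add(
                CircCandidate(
                    cand.chrom, cand.start, cand.end, cand.strand,
                    cand.junction_reads, cand.source,
                )
            )
    return out


def enrichment_score(m: int, n: int) -> float:
    """E = (m - n) / (m + n); antisymmetric in (m, n), bounded in [-1, 1]."""
    if m < 0 or n < 0:
        raise ValueError(f"counts must be non-negative, got m={m}, n={n}")
    if m + n == 0:
        raise UndefinedScoreError("enrichment score undefined for m + n == 0")
    return (m - n) / (m + n)


def label_candidates(
    total: PredictionSet, rnaser: PredictionSet
) -> list[LabeledCandidate]:
    """Label every total-RNA candidate by RNase-R enrichment.

    The evaluation universe is the total-RNA prediction set; candidates seen
    only in the RNase-R library are ignored.  A candidate absent from the
    RNase-R set gets m = 0, hence E = -1 and a false label.  Output is sorted
    by junction key, so downstream summaries are order-independent.
    """
    labeled: list[LabeledCandidate] = []
    for cand in total.sorted_candidates():
        n = cand.junction_reads
        match = rnaser.get(cand.key)
        m = match.junction_reads if match is not None else 0
        if m + n > 0:
            e = enrichment_score(m, n)
        else:
            e = -1.0  # degenerate zero-count candidate; conservatively false
        labeled.append(
            LabeledCandidate(
                cand.chrom, cand.start, cand.end, cand.strand,
                n=n, m=m, E=e, is_true=e > 0,
            )
        )
    return labeled


def summarize(labeled: Iterable[LabeledCandidate]) -> EvalSummary:
    labeled = list(labeled)
    return EvalSummary(
        n_predicted=len(labeled),
        n_overlap_with_rnaser=sum(1 for c in labeled if c.m > 0),
        n_true=sum(1 for c in labeled if c.is_true),
    )


def combine_algorithms(
    sets: Sequence[Iterable[LabeledCandidate]], min_support: int
) -> tuple[list[LabeledCandidate], pd.DataFrame]:
    """Intersect labeled sets from several callers at a support threshold.

    Returns the candidates whose key occurs in at least ``min_support`` of
    the input sets (counts taken from the first set containing the key, by
    input order) together with the full per-key membership table, from which
    every Venn region count can be derived.
    """
    sets = [list(s) for s in sets]
    if not (1 <= min_support <= len(sets)):
        raise ValueError(
            f"min_support must be in [1, {len(sets)}], got {min_support!r}"
        )
    first_seen: dict[tuple[str, int, int], LabeledCandidate] = {}
    membership: dict[tuple[str, int, int], list[bool]] = {}
    for idx, labeled in enumerate(sets):
        for cand in labeled:
            membership.setdefault(cand.key, [False] * len(sets))[idx] = True
            first_seen.setdefault(cand.key, cand)
    table = pd.DataFrame(
        [
            {"chrom": k[0], "start": k[1], "end": k[2]}
            | {f"set_{i}": flag for i, flag in enumerate(flags)}
            | {"support": sum(flags)}
            for k, flags in sorted(membership.items())
        ]
    )
    combined = [
        first_seen[key]
        for key, flags in sorted(membership.items())
        if sum(flags) >= min_support
    ]
    return combined, table


def top_k_by_reads(
    labeled: Iterable[LabeledCandidate], k: int
) -> tuple[list[LabeledCandidate], float]:
    """Re-rank by total-RNA junction reads and keep the top k.

    Sorting is by ``n`` descending with lexicographic key as the
    deterministic tie-break; returns the subset and its TPR.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k!r}")
    ranked = sorted(labeled, key=lambda c: (-c.n, c.key))
    subset = ranked[: min(k, len(ranked))]
    return subset, summarize(subset).tpr
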