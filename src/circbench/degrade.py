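"""Simulate "imperfect" total RNA-Seq from a perfect paired-end library.

Three degradation modes, mirroring how public total-RNA libraries commonly
fall short of a high-quality paired-end reference:

* ``single_end`` -- keep only one mate of every pair (single-end sequencing);
* ``subsample``  -- keep each read pair independently with probability
  ``rate`` (reduced sequencing depth);
* ``errors``     -- substitute exactly ``min(k, read length)`` bases per read
  (reduced base-call quality), drawing each replacement uniformly from
  {A,C,G,T,N} minus the original base.  Qualities are left untouched so the
  effect of base errors is isolated from quality-score effects.

Determinism: every per-read random decision is seeded from
``(seed, operation tag, pair ordinal[, mate])``, so outputs are reproducible
and independent of chunking.  A useful side effect of drawing error positions
as a prefix of one per-read permutation (and the subsample decision as one
per-pair uniform) is that condition families are nested: the errors at k=2
are a subset of those at k=5, and the pairs kept at rate 0.2 are a subset of
those kept at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seq_io import FastqRecord

__all__ = [
    "DegradeSpec",
    "PairingError",
    "split_single_end",
    "subsample_pairs",
    "inject_errors",
]

# Operation tags keep per-record streams of different operations disjoint.
_TAG_SUBSAMPLE = 1
_TAG_ERRORS = 2

_BASES = "ACGTN"
# Alternatives for each original base: never the base itself; N mutates to a
# uniform draw from {A,C,G,T}.
_ALTERNATIVES = {b: [x for x in _BASES if x != b] for b in "ACGT"}
_ALTERNATIVES["N"] = list("ACGT")


class PairingError(ValueError):
    """Mate files disagree in length or read ids."""


@dataclass(slots=True)
class DegradeSpec:
    """Declarative description of one degradation condition."""

    mode: str
    which_mate: int | None = None
    rate: float | None = None
    k_errors: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.mode == "single_end":
            if self.which_mate not in (1, 2):
                raise ValueError("single_end mode requires which_mate in {1, 2}")
        elif self.mode == "subsample":
            if self.rate is None or not (0.0 < self.rate <= 1.0):
                raise ValueError("subsample mode requires rate in (0, 1]")
        elif self.mode == "errors":
            if self.k_errors is None or self.k_errors < 0:
                raise ValueError("errors mode requires k_errors >= 0")
        else:
            raise ValueError(f"unknown degrade mode {self.mode!r}")

    @property
    def label(self) -> str:
        if self.mode == "single_end":
            return f"SE{self.which_mate}"
        if self.mode == "subsample":
            return f"sub{int(round(self.rate * 100))}"
        return f"err{self.k_errors}"


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


def _check_pairing(
    mate1: Sequence[FastqRecord], mate2: Sequence[FastqRecord]
) -> None:
    if len(mate1) != len(mate2):
        raise PairingError(
            f"mate files differ in length: {len(mate1)} vs {len(mate2)}"
        )
    for i, (r1, r2) in enumerate(zip(mate1, mate2)):
        if _strip_mate_suffix(r1.read_id) != _strip_mate_suffix(r2.read_id):
            raise PairingError(
                f"pair {i}: read ids differ: {r1.read_id!r} vs {r2.read_id!r}"
            )


def _record_rng(seed: int, tag: int, *ordinal: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, tag, *ordinal)))


def split_single_end(
    mate1: Sequence[FastqRecord],
    mate2: Sequence[FastqRecord],
    which_mate: int,
) -> list[FastqRecord]:
    """Project a paired library onto one mate, order and content preserved."""
    if which_mate not in (1, 2):
        raise ValueError(f"which_mate must be 1 or 2, got {which_mate!r}")
    mate1 = list(mate1)
    mate2 = list(mate2)
    _check_pairing(mate1, mate2)
    return mate1 if which_mate == 1 else mate2


def subsample_pairs(
    mate1: Sequence[FastqRecord],
    mate2: Sequence[FastqRecord],
    rate: float,
    seed: int,
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Keep each PAIR independently with probability ``rate``.

    Both mates are kept or dropped together; relative order is preserved and
    the kept set is a deterministic function of (seed, pair ordinal).
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError(f"rate must be in (0, 1], got {rate!r}")
    mate1 = list(mate1)
    mate2 = list(mate2)
    _check_pairing(mate1, mate2)
    out1: list[FastqRecord] = []
    out2: list[FastqRecord] = []
    for i, (r1, r2) in enumerate(zip(mate1, mate2)):
        # One uniform in [0, 1) per pair; u < rate keeps (rate=1 keeps all).
        u = _record_rng(seed, _TAG_SUBSAMPLE, i).random()
        if u < rate:
            out1.append(r1)
            out2.append(r2)
    return out1, out2


def _mutate_read(
    rec: FastqRecord, k: int, rng: np.random.Generator, position_bias: str
) -> FastqRecord:
    length = len(rec.bases)
    kk = min(k, length)
    if kk == 0:
        return rec
    if position_bias == "uniform":
        # Error positions are a prefix of one permutation: uniform without
        # replacement, and nested across increasing k for the same read/seed.
        positions = rng.permutation(length)[:kk]
    elif position_bias == "three_prime":
        # Weight proportional to 1-based position: errors pile up at the
        # 3' end, as base quality does on real instruments.
        weights = np.arange(1, length + 1, dtype=float)
        positions = rng.choice(length, size=kk, replace=False, p=weights / weights.sum())
    else:
        raise ValueError(f"unknown position_bias {position_bias!r}")
    draws = rng.integers(0, 4, size=kk)
    bases = list(rec.bases)
    for pos, draw in zip(positions, draws):
        bases[pos] = _ALTERNATIVES[bases[pos]][draw]
    return FastqRecord(rec.read_id, rec.mate, "".join(bases), rec.qualities)


def inject_errors(
    mate1: Sequence[FastqRecord],
    mate2: Sequence[FastqRecord] | None,
    k_errors: int,
    seed: int,
    position_bias: str = "uniform",
) -> tuple[list[FastqRecord], list[FastqRecord]] | list[FastqRecord]:
    """Substitute exactly min(k_errors, L) bases in every read.

    Chosen positions are distinct within each read, drawn uniformly by
    default or 3'-weighted with ``position_bias="three_prime"``; replacements
    are uniform over the four characters differing from the original (N is
    a legal replacement for A/C/G/T; an original N becomes one of A/C/G/T).
    Qualities, ids, read count and order are unchanged.  When ``mate2`` is
    None a single-end list is processed and returned.
    """
    if k_errors < 0:
        raise ValueError(f"k_errors must be >= 0, got {k_errors!r}")
    single = mate2 is None
    mate1 = list(mate1)
    if single:
        if k_errors == 0:
            return mate1
        return [
            _mutate_read(rec, k_errors, _record_rng(seed, _TAG_ERRORS, i, 1), position_bias)
            for i, rec in enumerate(mate1)
        ]
    mate2 = list(mate2)
    _check_pairing(mate1, mate2)
    if k_errors == 0:
        return mate1, mate2
    out1 = [
        _mutate_read(rec, k_errors, _record_rng(seed, _TAG_ERRORS, i, 1), position_bias)
        for i, rec in enumerate(mate1)
    ]
    out2 = [
        _mutate_read(rec, k_errors, _record_rng(seed, _TAG_ERRORS, i, 2), position_bias)
        for i, rec in enumerate(mate2)
    ]
    return out1, out2
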