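"""FASTQ and circRNA prediction-table I/O plus the shared candidate data model.

Coordinate convention
---------------------
Internally every back-splice junction (BSJ) is stored 1-based, inclusive on
both ends, matching the convention of CIRI-style caller output.  The canonical
on-disk table (the ``bedlike`` dialect) is 0-based half-open on the start
coordinate, like BED; the shift happens only at the I/O boundary.

Junction identity is the exact triple ``(chrom, start, end)``.  Strand is
recorded but deliberately ignored for matching: different callers disagree on
strand conventions, and cross-caller overlap requires a strand-blind key.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "FastqRecord",
    "CircCandidate",
    "PredictionSet",
    "FastqParseError",
    "TableParseError",
    "read_fastq",
    "write_fastq",
    "parse_prediction_table",
    "write_prediction_table",
]

_VALID_BASES = "ACGTN"
# translate() with this table deletes all valid characters; anything left over
# is an alphabet violation.
_DELETE_VALID = str.maketrans("", "", _VALID_BASES)

GZIP_MAGIC = b"\x1f\x8b"


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the 0-based record index."""


class TableParseError(ValueError):
    """Malformed prediction-table row; the message names the 1-based line."""


@dataclass(slots=True)
class FastqRecord:
    """One sequencing read: id, mate (1 or 2), bases and Phred+33 qualities."""

    read_id: str
    mate: int
    bases: str
    qualities: str

    def validate(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate!r}")
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.bases)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.bases.translate(_DELETE_VALID):
            raise ValueError(
                f"read {self.read_id!r}: bases outside alphabet {_VALID_BASES}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(slots=True)
class CircCandidate:
    """A predicted back-splice junction with its junction read count.

    ``start``/``end`` are the 1-based, inclusive left and right back-splice
    sites; ``junction_reads`` is the number of reads (pairs count once)
    spanning the junction.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    junction_reads: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"candidate {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be >= 0")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PredictionSet:
    """Candidates from one caller run, keyed by (chrom, start, end).

    Duplicate keys merge by summing ``junction_reads``; the first-seen strand
    is kept, which makes the aggregate independent of row order up to strand.
    """

    sample_id: str = ""
    candidates: dict[tuple[str, int, int], CircCandidate] = field(default_factory=dict)

    def add(self, cand: CircCandidate) -> None:
        key = cand.key
        existing = self.candidates.get(key)
        if existing is None:
            self.candidates[key] = cand
        else:
            existing.junction_reads += cand.junction_reads

    def get(self, key: tuple[str, int, int]) -> CircCandidate | None:
        return self.candidates.get(key)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self) -> Iterator[CircCandidate]:
        return iter(self.candidates.values())

    def __contains__(self, key: tuple[str, int, int]) -> bool:
        return key in self.candidates

    def keys(self) -> set[tuple[str, int, int]]:
        return set(self.candidates)

    def sorted_candidates(self) -> list[CircCandidate]:
        return [self.candidates[k] for k in sorted(self.candidates)]


def _open_maybe_gzip(path) -> IO[str]:
    """Open ``path`` for reading text, sniffing gzip by magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == GZIP_MAGIC:
        return gzip.open(raw, "rt")
    import io

    return io.TextIOWrapper(raw)


def read_fastq(path, mate: int = 1) -> Iterator[FastqRecord]:
    """Stream FastqRecords from a 4-line FASTQ file (optionally gzipped).

    The ``mate`` argument stamps every record; raises FastqParseError naming
    the record index on malformed input.
    """
    if mate not in (1, 2):
        raise ValueError(f"mate must be 1 or 2, got {mate!r}")
    with _open_maybe_gzip(path) as handle:
        index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"record {index}: header does not start with '@': {header!r}"
                )
            bases = handle.readline().rstrip("\n")
            plus = handle.readline()
            quals = handle.readline()
            if not plus or not quals:
                raise FastqParseError(f"record {index}: truncated record")
            if not plus.startswith("+"):
                raise FastqParseError(f"record {index}: missing '+' separator")
            quals = quals.rstrip("\n")
            if len(bases) != len(quals):
                raise FastqParseError(
                    f"record {index}: sequence length {len(bases)} != "
                    f"quality length {len(quals)}"
                )
            if bases.translate(_DELETE_VALID):
                raise FastqParseError(
                    f"record {index}: bases outside alphabet {_VALID_BASES}"
                )
            yield FastqRecord(header[1:], mate, bases, quals)
            index += 1


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    """Write records as 4-line FASTQ; gzip-compress when path ends in .gz."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.bases}\n+\n{rec.qualities}\n")


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise TableParseError(f"line {lineno}: non-integer {what}: {token!r}") from None


def _iter_table_lines(path):
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _parse_bedlike(path, ps: PredictionSet) -> None:
    for lineno, line in _iter_table_lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise TableParseError(f"line {lineno}: expected 5 columns, got {len(fields)}")
        chrom, start0, end, strand, count = fields[:5]
        start0_i = _parse_int(start0, "start", lineno)
        end_i = _parse_int(end, "end", lineno)
        count_i = _parse_int(count, "count", lineno)
        if start0_i >= end_i:
            raise TableParseError(f"line {lineno}: start0 {start0_i} >= end {end_i}")
        ps.add(
            CircCandidate(chrom, start0_i + 1, end_i, strand, count_i, source="bedlike")
        )


def _parse_ciri(path, ps: PredictionSet) -> None:
    header: list[str] | None = None
    for lineno, line in _iter_table_lines(path):
        fields = line.split("\t")
        if header is None:
            if not fields[0].startswith("circRNA_ID"):
                raise TableParseError(
                    f"line {lineno}: CIRI table must start with a 'circRNA_ID' header"
                )
            header = fields
            continue
        row = dict(zip(header, fields))
        try:
            chrom = row["chr"]
            start = _parse_int(row["circRNA_start"], "start", lineno)
            end = _parse_int(row["circRNA_end"], "end", lineno)
            count = _parse_int(row["#junction_reads"], "junction reads", lineno)
        except KeyError as exc:
            raise TableParseError(f"line {lineno}: missing column {exc}") from None
        if start > end:
            raise TableParseError(f"line {lineno}: start {start} > end {end}")
        strand = row.get("strand", ".")
        if strand not in ("+", "-"):
            strand = "."
        ps.add(CircCandidate(chrom, start, end, strand, count, source="ciri"))


def _parse_knife(path, ps: PredictionSet) -> None:
    for lineno, line in _iter_table_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise TableParseError(f"line {lineno}: expected junction id + count")
        tokens = fields[0].split("|")
        if len(tokens) < 3:
            raise TableParseError(
                f"line {lineno}: junction id must be chrom|pos1|pos2, got {fields[0]!r}"
            )
        chrom = tokens[0]
        pos1 = _parse_int(tokens[1], "pos1", lineno)
        pos2 = _parse_int(tokens[2], "pos2", lineno)
        count = _parse_int(fields[1], "count", lineno)
        strand = "."
        for tok in tokens[3:]:
            if tok in ("+", "-"):
                strand = tok
        # KNIFE orders donor/acceptor by strand; normalize to start <= end.
        start, end = min(pos1, pos2), max(pos1, pos2)
        ps.add(CircCandidate(chrom, start, end, strand, count, source="knife"))


_DIALECTS = {"ciri": _parse_ciri, "knife": _parse_knife, "bedlike": _parse_bedlike}


def parse_prediction_table(path, dialect: str, sample_id: str = "") -> PredictionSet:
    """Parse a caller output table into a normalized PredictionSet.

    Dialects: ``ciri`` (headered TSV, 1-based inclusive), ``knife``
    (``chrom|pos1|pos2`` junction id + count column) and ``bedlike``
    (0-based half-open TSV, the canonical output format of this package).
    """
    try:
        parser = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        ) from None
    ps = PredictionSet(sample_id=sample_id or str(path))
    parser(path, ps)
    return ps


def write_prediction_table(ps: PredictionSet, path) -> None:
    """Serialize to the canonical bedlike dialect, sorted by junction key."""
    with open(path, "w") as handle:
        for cand in ps.sorted_candidates():
            handle.write(
                f"{cand.chrom}\t{cand.start - 1}\t{cand.end}\t{cand.strand}\t"
                f"{cand.junction_reads}\n"
            )
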