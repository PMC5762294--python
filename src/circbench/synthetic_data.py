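"""Fully synthetic, ground-truthed stand-in for a circRNA validation experiment.

The generator emulates the experimental design used to validate circRNA
predictions: one rRNA-depleted *total RNA* library containing both linear and
circular transcripts, and one *RNase-R-treated* library in which linear RNAs
are preferentially digested so circles are enriched.  Everything is planted:

* a random toy genome with linear transcripts and circular transcripts carved
  out of linear hosts (so linear reads overlap the back-splice sites, giving
  the junction-reads ratio a meaningful denominator);
* paired-end reads sampled from transcripts proportional to expression weight
  x transcript length, with circular fragments drawn on the circle so that
  wrapping fragments produce genuine back-splice-junction (BSJ) reads;
* an anchor-based pseudo-predictor that scans reads for junction probes
  (the concatenated flanks of each planted BSJ) and reports junction read
  counts per candidate, in the same normalized table format as real callers;
* a decoy channel -- probes taken from contiguous positions of highly
  expressed linear transcripts and assigned fabricated BSJ coordinates --
  so the prediction sets contain false positives whose reads are linear-derived
  and therefore depleted by the simulated RNase-R treatment.

Every operation is a pure function of its config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seq_io import (
    CircCandidate,
    FastqRecord,
    PredictionSet,
    write_fastq,
    write_prediction_table,
)

__all__ = [
    "SimConfig",
    "Transcript",
    "Decoy",
    "SyntheticTranscriptome",
    "SyntheticTruth",
    "simulate_transcriptome",
    "simulate_reads",
    "pseudo_predict",
    "make_benchmark",
    "linear_site_coverage",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T; anything else -> 4

# Sub-stream tags for seed derivation.
_TAG_TRANSCRIPTOME = 11
_TAG_READS_TOTAL = 12
_TAG_READS_RNASER = 13


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    The defaults describe a desk-scale analogue of a fibroblast total-RNA /
    RNase-R experiment: 100-bp paired-end reads, 200k pairs per library, 50
    planted circles over a 1-Mb toy genome, RNase-R leaving 5% of linear
    molecules intact while circles survive untouched.  Circular transcripts
    contribute well under 1% of fragments (``circ_abundance``), putting the
    median junction coverage of a planted circle near 2 reads -- the sparse
    regime where real shallow libraries live and where depth and error
    degradation bite.
    """

    n_circ: int = 50
    n_linear: int = 100
    genome_length: int = 1_000_000
    chrom: str = "chr1"
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 30.0
    depth: int = 200_000  # read pairs per library
    circ_len_range: tuple[int, int] = (1500, 6000)
    linear_len_range: tuple[int, int] = (500, 2000)
    circ_log_mu: float = 0.0
    circ_log_sigma: float = 0.6
    linear_log_mu: float = 0.0
    linear_log_sigma: float = 1.5
    circ_abundance: float = 0.026  # multiplier on circular expression weights
    rnaser_linear_survival: float = 0.05
    rnaser_circ_survival: float = 1.0
    n_decoys: int = 10
    decoy_top_fraction: float = 0.02  # decoys sit on the top-expressed linears
    probe_flank: int = 20  # J: bases kept on each side of the junction
    min_overlap: int = 10  # required read overlap on each side of the BSJ
    max_mismatch: int = 2
    seed: int = 42

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0.0 <= self.rnaser_linear_survival <= 1.0):
            raise ValueError("rnaser_linear_survival must be in [0, 1]")
        if not (0.0 <= self.rnaser_circ_survival <= 1.0):
            raise ValueError("rnaser_circ_survival must be in [0, 1]")
        if self.circ_len_range[0] < 2 * self.read_length:
            raise ValueError(
                "minimum circular transcript length must be >= 2 * read_length "
                "so a read can span the junction with flanks"
            )
        if self.min_overlap > self.probe_flank:
            raise ValueError("min_overlap cannot exceed probe_flank")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(slots=True)
class Transcript:
    tid: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    weight: float
    is_circ: bool
    host_tid: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(slots=True)
class Decoy:
    """A fabricated BSJ candidate whose probe is contiguous linear sequence."""

    key: tuple[str, int, int]
    probe: str
    host_tid: str


@dataclass
class SyntheticTranscriptome:
    chrom: str
    genome: str
    linears: list[Transcript]
    circs: list[Transcript]
    decoys: list[Decoy]

    def sequence(self, t: Transcript) -> str:
        return self.genome[t.start - 1 : t.end]

    def circ_keys(self) -> set[tuple[str, int, int]]:
        return {t.key for t in self.circs}

    def decoy_keys(self) -> set[tuple[str, int, int]]:
        return {d.key for d in self.decoys}

    def junction_probe(self, t: Transcript, flank: int) -> str:
        """suffix(seq, J) + prefix(seq, J): the BSJ-spanning probe sequence."""
        seq = self.sequence(t)
        return seq[-flank:] + seq[:flank]


@dataclass
class SyntheticTruth:
    """Per-read-pair provenance for one simulated library.

    Arrays are indexed by pair ordinal; ``pair_id(i)`` maps to the FASTQ read
    id.  ``bsj_overlap`` is the largest junction overlap (min of the two
    flanks, in bases) achieved by either mate, 0 for non-spanning or
    linear-derived pairs.  ``frag_start``/``frag_end`` give the genomic span
    of linear fragments (1-based inclusive; -1 for circular pairs, whose
    genomic footprint wraps).
    """

    treatment: str
    source_tid: np.ndarray  # object array of transcript ids
    is_circ: np.ndarray  # bool
    bsj_overlap: np.ndarray  # int
    frag_start: np.ndarray  # int, -1 for circ
    frag_end: np.ndarray  # int, -1 for circ

    @property
    def n_pairs(self) -> int:
        return self.source_tid.size

    def pair_id(self, i: int) -> str:
        return f"{self.treatment}:{i:07d}"

    @property
    def spans_bsj(self) -> np.ndarray:
        return self.bsj_overlap >= 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pair_id": [self.pair_id(i) for i in range(self.n_pairs)],
                "source_tid": self.source_tid,
                "is_circ": self.is_circ,
                "bsj_overlap": self.bsj_overlap,
                "frag_start": self.frag_start,
                "frag_end": self.frag_end,
            }
        )


def _random_genome(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytes(lut[codes]).decode("ascii")


def simulate_transcriptome(config: SimConfig) -> SyntheticTranscriptome:
    """Plant linear transcripts, circular transcripts and decoy probes."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _TAG_TRANSCRIPTOME)))
    glen = config.genome_length
    lmin, lmax = config.linear_len_range
    cmin, cmax = config.circ_len_range
    if lmax >= glen or cmax >= glen:
        raise ValueError("genome too short for the requested transcript lengths")

    genome = _random_genome(rng, glen)

    linears: list[Transcript] = []
    for i in range(config.n_linear):
        length = int(rng.integers(lmin, lmax + 1))
        start = int(rng.integers(1, glen - length + 2))
        weight = float(rng.lognormal(config.linear_log_mu, config.linear_log_sigma))
        linears.append(
            Transcript(f"lin{i:04d}", config.chrom, start, start + length - 1, weight, False)
        )

    circs: list[Transcript] = []
    used_keys: set[tuple[str, int, int]] = set()
    for i in range(config.n_circ):
        for _ in range(1000):
            length = int(rng.integers(cmin, cmax + 1))
            # Anchor the left back-splice site inside a host transcript so
            # linear reads cover it (the R denominator); the circle may run
            # past the host's annotated end.
            if linears:
                host = linears[int(rng.integers(0, len(linears)))]
                start = host.start + int(rng.integers(0, host.length))
                host_tid = host.tid
            else:
                start = int(rng.integers(1, glen - length + 2))
                host_tid = None
            if start + length - 1 > glen:
                continue
            key = (config.chrom, start, start + length - 1)
            if key not in used_keys:
                used_keys.add(key)
                break
        else:  # pragma: no cover - would need a pathological config
            raise RuntimeError("could not place a unique circular transcript")
        weight = config.circ_abundance * float(
            rng.lognormal(config.circ_log_mu, config.circ_log_sigma)
        )
        circs.append(
            Transcript(f"circ{i:04d}", config.chrom, key[1], key[2], weight, True, host_tid)
        )

    decoys: list[Decoy] = []
    if config.n_decoys > 0 and linears:
        j = config.probe_flank
        n_top = max(1, int(round(config.n_linear * config.decoy_top_fraction)))
        top_hosts = sorted(linears, key=lambda t: -t.weight)[:n_top]
        taken = set(used_keys)
        for i in range(config.n_decoys):
            for _ in range(1000):
                host = top_hosts[int(rng.integers(0, len(top_hosts)))]
                if host.length < 2 * j + 2:
                    continue
                # Junction point x: probe is the contiguous genomic window
                # [x-J, x+J), so host-derived reads match it "spanning" the
                # fabricated junction.
                x = int(rng.integers(host.start + j, host.end - j + 1))
                span = int(rng.integers(cmin, cmax + 1))
                s = max(1, x - span // 2)
                e = min(glen, s + span - 1)
                key = (config.chrom, s, e)
                if key in taken:
                    continue
                taken.add(key)
                probe = genome[x - j : x + j]
                decoys.append(Decoy(key, probe, host.tid))
                break
            else:  # pragma: no cover
                raise RuntimeError("could not place a unique decoy probe")

    return SyntheticTranscriptome(config.chrom, genome, linears, circs, decoys)


def _sample_fragments_for_transcript(
    tx: SyntheticTranscriptome,
    t: Transcript,
    count: int,
    config: SimConfig,
    rng: np.random.Generator,
):
    """Yield (mate1, mate2, bsj_overlap, frag_start, frag_end) tuples."""
    L = config.read_length
    seq = tx.sequence(t)
    tlen = t.length
    flen = np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=count))
    flen = np.clip(flen, L, tlen).astype(np.int64)
    flip = rng.integers(0, 2, size=count).astype(bool)
    if t.is_circ:
        starts = rng.integers(0, tlen, size=count)
        doubled = seq + seq
        for s, fl, fp in zip(starts, flen, flip):
            frag = doubled[s : s + fl]
            # Junction overlap of each mate: the BSJ sits at circle coordinate
            # tlen (between the last and first base of the planted interval).
            ov = 0
            for a in (s, s + fl - L):  # mate intervals [a, a+L) on the circle
                if a < tlen < a + L:
                    ov = max(ov, min(tlen - a, a + L - tlen))
            if fp:
                frag = revcomp(frag)
            yield frag[:L], revcomp(frag[-L:]), int(ov), -1, -1
    else:
        span = tlen - flen + 1
        starts = (rng.random(count) * span).astype(np.int64)
        for s, fl, fp in zip(starts, flen, flip):
            frag = seq[s : s + fl]
            if fp:
                frag = revcomp(frag)
            yield frag[:L], revcomp(frag[-L:]), 0, t.start + int(s), t.start + int(s) + int(fl) - 1


def simulate_reads(
    tx: SyntheticTranscriptome, config: SimConfig, treatment: str
) -> tuple[list[FastqRecord], list[FastqRecord], SyntheticTruth]:
    """Sample a paired-end library of ``config.depth`` pairs.

    Fragments are drawn from transcripts proportional to expression weight x
    transcript length; under ``treatment="rnaser"`` the weights are further
    multiplied by the class survival probabilities (linear molecules digested,
    circles retained) and the surviving pool is sequenced to the same depth --
    i.e. Bernoulli digestion followed by library re-normalization.
    """
    config.validate()
    if treatment not in ("total", "rnaser"):
        raise ValueError(f"treatment must be 'total' or 'rnaser', got {treatment!r}")
    tag = _TAG_READS_TOTAL if treatment == "total" else _TAG_READS_RNASER
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, tag)))

    transcripts = tx.linears + tx.circs
    weights = np.array(
        [
            t.weight
            * t.length
            * (
                1.0
                if treatment == "total"
                else (config.rnaser_circ_survival if t.is_circ else config.rnaser_linear_survival)
            )
            for t in transcripts
        ],
        dtype=float,
    )
    if weights.sum() <= 0:
        raise ValueError("no transcript has positive sampling weight")
    counts = rng.multinomial(config.depth, weights / weights.sum())

    quals = "I" * config.read_length
    mate1: list[FastqRecord] = []
    mate2: list[FastqRecord] = []
    source_tid: list[str] = []
    is_circ: list[bool] = []
    bsj_overlap: list[int] = []
    frag_start: list[int] = []
    frag_end: list[int] = []

    ordinal = 0
    for t, c in zip(transcripts, counts):
        if c == 0:
            continue
        for b1, b2, ov, fs, fe in _sample_fragments_for_transcript(tx, t, int(c), config, rng):
            rid = f"{treatment}:{ordinal:07d}"
            mate1.append(FastqRecord(rid, 1, b1, quals))
            mate2.append(FastqRecord(rid, 2, b2, quals))
            source_tid.append(t.tid)
            is_circ.append(t.is_circ)
            bsj_overlap.append(ov)
            frag_start.append(fs)
            frag_end.append(fe)
            ordinal += 1

    truth = SyntheticTruth(
        treatment=treatment,
        source_tid=np.array(source_tid, dtype=object),
        is_circ=np.array(is_circ, dtype=bool),
        bsj_overlap=np.array(bsj_overlap, dtype=np.int64),
        frag_start=np.array(frag_start, dtype=np.int64),
        frag_end=np.array(frag_end, dtype=np.int64),
    )
    return mate1, mate2, truth


def _encode_reads(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate reads into one uint8 code array + start offsets."""
    big = "".join(seqs)
    arr = np.frombuffer(big.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.uint8)
    for byte, code in _BASE_CODE.items():
        lut[byte] = code
    codes = lut[arr]
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    starts = np.concatenate([[0], np.cumsum(lengths)])
    return codes, starts


def _split_core(core_len: int, n_parts: int) -> list[tuple[int, int]]:
    """(offset, length) of n_parts near-equal contiguous pieces of the core."""
    base, extra = divmod(core_len, n_parts)
    parts = []
    off = 0
    for i in range(n_parts):
        plen = base + (1 if i < extra else 0)
        parts.append((off, plen))
        off += plen
    return parts


def pseudo_predict(
    reads, tx: SyntheticTranscriptome, config: SimConfig, sample_id: str = ""
) -> PredictionSet:
    """Anchor-based BSJ detection against the planted junction probes.

    A read supports a candidate when it contains the probe's junction core --
    the ``min_overlap`` bases on each side of the junction point -- with at
    most ``max_mismatch`` mismatches.  (Any alignment spanning the junction
    with >= min_overlap on each side and <= max_mismatch mismatches contains
    such a core window, and the core window is itself such an alignment, so
    the two criteria are equivalent.)  Paired mates count once per pair.

    Matching is exact-seed + verify: the core is split into max_mismatch + 1
    contiguous parts, one of which must occur exactly (pigeonhole); candidate
    placements are then verified by direct mismatch counting, vectorized
    across all reads.
    """
    if isinstance(reads, tuple):
        flat: list[FastqRecord] = list(reads[0]) + list(reads[1])
        pair_ids = np.concatenate(
            [np.arange(len(reads[0]), dtype=np.int64), np.arange(len(reads[1]), dtype=np.int64)]
        )
        if len(reads[0]) != len(reads[1]):
            raise ValueError("paired input requires equal mate counts")
    else:
        flat = list(reads)
        pair_ids = np.arange(len(flat), dtype=np.int64)

    h = config.min_overlap
    probes: list[tuple[tuple[str, int, int], str]] = []
    for t in tx.circs:
        probe = tx.junction_probe(t, config.probe_flank)
        probes.append((t.key, probe[config.probe_flank - h : config.probe_flank + h]))
    for d in tx.decoys:
        j = len(d.probe) // 2
        probes.append((d.key, d.probe[j - h : j + h]))

    result = PredictionSet(sample_id=sample_id or f"pseudo:{len(flat)}reads")
    if not probes or not flat:
        return result

    core_len = 2 * h
    codes, starts = _encode_reads([r.bases for r in flat])
    n_big = codes.size

    # Search both senses: a flipped fragment presents the junction core as
    # its reverse complement.  Rows [0, P) are forward cores, [P, 2P) their
    # reverse complements; row % P recovers the probe.
    n_probes = len(probes)
    cores_mat = np.zeros((2 * n_probes, core_len), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.uint8)
    for byte, code in _BASE_CODE.items():
        lut[byte] = code
    for i, (_, core) in enumerate(probes):
        cores_mat[i] = lut[np.frombuffer(core.encode("ascii"), dtype=np.uint8)]
        rc = revcomp(core)
        cores_mat[n_probes + i] = lut[np.frombuffer(rc.encode("ascii"), dtype=np.uint8)]

    parts = _split_core(core_len, config.max_mismatch + 1)

    cand_probe: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    for plen in sorted({p for _, p in parts}):
        # Rolling codes of every length-plen window in the read concatenation.
        n_win = n_big - plen + 1
        win = np.zeros(n_win, dtype=np.int64)
        for i in range(plen):
            win = win * 5 + codes[i : i + n_win]
        # Seed table: code of each core-row part of this length.
        entries = []  # (code, core_row, offset)
        for pi in range(cores_mat.shape[0]):
            for off, pl in parts:
                if pl != plen:
                    continue
                code = 0
                for v in cores_mat[pi, off : off + pl]:
                    code = code * 5 + int(v)
                entries.append((code, pi, off))
        entries.sort()
        seed_codes = np.array([e[0] for e in entries], dtype=np.int64)
        seed_probe = np.array([e[1] for e in entries], dtype=np.int64)
        seed_off = np.array([e[2] for e in entries], dtype=np.int64)

        lo = np.searchsorted(seed_codes, win, side="left")
        hi = np.searchsorted(seed_codes, win, side="right")
        hit_mask = hi > lo
        hit_pos = np.nonzero(hit_mask)[0]
        if hit_pos.size == 0:
            continue
        reps = (hi - lo)[hit_pos]
        pos_rep = np.repeat(hit_pos, reps)
        # Entry indices for each (position, entry) hit, expanded without a
        # Python-level loop: base index + within-group offset.
        total = int(reps.sum())
        base = np.repeat(lo[hit_pos], reps)
        group_start = np.repeat(np.cumsum(reps) - reps, reps)
        entry_idx = base + (np.arange(total, dtype=np.int64) - group_start)
        cand_probe.append(seed_probe[entry_idx])
        cand_start.append(pos_rep - seed_off[entry_idx])

    if not cand_probe:
        return result
    cp = np.concatenate(cand_probe)
    cs = np.concatenate(cand_start)
    # Dedupe (probe, core start) pairs found via multiple seed parts.
    packed = cp * np.int64(n_big + core_len) + (cs + core_len)
    packed, keep_idx = np.unique(packed, return_index=True)
    cp = cp[keep_idx]
    cs = cs[keep_idx]

    # Bounds: the core window must lie inside a single read.
    valid = (cs >= 0) & (cs + core_len <= n_big)
    cp, cs = cp[valid], cs[valid]
    read_idx = np.searchsorted(starts, cs, side="right") - 1
    inside = cs + core_len <= starts[read_idx + 1]
    cp, cs, read_idx = cp[inside], cs[inside], read_idx[inside]
    if cp.size == 0:
        return result

    windows = codes[cs[:, None] + np.arange(core_len)[None, :]]
    mism = (windows != cores_mat[cp]).sum(axis=1)
    ok = mism <= config.max_mismatch
    cp, read_idx = cp[ok], read_idx[ok]
    if cp.size == 0:
        return result
    cp = cp % n_probes  # collapse forward/reverse-complement rows

    support = np.unique(cp * np.int64(len(flat) + 1) + pair_ids[read_idx])
    probe_idx, counts = np.unique(support // np.int64(len(flat) + 1), return_counts=True)
    for pi, cnt in zip(probe_idx, counts):
        key = probes[int(pi)][0]
        result.add(
            CircCandidate(key[0], key[1], key[2], ".", int(cnt), source="pseudo")
        )
    return result


def linear_site_coverage(
    truth: SyntheticTruth, keys: Iterable[tuple[str, int, int]]
) -> dict[tuple[str, int, int], int]:
    """Linear-derived pairs whose fragment overlaps either back-splice site.

    This is the linear component of N in the junction-reads ratio R = n/N:
    reads around the circularized region that do NOT support the junction.
    """
    lin = ~truth.is_circ
    gs = truth.frag_start[lin]
    ge = truth.frag_end[lin]
    out: dict[tuple[str, int, int], int] = {}
    for key in keys:
        _, s, e = key
        cover = ((gs <= s) & (ge >= s)) | ((gs <= e) & (ge >= e))
        out[key] = int(np.count_nonzero(cover))
    return out


def make_benchmark(config: SimConfig, out_dir) -> dict:
    """Write the full benchmark to disk and return its manifest.

    Emits total/rnaser FASTQ pairs, per-library truth tables, pseudo-predictor
    prediction tables (bedlike dialect) and a JSON manifest listing files,
    seeds and planted-truth counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tx = simulate_transcriptome(config)
    files: dict[str, str] = {}
    realized: dict[str, int] = {}
    for treatment in ("total", "rnaser"):
        m1, m2, truth = simulate_reads(tx, config, treatment)
        f1 = out / f"{treatment}_1.fastq"
        f2 = out / f"{treatment}_2.fastq"
        write_fastq(m1, f1)
        write_fastq(m2, f2)
        truth_path = out / f"{treatment}_truth.tsv"
        truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        preds = pseudo_predict((m1, m2), tx, config, sample_id=treatment)
        pred_path = out / f"{treatment}_preds.tsv"
        write_prediction_table(preds, pred_path)
        files[f"{treatment}_fastq_1"] = f1.name
        files[f"{treatment}_fastq_2"] = f2.name
        files[f"{treatment}_truth"] = truth_path.name
        files[f"{treatment}_preds"] = pred_path.name
        realized[f"{treatment}_pairs"] = truth.n_pairs
        realized[f"{treatment}_bsj_pairs"] = int(truth.spans_bsj.sum())
        realized[f"{treatment}_predicted"] = len(preds)
    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        },
        "files": files,
        "realized": realized,
        "planted_circs": [list(k) for k in sorted(tx.circ_keys())],
        "decoy_keys": [list(k) for k in sorted(tx.decoy_keys())],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
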