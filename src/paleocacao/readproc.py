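"""Read processing for degraded-DNA libraries.

The chain is trim (adapter + quality) -> merge pairs -> exact
deduplication -> low-complexity (entropy) filter, with exact per-stage
accounting. Reads shorter than 30 nt after trimming are discarded;
quality trimming strips bases below Q20 from both ends; merging picks the
best overlap (>= 10 nt, mismatch density <= 0.25) and resolves
disagreements to the higher-quality call; deduplication collapses exact
sequence duplicates only; the entropy filter removes any read containing
a window whose normalized k-mer Shannon entropy falls below threshold.

Unmerged pairs are retained as two independent single-end sequences by
default (a config switch), so no recoverable fragment is thrown away.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import ADAPTER_R1, ADAPTER_R2, revcomp


class FastqFormatError(ValueError):
    """Malformed or desynchronized FASTQ input."""


@dataclass
class ProcessedRead:
    id: str
    seq: str
    qual: str
    merged: bool = False
    trimmed5: int = 0
    trimmed3: int = 0

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise FastqFormatError(f"record {self.id}: sequence/quality length mismatch")


@dataclass
class StageCounts:
    """Ordered map stage -> (units in, units out); unit = sequences."""

    stages: "OrderedDict[str, tuple[int, int]]" = field(default_factory=OrderedDict)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if self.stages:
            last_out = list(self.stages.values())[-1][1]
            if n_in != last_out:
                raise ValueError(f"stage {stage}: in-count {n_in} != previous out-count {last_out}")
        if n_out > n_in:
            raise ValueError(f"stage {stage}: out-count exceeds in-count")
        self.stages[stage] = (n_in, n_out)

    def as_dict(self) -> dict:
        return {k: {"in": v[0], "out": v[1]} for k, v in self.stages.items()}


def _phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def trim_read(
    read_id: str,
    seq: str,
    qual: str,
    quality_cutoff: int = 20,
    min_length: int = 30,
    adapters: tuple[str, ...] = (ADAPTER_R1, ADAPTER_R2),
    min_adapter_overlap: int = 3,
) -> ProcessedRead | None:
    """Remove adapter read-through and low-quality ends; drop short reads.

    The adapter is located by exact substring match, else by the longest
    suffix of the read matching an adapter prefix (>= ``min_adapter_overlap``).
    Everything from the adapter start onward is removed. Then bases with
    Q < ``quality_cutoff`` are trimmed from both ends inward. Returns
    ``None`` if fewer than ``min_length`` bases remain.
    """
    if len(seq) != len(qual):
        raise FastqFormatError(f"record {read_id}: sequence/quality length mismatch")
    cut = len(seq)
    for adapter in adapters:
        idx = seq.find(adapter)
        if idx != -1:
            cut = min(cut, idx)
            continue
        max_o = min(len(adapter), len(seq)) - 1
        for o in range(max_o, min_adapter_overlap - 1, -1):
            if seq.endswith(adapter[:o]):
                cut = min(cut, len(seq) - o)
                break
    seq, qual = seq[:cut], qual[:cut]

    q = _phred(qual)
    lo, hi = 0, len(seq)
    while lo < hi and q[lo] < quality_cutoff:
        lo += 1
    while hi > lo and q[hi - 1] < quality_cutoff:
        hi -= 1
    if hi - lo < min_length:
        return None
    return ProcessedRead(read_id, seq[lo:hi], qual[lo:hi], trimmed5=lo, trimmed3=len(seq) - hi)


def merge_pair(
    r1: ProcessedRead,
    r2: ProcessedRead,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> ProcessedRead | None:
    """Merge a pair into one fragment sequence, or return ``None``.

    ``r2`` is reverse-complemented, then the suffix of ``r1`` is scanned
    against its prefix. The accepted overlap minimizes mismatch density
    (ties -> longer overlap); overlapping positions take the
    higher-quality base call. Merged length is ``|r1| + |r2| - overlap``.
    """
    s2 = revcomp(r2.seq)
    q2 = r2.qual[::-1]
    l1, l2 = len(r1.seq), len(s2)
    best: tuple[float, int] | None = None  # (density, overlap)
    for o in range(min_overlap, min(l1, l2) + 1):
        a, b = r1.seq[l1 - o:], s2[:o]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        density = mism / o
        if density <= max_mismatch_density and (best is None or (density, -o) < (best[0], -best[1])):
            best = (density, o)
    if best is None:
        return None
    o = best[1]
    mid_s, mid_q = [], []
    for i in range(o):
        c1, p1 = r1.seq[l1 - o + i], r1.qual[l1 - o + i]
        c2, p2 = s2[i], q2[i]
        if c1 == c2 or p1 >= p2:
            mid_s.append(c1)
            mid_q.append(max(p1, p2) if c1 == c2 else p1)
        else:
            mid_s.append(c2)
            mid_q.append(p2)
    seq = r1.seq[: l1 - o] + "".join(mid_s) + s2[o:]
    qual = r1.qual[: l1 - o] + "".join(mid_q) + q2[o:]
    return ProcessedRead(r1.id, seq, qual, merged=True)


def deduplicate(reads: Iterable[ProcessedRead]) -> list[ProcessedRead]:
    """Collapse exact sequence duplicates, keeping the first occurrence."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def sequence_entropy(seq: str, k: int = 5, window: int = 50) -> float:
    """Minimum normalized k-mer Shannon entropy over sliding windows.

    Each window's entropy is normalized by log of the number of k-mer
    slots in the window (so a window of unique k-mers scores 1 and a
    homopolymer scores 0). Windows slide by one base; short reads are a
    single window.
    """
    n = len(seq)
    if n < k:
        return 1.0
    win = min(window, n)
    n_slots = win - k + 1
    norm = math.log(min(4**k, n_slots))
    if norm == 0:
        return 0.0
    best = math.inf
    counts: Counter[str] = Counter(seq[i:i + k] for i in range(n_slots))
    pos = 0
    while True:
        h = 0.0
        for c in counts.values():
            if c:
                p = c / n_slots
                h -= p * math.log(p)
        best = min(best, h / norm)
        if pos + win >= n:
            break
        counts[seq[pos:pos + k]] -= 1
        counts[seq[pos + win - k + 1:pos + win + 1]] += 1
        pos += 1
    return best


def entropy_filter(
    reads: Iterable[ProcessedRead],
    entropy_threshold: float = 0.7,
    k: int = 5,
    window: int = 50,
) -> list[ProcessedRead]:
    """Drop reads containing any window below the entropy threshold."""
    return [r for r in reads if sequence_entropy(r.seq, k, window) >= entropy_threshold]


@dataclass
class ReadprocParams:
    quality_cutoff: int = 20
    min_length: int = 30
    min_overlap: int = 10
    max_mismatch_density: float = 0.25
    entropy_threshold: float = 0.7
    entropy_k: int = 5
    entropy_window: int = 50
    keep_unmerged: bool = True
    adapters: tuple[str, ...] = (ADAPTER_R1, ADAPTER_R2)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(source) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual) from a FASTQ(.gz) path or pass tuples through."""
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as fh:
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    yield title.split()[0], seq, qual
            except ValueError as exc:
                raise FastqFormatError(str(exc)) from exc
    else:
        yield from source


def run_readproc(fastq_r1, fastq_r2, params: ReadprocParams | None = None):
    """Run the full chain on a read pair set.

    Returns ``(processed_reads, StageCounts)``. The accounting unit is a
    sequence (2 per input pair); counts are exact and non-increasing.
    """
    params = params or ReadprocParams()
    pairs1 = list(read_fastq(fastq_r1))
    pairs2 = list(read_fastq(fastq_r2))
    if len(pairs1) != len(pairs2):
        raise FastqFormatError("R1/R2 files have different numbers of records")
    for (id1, _, _), (id2, _, _) in zip(pairs1, pairs2):
        if id1 != id2:
            raise FastqFormatError(f"desynchronized pair: {id1!r} vs {id2!r}")

    counts = StageCounts()
    n_in = 2 * len(pairs1)

    trimmed: list[tuple[ProcessedRead | None, ProcessedRead | None]] = []
    n_surv = 0
    for (rid, s1, q1), (_, s2, q2) in zip(pairs1, pairs2):
        t1 = trim_read(rid, s1, q1, params.quality_cutoff, params.min_length, params.adapters)
        t2 = trim_read(rid, s2, q2, params.quality_cutoff, params.min_length, params.adapters)
        n_surv += (t1 is not None) + (t2 is not None)
        trimmed.append((t1, t2))
    counts.add("trim", n_in, n_surv)

    merged_out: list[ProcessedRead] = []
    n_after_merge = 0
    for t1, t2 in trimmed:
        if t1 is not None and t2 is not None:
            m = merge_pair(t1, t2, params.min_overlap, params.max_mismatch_density)
            if m is not None:
                merged_out.append(m)
                n_after_merge += 1
                continue
            if params.keep_unmerged:
                merged_out.extend([t1, t2])
                n_after_merge += 2
        else:
            for t in (t1, t2):
                if t is not None:
                    if params.keep_unmerged:
                        merged_out.append(t)
                        n_after_merge += 1
    counts.add("merge", n_surv, n_after_merge)

    unique = deduplicate(merged_out)
    counts.add("dedup", n_after_merge, len(unique))

    kept = entropy_filter(unique, params.entropy_threshold, params.entropy_k, params.entropy_window)
    counts.add("entropy", len(unique), len(kept))
    return kept, counts


def write_fastq(reads: Iterable[ProcessedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
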