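"""Best-hit taxonomic assignment for residue metagenomes.

Two stages mirror the filter chain used on the real libraries: a focal
(cacao) genome prefilter, then best-hit classification against a
multi-taxon reference, followed by the per-item presence call: a taxon is
present when at least five *distinct* first-hit sequences point to it.

Alignment is explicit Smith–Waterman with affine gaps, row-vectorized in
numpy so a short query against a multi-kilobase reference stays fast. A
read whose best score ties across different taxa is ambiguous and is
assigned to none — the conservative reading of a "first hit".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

from .simulate import revcomp


class TaxonRecord(NamedTuple):
    id: str
    taxon: str
    seq: str


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local score with every tied optimal start/end position."""

    score: float
    ref_starts: tuple[int, ...]  # 0-based starts of optimal local alignments
    ref_ends: tuple[int, ...]  # 0-based exclusive ends


@dataclass
class HitRecord:
    read_id: str
    taxon: str | None
    best_score: float
    runner_up: float
    ambiguous: bool


@dataclass
class TaxonCall:
    """Per-item presence verdicts from distinct first-hit sequence counts."""

    item_id: str
    counts: dict[str, int]
    positive: dict[str, bool]
    threshold: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _sw_scan(query: np.ndarray, ref: np.ndarray, match: float, mismatch: float,
             gap_open: float, gap_extend: float, want_ends: bool):
    """One Smith–Waterman pass; returns (best score, tied end columns).

    The within-row (reference-gap) state is resolved by a prefix-max
    accumulate, which is exact when gap_open <= gap_extend <= 0: opening a
    new gap from a gap-closing cell is then never better than extending.
    """
    n = len(ref)
    m = len(query)
    NEG = -1e18
    H_prev = np.zeros(n + 1)
    F = np.full(n + 1, NEG)
    best = 0.0
    ends: set[int] = set()
    idx = np.arange(n + 1, dtype=float)
    ref_is_n = np.concatenate(([False], ref == ord("N")))
    for i in range(m):
        qc = query[i]
        s = np.empty(n + 1)
        s[0] = NEG
        if qc == ord("N"):
            s[1:] = mismatch
        else:
            s[1:] = np.where(ref == qc, match, mismatch)
        s[ref_is_n] = mismatch
        M = np.empty(n + 1)
        M[0] = 0.0
        M[1:] = H_prev[:-1] + s[1:]
        F = np.maximum(F + gap_extend, H_prev + gap_open)
        H0 = np.maximum(np.maximum(M, F), 0.0)
        # E[j] = max_{k<=j-1} H0[k] + gap_open + (j-1-k) * gap_extend
        A = H0 + gap_open - idx * gap_extend
        P = np.maximum.accumulate(A)
        H = H0.copy()
        H[1:] = np.maximum(H0[1:], P[:-1] + (idx[1:] - 1) * gap_extend)
        H[0] = 0.0
        row_max = H.max()
        if row_max > best:
            best = row_max
            if want_ends:
                ends = set(np.flatnonzero(H == best))
        elif want_ends and row_max == best and best > 0:
            ends.update(np.flatnonzero(H == best))
        H_prev = H
    return best, ends


def local_score(query: str, reference: str, match: float = 1, mismatch: float = -1,
                gap_open: float = -2, gap_extend: float = -1) -> float:
    """Optimal Smith–Waterman local score (score only, fastest path)."""
    if not query:
        raise ValueError("empty query")
    if not reference:
        raise ValueError("empty reference")
    if not (gap_open <= gap_extend <= 0 and match > 0 > mismatch):
        raise ValueError("requires gap_open <= gap_extend <= 0 and match > 0 > mismatch")
    score, _ = _sw_scan(_encode(query), _encode(reference), match, mismatch,
                        gap_open, gap_extend, want_ends=False)
    return score


def align_local(query: str, reference: str, match: float = 1, mismatch: float = -1,
                gap_open: float = -2, gap_extend: float = -1) -> LocalAlignment:
    """Smith–Waterman local alignment with all tied optimal locations.

    N matches nothing (scores as a mismatch against every base). End
    positions come from the forward pass; start positions from the same
    pass over the reversed pair.
    """
    if not query:
        raise ValueError("empty query")
    if not reference:
        raise ValueError("empty reference")
    if not (gap_open <= gap_extend <= 0 and match > 0 > mismatch):
        raise ValueError("requires gap_open <= gap_extend <= 0 and match > 0 > mismatch")
    q, r = _encode(query), _encode(reference)
    score, ends = _sw_scan(q, r, match, mismatch, gap_open, gap_extend, True)
    if score <= 0:
        return LocalAlignment(0.0, (), ())
    _, rev_ends = _sw_scan(q[::-1], r[::-1], match, mismatch, gap_open, gap_extend, True)
    starts = tuple(sorted(len(reference) - j for j in rev_ends))
    return LocalAlignment(float(score), starts, tuple(sorted(int(j) for j in ends)))


def best_locations(read: str, references: Mapping[str, str], **kw):
    """Best score over all references and strands, with tied locations.

    Returns ``(score, [(ref_name, strand, start), ...])`` where start is
    the 0-based reference coordinate of each optimal local alignment.
    """
    best = 0.0
    locs: list[tuple[str, str, int]] = []
    for name, seq in references.items():
        for strand, q in (("+", read), ("-", revcomp(read))):
            aln = align_local(q, seq, **kw)
            if aln.score > best:
                best = aln.score
                locs = [(name, strand, s) for s in aln.ref_starts]
            elif aln.score == best and best > 0:
                locs.extend((name, strand, s) for s in aln.ref_starts)
    return best, locs


def prefilter_focal(
    reads: Iterable[tuple[str, str]],
    focal: Mapping[str, str],
    min_score_fraction: float = 0.9,
    **kw,
) -> list[tuple[str, str]]:
    """Keep reads whose best local score against the focal genome reaches
    ``min_score_fraction`` x read length on either strand."""
    if not focal or all(len(s) == 0 for s in focal.values()):
        raise ValueError("empty focal reference")
    kept = []
    for rid, seq in reads:
        need = min_score_fraction * len(seq)
        hit = False
        for ref in focal.values():
            if local_score(seq, ref, **kw) >= need or local_score(revcomp(seq), ref, **kw) >= need:
                hit = True
                break
        if hit:
            kept.append((rid, seq))
    return kept


def best_hit(read_id: str, read_seq: str, taxon_db: Sequence[TaxonRecord], **kw) -> HitRecord:
    """Best-hit classification over a labelled multi-taxon database.

    The hit taxon maximizes the local score over all records and both
    strands; an exact score tie between different taxa makes the read
    ambiguous (assigned to no taxon). ``runner_up`` is the best score
    among taxa other than the winner.
    """
    if not taxon_db:
        raise ValueError("empty taxon database")
    per_taxon: dict[str, float] = {}
    for rec in taxon_db:
        sc = max(local_score(read_seq, rec.seq, **kw),
                 local_score(revcomp(read_seq), rec.seq, **kw))
        per_taxon[rec.taxon] = max(per_taxon.get(rec.taxon, 0.0), sc)
    ranked = sorted(per_taxon.items(), key=lambda kv: -kv[1])
    best_taxon, best_score = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else 0.0
    ambiguous = len(ranked) > 1 and runner_up == best_score
    return HitRecord(read_id, None if ambiguous else best_taxon, best_score, runner_up, ambiguous)


def call_presence(
    hits: Iterable[tuple[str, HitRecord]],
    target_taxa: Sequence[str],
    min_distinct: int = 5,
    item_id: str = "",
) -> TaxonCall:
    """Per-taxon presence: >= ``min_distinct`` distinct first-hit sequences.

    ``hits`` pairs each read's (deduplicated) sequence with its
    :class:`HitRecord`; distinctness is by exact sequence, so repeated
    reads of one fragment count once.
    """
    distinct: dict[str, set[str]] = {t: set() for t in target_taxa}
    for seq, hit in hits:
        if hit.taxon in distinct and not hit.ambiguous:
            distinct[hit.taxon].add(seq)
    counts = {t: len(s) for t, s in distinct.items()}
    positive = {t: c >= min_distinct for t, c in counts.items()}
    return TaxonCall(item_id, counts, positive, min_distinct)


def load_taxon_fasta(path) -> list[TaxonRecord]:
    """Load a multi-taxon FASTA whose headers carry ``taxon=<label>``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = None
        for tok in rec.description.split():
            if tok.startswith("taxon="):
                taxon = tok[len("taxon="):]
        if taxon is None:
            raise ValueError(f"record {rec.id}: missing taxon=<label> in header")
        records.append(TaxonRecord(rec.id, taxon, str(rec.seq)))
    return records


def first_hit_percent(n_first_hit: int, n_mapped: int, digits: int = 2) -> float:
    """Fraction of genome-mapped sequences that are first-hit assignments,
    as a percentage rounded to the reporting precision."""
    if n_mapped <= 0:
        raise ValueError("n_mapped must be positive")
    return round(100.0 * n_first_hit / n_mapped, digits)
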