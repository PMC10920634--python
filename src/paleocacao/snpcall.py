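"""Damage-aware SNP allele extraction from aligned ancient fragments.

Filters follow the stringent practice for degraded templates: fragments
must map to a unique best-scoring location on the focal genome;
observations within the first five bases of either fragment end are
discarded when — and only when — the observed allele could be a
deamination artefact (T at a C/T site near the 5' end, A at a G/A site
near the 3' end, in read orientation); observations matching neither
panel allele are discarded and their fraction reported. Per-locus
evidence is collapsed to a coarse dosage in {0, 0.5, 1}, and items with
fewer than 20 covered loci are flagged ineligible for ancestry work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .simulate import ReferencePanel, SNPLocus
from .taxassign import best_locations


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class AlleleObservation:
    """One panel-locus base observed on one fragment.

    ``base_read`` is the base as sequenced; ``base_genome`` is the same
    base in genome orientation (complemented for minus-strand fragments).
    End distances are on the read as sequenced.
    """

    locus_id: str
    fragment_id: str
    base_read: str
    base_genome: str
    dist5: int
    dist3: int
    status: str = "kept"  # kept / terminal_damage / allele_mismatch / multi_mapped


@dataclass
class ItemGenotype:
    """Per-item dosage estimates over covered panel loci."""

    item_id: str
    dosage: dict[str, float]  # locus id -> 0 / 0.5 / 1 (alt fraction)
    depth: dict[str, tuple[int, int]]  # locus id -> (n_ref, n_alt)
    min_loci: int = 20

    @property
    def n_loci(self) -> int:
        return len(self.dosage)

    @property
    def eligible(self) -> bool:
        return self.n_loci >= self.min_loci


def unique_mapping_filter(fragment_sequence: str, focal_genome: Mapping[str, str], **kw) -> bool:
    """Keep a fragment iff it has exactly one optimal-score location
    (both strands pooled) on the focal genome."""
    score, locs = best_locations(fragment_sequence, focal_genome, **kw)
    return score > 0 and len(set(locs)) == 1


def map_fragment(
    fragment_sequence: str,
    focal_genome: Mapping[str, str],
    min_score_fraction: float = 0.0,
    **kw,
):
    """Place a fragment on the focal genome if it maps uniquely.

    Returns ``(chrom, start, end, strand)`` assuming a gapless placement
    (deamination produces substitutions, not indels), or ``None`` when
    the best score is tied across locations or falls below
    ``min_score_fraction`` x fragment length (use ~0.9 to reject
    spurious weak placements of non-target reads).
    """
    score, locs = best_locations(fragment_sequence, focal_genome, **kw)
    locs = sorted(set(locs))
    if score <= 0 or score < min_score_fraction * len(fragment_sequence) or len(locs) != 1:
        return None
    chrom, strand, start = locs[0]
    return chrom, start, start + len(fragment_sequence), strand


def extract_alleles(fragment, loci: Sequence[SNPLocus]) -> list[AlleleObservation]:
    """One observation per panel locus covered by the fragment.

    ``fragment`` needs ``sequence``, ``chrom``, ``start``, ``end``,
    ``strand`` and (optionally) ``read_id``. Read position, and hence the
    end distances, follow the sequencing orientation.
    """
    obs = []
    L = len(fragment.sequence)
    frag_id = getattr(fragment, "read_id", "")
    for locus in loci:
        if locus.chrom != fragment.chrom or not fragment.start <= locus.pos < fragment.end:
            continue
        if fragment.strand == "+":
            rp = locus.pos - fragment.start
        else:
            rp = fragment.end - 1 - locus.pos
        base_read = fragment.sequence[rp]
        base_genome = base_read if fragment.strand == "+" else _COMP[base_read]
        obs.append(
            AlleleObservation(locus.id, frag_id, base_read, base_genome, rp, L - 1 - rp)
        )
    return obs


def _alleles_read_orientation(locus: SNPLocus, strand: str) -> set[str]:
    if strand == "+":
        return {locus.ref, locus.alt}
    return {_COMP[locus.ref], _COMP[locus.alt]}


def terminal_damage_filter(
    observations: Iterable[AlleleObservation],
    loci_by_id: Mapping[str, SNPLocus],
    end_window: int = 5,
    strand_by_fragment: Mapping[str, str] | None = None,
) -> list[AlleleObservation]:
    """Drop terminal observations explainable as deamination.

    An observation is removed iff it lies within ``end_window`` bases of
    an end AND matches the damage pattern there: observed T at a C/T
    locus near the 5' end, or observed A at a G/A locus near the 3' end
    (allele pairs taken in read orientation). Every other terminal
    observation is kept. Dropped observations are returned too, with
    status ``terminal_damage`` — callers keep only ``kept``.
    """
    out = []
    for o in observations:
        if o.status != "kept":
            out.append(o)
            continue
        locus = loci_by_id[o.locus_id]
        strand = strand_by_fragment.get(o.fragment_id, "+") if strand_by_fragment else "+"
        # allele pair as the sequencer saw it
        pair = _alleles_read_orientation(locus, strand)
        drop = (o.dist5 < end_window and o.base_read == "T" and pair == {"C", "T"}) or (
            o.dist3 < end_window and o.base_read == "A" and pair == {"G", "A"}
        )
        out.append(replace(o, status="terminal_damage") if drop else o)
    return out


def allele_match_filter(
    observations: Iterable[AlleleObservation],
    loci_by_id: Mapping[str, SNPLocus],
) -> tuple[list[AlleleObservation], float]:
    """Discard observations matching neither panel allele.

    Returns the annotated observations and the discarded fraction (of
    observations that were still ``kept`` on entry).
    """
    out, n_seen, n_bad = [], 0, 0
    for o in observations:
        if o.status != "kept":
            out.append(o)
            continue
        n_seen += 1
        locus = loci_by_id[o.locus_id]
        if o.base_genome not in (locus.ref, locus.alt):
            n_bad += 1
            out.append(replace(o, status="allele_mismatch"))
        else:
            out.append(o)
    return out, (n_bad / n_seen if n_seen else 0.0)


def aggregate_genotype(
    item_id: str,
    observations: Iterable[AlleleObservation],
    loci_by_id: Mapping[str, SNPLocus],
    min_loci: int = 20,
) -> ItemGenotype:
    """Collapse kept observations to per-locus dosage.

    All-ref reads -> 0, all-alt -> 1, both observed -> 0.5. Loci with no
    kept observation are absent.
    """
    counts: dict[str, list[int]] = {}
    for o in observations:
        if o.status != "kept":
            continue
        locus = loci_by_id[o.locus_id]
        c = counts.setdefault(o.locus_id, [0, 0])
        if o.base_genome == locus.ref:
            c[0] += 1
        elif o.base_genome == locus.alt:
            c[1] += 1
    dosage, depth = {}, {}
    for lid, (n_ref, n_alt) in counts.items():
        if n_ref + n_alt == 0:
            continue
        if n_alt == 0:
            dosage[lid] = 0.0
        elif n_ref == 0:
            dosage[lid] = 1.0
        else:
            dosage[lid] = 0.5
        depth[lid] = (n_ref, n_alt)
    return ItemGenotype(item_id, dosage, depth, min_loci=min_loci)


def call_item(
    fragments,
    panel: ReferencePanel,
    focal_genome: Mapping[str, str],
    item_id: str = "",
    end_window: int = 5,
    require_unique: bool = True,
    align_kw: dict | None = None,
) -> tuple[ItemGenotype, dict]:
    """Full per-item chain: unique mapping -> extract -> damage filter ->
    allele-match filter -> dosage aggregation.

    ``fragments`` carry their alignment (chrom/start/end/strand); when
    ``require_unique`` the sequence is additionally checked for a single
    best-scoring placement on the focal genome. Returns the genotype and
    a filter report.
    """
    loci_by_id = {l.id: l for l in panel.loci}
    strand_by_fragment: dict[str, str] = {}
    obs: list[AlleleObservation] = []
    n_multi = 0
    for frag in fragments:
        if require_unique and not unique_mapping_filter(frag.sequence, focal_genome, **(align_kw or {})):
            n_multi += 1
            continue
        strand_by_fragment[getattr(frag, "read_id", "")] = frag.strand
        obs.extend(extract_alleles(frag, panel.loci))
    obs = terminal_damage_filter(obs, loci_by_id, end_window, strand_by_fragment)
    obs, mismatch_fraction = allele_match_filter(obs, loci_by_id)
    genotype = aggregate_genotype(item_id, obs, loci_by_id)
    report = {
        "n_fragments_multi_mapped": n_multi,
        "n_observations": len(obs),
        "n_terminal_damage": sum(o.status == "terminal_damage" for o in obs),
        "n_allele_mismatch": sum(o.status == "allele_mismatch" for o in obs),
        "mismatch_fraction": mismatch_fraction,
        "n_loci": genotype.n_loci,
        "eligible": genotype.eligible,
    }
    return genotype, report


def genotype_to_vcf(genotype: ItemGenotype, panel: ReferencePanel, path) -> None:
    """Write an item genotype as a minimal single-sample VCF (1-based)."""
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % genotype.item_id)
        for locus in panel.loci:
            gt = gt_map.get(genotype.dosage.get(locus.id, None), "./.")
            fh.write(
                f"{locus.chrom}\t{locus.pos + 1}\t{locus.id}\t{locus.ref}\t{locus.alt}\t.\t.\t.\tGT\t{gt}\n"
            )
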