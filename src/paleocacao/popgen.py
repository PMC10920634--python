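"""Ancestry inference against a labelled reference panel.

The membership proportions q of an archaeological item over the
reference genetic groups are obtained by supervised maximum-likelihood
admixture: each observed allele copy is an independent draw from the
mixture sum_k q_k p_{k,l}, and EM over q on the simplex maximizes the
(concave) log-likelihood. Group frequencies are clipped away from 0/1 by
1/(2 n_k + 1) so private alleles in small groups cannot produce infinite
penalties. Group pairs whose merge barely changes the optimum are
flagged ambiguous — the analogue of two reference groups a sparse item
cannot tell apart.

Between-group structure is summarized by Nei's (1978) unbiased genetic
distance, an allele-sharing dissimilarity between individuals, and
neighbor-joining trees with locus-bootstrap support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .simulate import ReferencePanel
from .snpcall import ItemGenotype


class IneligibleItemError(ValueError):
    """Raised when an item has too few loci for ancestry inference."""


@dataclass
class AncestryEstimate:
    item_id: str
    groups: list[str]
    q: np.ndarray
    loglik: float
    n_loci: int
    n_iterations: int
    ll_history: np.ndarray
    ambiguous_pairs: list[tuple[str, str]] = field(default_factory=list)

    def top_group(self) -> str:
        return self.groups[int(np.argmax(self.q))]

    def as_series(self) -> pd.Series:
        return pd.Series(self.q, index=self.groups, name=self.item_id)


def _clip_freqs(panel: ReferencePanel) -> np.ndarray:
    sizes = panel.group_sizes
    eps = 1.0 / (2 * sizes + 1)
    return np.clip(panel.freqs, eps[None, :], 1 - eps[None, :])


def _genotype_arrays(genotype, panel: ReferencePanel):
    """Alt/ref allele-copy counts aligned to panel locus order."""
    if isinstance(genotype, ItemGenotype):
        dosage = genotype.dosage
    else:
        dosage = dict(genotype)
    ids = [l.id for l in panel.loci]
    keep = [i for i, lid in enumerate(ids) if lid in dosage]
    alt = np.array([2.0 * dosage[ids[i]] for i in keep])
    return np.array(keep, dtype=int), alt, 2.0 - alt


def _em(P: np.ndarray, alt: np.ndarray, ref: np.ndarray, q0: np.ndarray,
        tol: float, max_iter: int):
    """EM on the simplex; returns (q, ll_history). Log-likelihood is
    monotone non-decreasing by construction and asserted per step."""
    q = q0.copy()
    hist = []
    total = alt.sum() + ref.sum()
    for _ in range(max_iter):
        mix_alt = P @ q
        mix_ref = (1 - P) @ q
        ll = float(alt @ np.log(mix_alt) + ref @ np.log(mix_ref))
        if hist and ll < hist[-1] - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        converged = bool(hist) and ll - hist[-1] < tol
        hist.append(ll)
        if converged:
            break
        r_alt = P * q[None, :] / mix_alt[:, None]
        r_ref = (1 - P) * q[None, :] / mix_ref[:, None]
        q = (alt @ r_alt + ref @ r_ref) / total
        q = np.maximum(q, 0)
        q /= q.sum()
    return q, np.asarray(hist)


def admixture_em(
    genotype,
    panel: ReferencePanel,
    tol: float = 1e-8,
    max_iter: int = 1000,
    ambiguity_delta: float = 2.0,
    min_loci: int = 20,
    q0: np.ndarray | None = None,
    flag_ambiguous: bool = True,
) -> AncestryEstimate:
    """Supervised admixture proportions for one item by EM.

    ``genotype`` is an :class:`~paleocacao.snpcall.ItemGenotype` or a
    mapping locus id -> dosage in {0, 0.5, 1}. A pair of groups the item
    draws ancestry from is reported ambiguous when swapping their
    proportions costs less than ``ambiguity_delta`` log-likelihood units
    — the item cannot tell the two attributions apart.
    """
    item_id = genotype.item_id if isinstance(genotype, ItemGenotype) else ""
    keep, alt, ref = _genotype_arrays(genotype, panel)
    if len(keep) == 0:
        raise ValueError("no genotyped loci overlap the panel")
    if len(keep) < min_loci:
        raise IneligibleItemError(
            f"item {item_id!r}: {len(keep)} loci < required {min_loci}"
        )
    P = _clip_freqs(panel)[keep, :]
    K = panel.n_groups
    q0 = np.full(K, 1.0 / K) if q0 is None else np.asarray(q0, float)
    q, hist = _em(P, alt, ref, q0, tol, max_iter)

    ambiguous: list[tuple[str, str]] = []
    if flag_ambiguous:

        def loglik(qv):
            return float(alt @ np.log(P @ qv) + ref @ np.log((1 - P) @ qv))

        ll_opt = hist[-1]
        for j, k in itertools.combinations(range(K), 2):
            if q[j] + q[k] < 0.05:
                continue  # a pair the item draws nothing from cannot matter
            q_swap = q.copy()
            q_swap[[j, k]] = q_swap[[k, j]]
            if ll_opt - loglik(q_swap) < ambiguity_delta:
                ambiguous.append((panel.groups[j], panel.groups[k]))

    return AncestryEstimate(
        item_id=item_id,
        groups=list(panel.groups),
        q=q,
        loglik=float(hist[-1]),
        n_loci=len(keep),
        n_iterations=len(hist),
        ll_history=hist,
        ambiguous_pairs=ambiguous,
    )


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------


def _unbiased_identity(p: np.ndarray, n: int) -> np.ndarray:
    """Nei (1978) unbiased within-population gene identity per biallelic
    locus: (2n * sum(p_i^2) - 1) / (2n - 1)."""
    hom = p**2 + (1 - p) ** 2
    return (2 * n * hom - 1) / (2 * n - 1) if n > 0.5 else hom


def nei_distance(freqs_x, freqs_y, n_x: int, n_y: int) -> float:
    """Nei's (1978) small-sample-corrected genetic distance.

    D = -ln( J_xy / sqrt(J_x J_y) ) with J_x, J_y the unbiased within-
    population identities averaged over loci and J_xy the between-
    population identity. Small sampling-induced negatives are clamped
    to 0.
    """
    px = np.asarray(freqs_x, float)
    py = np.asarray(freqs_y, float)
    if px.shape != py.shape or px.size == 0:
        raise ValueError("frequency vectors must be non-empty and congruent")
    if n_x < 1 or n_y < 1:
        raise ValueError("sample sizes must be >= 1")
    jx = _unbiased_identity(px, n_x).mean()
    jy = _unbiased_identity(py, n_y).mean()
    jxy = (px * py + (1 - px) * (1 - py)).mean()
    d = -np.log(jxy / np.sqrt(jx * jy))
    return float(max(d, 0.0))


def item_group_nei(genotype, panel: ReferencePanel) -> pd.Series:
    """Nei distance from one item (a pseudo-population of size 1) to each
    reference group, over the item's covered loci."""
    keep, alt, _ = _genotype_arrays(genotype, panel)
    p_item = alt / 2.0
    sample_freqs = panel.sample_freqs()[keep, :]
    sizes = panel.group_sizes
    out = {
        g: nei_distance(p_item, sample_freqs[:, k], 1, int(sizes[k]))
        for k, g in enumerate(panel.groups)
    }
    name = genotype.item_id if isinstance(genotype, ItemGenotype) else ""
    return pd.Series(out, name=name).sort_values()


# ---------------------------------------------------------------------------
# Dissimilarity, neighbor joining, bootstrap
# ---------------------------------------------------------------------------


def dissimilarity_matrix(genotypes: pd.DataFrame) -> DistanceMatrix:
    """Allele-sharing dissimilarity between individuals.

    ``genotypes``: individuals x loci with dosage in [0, 1] (alt-allele
    fraction; 0/1/2 calls divided by 2) and NaN for missing. Each pair is
    averaged over loci typed in both; a pair with no shared locus is an
    error (the matrix must be complete).
    """
    if genotypes.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    X = genotypes.to_numpy(float)
    ids = list(genotypes.index)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if not both.any():
                raise ValueError(f"no shared loci between {ids[i]} and {ids[j]}")
            D[i, j] = D[j, i] = np.abs(X[i, both] - X[j, both]).mean()
    return DistanceMatrix(D, ids)


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to 0.

    On an additive matrix the unique generating tree is recovered exactly.
    """
    if not isinstance(matrix, DistanceMatrix):
        matrix = DistanceMatrix(matrix[1], matrix[0]) if isinstance(matrix, tuple) else DistanceMatrix(matrix)
    return nj(matrix, neg_as_zero=True)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of a tree as frozensets of the smaller
    (canonical) side's leaf names."""
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


@dataclass
class BootstrapResult:
    tree: TreeNode
    supports: dict[frozenset, float] | None  # bipartition -> % of replicates
    n_replicates: int


def bootstrap_support(
    genotypes: pd.DataFrame,
    n_replicates: int = 500,
    seed=0,
) -> BootstrapResult:
    """NJ tree with locus-bootstrap support percentages.

    Loci are resampled with replacement per replicate; the support of
    each internal bipartition of the full-data tree is the percentage of
    replicate trees containing it. Supports are attached to the internal
    nodes (``node.support``, also mirrored into the node name so newick
    output carries them). ``n_replicates=0`` returns the bare tree.
    """
    if genotypes.shape[1] < 10:
        raise ValueError("need at least 10 loci to bootstrap")
    tree = neighbor_joining(dissimilarity_matrix(genotypes))
    if n_replicates == 0:
        return BootstrapResult(tree, None, 0)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(2**31, size=n_replicates)
    base_parts = bipartitions(tree)
    hits = {p: 0 for p in base_parts}
    L = genotypes.shape[1]
    for s in rep_seeds:
        r = np.random.default_rng(int(s))
        cols = r.integers(L, size=L)
        rep = genotypes.iloc[:, cols]
        rep.columns = [f"b{i}" for i in range(L)]
        parts = bipartitions(neighbor_joining(dissimilarity_matrix(rep)))
        for p in base_parts:
            if p in parts:
                hits[p] += 1
    supports = {p: 100.0 * h / n_replicates for p, h in hits.items()}
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        if key in supports:
            node.support = supports[key]
            node.name = f"{supports[key]:.0f}"
    return BootstrapResult(tree, supports, n_replicates)


def group_mean_genotypes(panel: ReferencePanel) -> pd.DataFrame:
    """Accession genotype matrix (alt fraction in [0,1]) indexed by
    accession id — the input for reference-collection trees."""
    return pd.DataFrame(
        panel.genotypes / 2.0, index=panel.acc_ids, columns=panel.locus_ids
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def ancestry_report(
    estimates: Sequence[AncestryEstimate],
    nei_tables: Mapping[str, pd.Series],
    min_loci: int = 20,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-item ancestry summary combining admixture and Nei evidence.

    For each item: the admixture argmax group, its q, the two nearest
    groups by Nei distance, a concordance flag (argmax group among the
    two nearest), and any ambiguous group pairs (reported as alternative
    attributions). Items below the locus floor are listed separately.
    """
    rows, excluded = [], []
    for est in estimates:
        if est.n_loci < min_loci:
            excluded.append(est.item_id)
            continue
        nei = nei_tables[est.item_id].sort_values()
        nearest = list(nei.index[:2])
        top = est.top_group()
        rows.append(
            {
                "item_id": est.item_id,
                "n_loci": est.n_loci,
                "admixture_top_group": top,
                "admixture_top_q": float(est.q.max()),
                "nei_nearest": nearest[0],
                "nei_second": nearest[1] if len(nearest) > 1 else None,
                "concordant": top in nearest,
                "ambiguous_pairs": "; ".join(
                    f"{a}/{b}" for a, b in est.ambiguous_pairs
                ),
            }
        )
    return pd.DataFrame(rows), excluded
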