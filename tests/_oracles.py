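"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations


def sw_bruteforce(q: str, r: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1) -> float:
    """Scalar Gotoh local alignment (affine gaps); O(mn), small inputs only."""
    m, n = len(q), len(r)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            if q[i - 1] == "N" or r[j - 1] == "N":
                s = mismatch
            else:
                s = match if q[i - 1] == r[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def entropy_bruteforce(seq: str, k: int = 5, window: int = 50) -> float:
    """Windowed normalized k-mer entropy, recomputed per window from scratch."""
    import math
    from collections import Counter

    n = len(seq)
    if n < k:
        return 1.0
    win = min(window, n)
    slots = win - k + 1
    norm = math.log(min(4**k, slots))
    best = float("inf")
    for start in range(n - win + 1):
        w = seq[start:start + win]
        counts = Counter(w[i:i + k] for i in range(slots))
        h = -sum((c / slots) * math.log(c / slots) for c in counts.values())
        best = min(best, (h / norm) if norm else 0.0)
    return best


def random_additive_tree(n_taxa: int, rng):
    """Random binary tree with positive branch lengths and its additive
    distance matrix (path lengths). Returns (newick, labels, matrix)."""
    import numpy as np

    labels = [f"T{i}" for i in range(n_taxa)]
    # start from a star over 3 taxa and repeatedly split a random edge
    # represented as a weighted graph over nodes
    next_id = [n_taxa]
    edges = {}  # (a, b) sorted -> weight

    def add_edge(a, b, w):
        edges[tuple(sorted((a, b)))] = w

    nodes = list(range(3))
    center = next_id[0]
    next_id[0] += 1
    for t in range(3):
        add_edge(t, center, float(rng.uniform(0.5, 2.0)))
    for t in range(3, n_taxa):
        # attach taxon t to a random existing edge via a new internal node
        (a, b), w = list(edges.items())[rng.integers(len(edges))]
        del edges[tuple(sorted((a, b)))]
        mid = next_id[0]
        next_id[0] += 1
        split = float(rng.uniform(0.2, 0.8)) * w
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(t, mid, float(rng.uniform(0.5, 2.0)))

    # all-pairs path lengths over the tree graph
    adj = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        di = dists_from(i)
        for j in range(n_taxa):
            D[i, j] = di[j]
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    np.fill_diagonal(D, 0.0)
    return labels, D, edges
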