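"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (explicit loops, exact rational
arithmetic) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

MISSING = -1


def fst_site_oracle(p_a: float, p_b: float) -> float:
    """Direct substitution into the two-population F_ST ratio,
    clipped at 1; NaN when both fixed for the same allele."""
    denom = p_a * (1 - p_a) + p_b * (1 - p_b)
    if denom == 0:
        return float("nan") if p_a == p_b else 1.0
    return min(1.0, (p_a - p_b) ** 2 / denom)


def pi_site_oracle(dosages) -> float:
    """Exhaustive pair sum of |g_i - g_j| / 2 over non-missing calls,
    normalized by n(n-1)."""
    d = [g for g in dosages if g != MISSING]
    n = len(d)
    if n < 2:
        return float("nan")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += abs(d[i] - d[j]) / 2.0
    return total / (n * (n - 1))


def pop_alt_freq_oracle(column) -> float:
    called = [g for g in column if g != MISSING]
    if not called:
        return float("nan")
    return sum(called) / (2.0 * len(called))


def window_fst_oracle(dosage_a, dosage_b, site_pos, start, end, min_snps=3):
    """Unweighted mean per-site F_ST over sites with pos-1 in [start, end)."""
    vals = []
    for j, pos in enumerate(site_pos):
        if not (start <= pos - 1 < end):
            continue
        pa = pop_alt_freq_oracle(dosage_a[:, j])
        pb = pop_alt_freq_oracle(dosage_b[:, j])
        if math.isnan(pa) or math.isnan(pb):
            continue
        v = fst_site_oracle(pa, pb)
        if not math.isnan(v):
            vals.append(v)
    if len(vals) < min_snps:
        return float("nan")
    return sum(vals) / len(vals)


def window_pi_oracle(dosage_pop, site_pos, start, end):
    total = 0.0
    for j, pos in enumerate(site_pos):
        if not (start <= pos - 1 < end):
            continue
        v = pi_site_oracle(dosage_pop[:, j])
        if not math.isnan(v):
            total += v
    return total / (end - start)


def grm_oracle(dosage) -> np.ndarray:
    """Double-loop variance-standardized relationship matrix; missing
    entries contribute zero after standardization."""
    n, m = dosage.shape
    cols = []
    for j in range(m):
        col = dosage[:, j]
        called = col[col != MISSING]
        if len(called) == 0:
            continue
        p = called.sum() / (2.0 * len(called))
        if p <= 0 or p >= 1:
            continue
        z = np.zeros(n)
        for i in range(n):
            if col[i] != MISSING:
                z[i] = (col[i] - 2 * p) / math.sqrt(2 * p * (1 - p))
        cols.append(z)
    used = len(cols)
    r = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            r[i, k] = sum(z[i] * z[k] for z in cols) / used
    return r


def p_distance_oracle(dosage) -> np.ndarray:
    n, m = dosage.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = cnt = 0
            for s in range(m):
                a, b = dosage[i, s], dosage[j, s]
                if a == MISSING or b == MISSING:
                    continue
                num += abs(int(a) - int(b)) / 2.0
                cnt += 1
            d[i, j] = d[j, i] = num / cnt
    return d


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact rational enumeration of the conditional heterozygote-count
    distribution; p-value sums outcomes no more probable than observed."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * min(n_hom_ref, n_hom_alt) + n_het
    weights = {}
    for k in range(n_a % 2, n_a + 1, 2):
        minor_hom = (n_a - k) // 2
        major_hom = n - k - minor_hom
        if major_hom < 0:
            continue
        w = Fraction(math.factorial(n), math.factorial(major_hom)
                     * math.factorial(k) * math.factorial(minor_hom)) * 2**k
        weights[k] = w
    total = sum(weights.values())
    probs = {k: Fraction(w, total) for k, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hypergeom_upper_oracle(k: int, m_universe: int, m_set: int, n_draw: int) -> float:
    """P(X >= k) by exact rational summation of hypergeometric terms."""
    total = Fraction(0)
    denom = math.comb(m_universe, n_draw)
    for x in range(k, min(m_set, n_draw) + 1):
        if n_draw - x > m_universe - m_set:
            continue
        total += Fraction(math.comb(m_set, x) * math.comb(m_universe - m_set, n_draw - x), denom)
    return float(min(total, Fraction(1)))


def bh_oracle(pvals):
    """Step-up arithmetic from the definition q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m - 1, -1, -1):
        running = min(running, m * pvals[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree with branch lengths in [0.1, 2];
    returns (names, pairwise path-length matrix, newick string).

    Built by sequential leaf attachment: each new leaf splits a random
    existing edge, guaranteeing an additive matrix.
    """
    # adjacency on nodes; leaves 0..n-1
    names = [f"t{i}" for i in range(n_taxa)]
    edges = {}  # frozenset({u,v}) -> length
    next_node = n_taxa

    def add_edge(u, v, w):
        edges[frozenset((u, v))] = w

    # start with 3-leaf star around internal node
    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, center, rng.uniform(0.1, 2))
    for leaf in range(3, n_taxa):
        e = list(edges)[rng.integers(len(edges))]
        u, v = tuple(e)
        w = edges.pop(e)
        mid = next_node
        next_node += 1
        cut = rng.uniform(0.25, 0.75) * w
        add_edge(u, mid, cut)
        add_edge(mid, v, w - cut)
        add_edge(leaf, mid, rng.uniform(0.1, 2))

    # path lengths by BFS per leaf
    adj = {}
    for e, w in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + w
                    stack.append(nxt)
        for dst in range(n_taxa):
            dist[src, dst] = seen[dst]
    return names, dist


def patristic_from_newick(newick: str):
    """Leaf-to-leaf path lengths parsed from a newick string (dendropy)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tree.taxon_namespace]
    n = len(labels)
    out = {}
    for i, ti in enumerate(tree.taxon_namespace):
        for tj in tree.taxon_namespace:
            out[(ti.label, tj.label)] = pdm.patristic_distance(ti, tj)
    return out
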