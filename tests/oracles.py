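"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's data structures and shortcuts:
naive loops, direct string comparison, scipy matrix exponentials, and
exhaustive topology enumeration, so they can disagree with the
implementation when the implementation is wrong.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Tandem repeats: enumerate every (unit length, offset) directly
# ---------------------------------------------------------------------------

def brute_force_tandem_candidates(seq, min_unit, max_unit, min_copies, min_identity):
    """All left-maximal tandem-array candidates as comparable tuples
    (unit_length, start, length, copies, identity)."""
    seq = seq.upper()
    n = len(seq)
    max_unit = min(max_unit, n // 2)
    out = set()

    def ident(a, b, p):
        return sum(seq[a + i] == seq[b + i] for i in range(p)) / p

    for p in range(min_unit, max_unit + 1):
        for s in range(0, n - 2 * p + 1):
            if seq[s] != seq[s + p]:
                continue  # arrays anchor on a matching position
            if s >= p and ident(s - p, s, p) >= min_identity:
                continue  # extendable one full copy to the left
            k = 1
            while s + (k + 1) * p <= n and ident(s + (k - 1) * p, s + k * p, p) >= min_identity:
                k += 1
            a = s + k * p
            m = 0
            while m < p and a + m < n and seq[a + m] == seq[a - p + m]:
                m += 1
            copies = k + m / p
            if copies < min_copies:
                continue
            matches = sum(
                sum(seq[s + j * p + i] == seq[s + (j + 1) * p + i] for i in range(p))
                for j in range(k - 1)
            ) + m
            compared = p * (k - 1) + m
            identity = matches / compared if compared else 1.0
            if identity < min_identity:
                continue
            out.add((p, s, k * p + m, round(copies, 3), round(identity, 4)))
    return out


# ---------------------------------------------------------------------------
# K80 process: matrix-exponential expectation of the p-distance
# ---------------------------------------------------------------------------

def k80_rate_matrix(kappa):
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    # order A, C, G, T; transitions A<->G, C<->T
    Q = np.full((4, 4), beta)
    Q[0, 2] = Q[2, 0] = alpha
    Q[1, 3] = Q[3, 1] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def expected_p_distance(t1, t2, kappa, pi_root):
    """P(leaf1 != leaf2) for two leaves hanging off one root at branch
    lengths t1, t2, root drawn from pi_root; via scipy's expm."""
    from scipy.linalg import expm

    Q = k80_rate_matrix(kappa)
    P1 = expm(Q * t1)
    P2 = expm(Q * t2)
    p_same = sum(
        pi_root[r] * sum(P1[r, x] * P2[r, x] for x in range(4)) for r in range(4)
    )
    return 1.0 - p_same


# ---------------------------------------------------------------------------
# Exhaustive least-squares topology search for 5 taxa
# ---------------------------------------------------------------------------

def _caterpillar_splits(cherry1, cherry2):
    return frozenset([frozenset(cherry1), frozenset(cherry2)])


def all_five_taxon_topologies(taxa):
    """The 15 unrooted binary topologies on five leaves, each as its pair of
    nontrivial splits (every such tree is a caterpillar: two cherries)."""
    taxa = list(taxa)
    seen = set()
    for c1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in c1]
        for c2 in itertools.combinations(rest, 2):
            key = _caterpillar_splits(c1, c2)
            if key not in seen:
                seen.add(key)
    return sorted(seen, key=lambda s: sorted(map(sorted, s)))


def least_squares_rss(topology, taxa, dist):
    """Ordinary least-squares fit of the 7 branch lengths of a 5-taxon
    caterpillar; returns the residual sum of squares."""
    (c1, c2) = sorted(topology, key=lambda s: sorted(s))
    c1, c2 = sorted(c1), sorted(c2)
    middle = [t for t in taxa if t not in c1 and t not in c2]
    # edges: pendants in fixed order + internal u-x and x-w
    order = c1 + middle + c2
    e_index = {t: i for i, t in enumerate(order)}
    E_UX, E_XW = 5, 6
    rows, y = [], []
    for a, b in itertools.combinations(taxa, 2):
        row = [0.0] * 7
        row[e_index[a]] = 1
        row[e_index[b]] = 1
        in1 = {a, b} & set(c1)
        in2 = {a, b} & set(c2)
        if len(in1) == 1 and len(in2) == 1:
            row[E_UX] = 1
            row[E_XW] = 1
        elif len(in1) == 1 and not in2 and len({a, b} & set(middle)) == 1:
            row[E_UX] = 1
        elif len(in2) == 1 and not in1 and len({a, b} & set(middle)) == 1:
            row[E_XW] = 1
        rows.append(row)
        y.append(dist[frozenset((a, b))])
    A = np.array(rows)
    yv = np.array(y)
    coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
    rss = float(((A @ coef - yv) ** 2).sum())
    return rss


def best_ls_topology(taxa, dist):
    tops = all_five_taxon_topologies(taxa)
    scored = [(least_squares_rss(t, list(taxa), dist), t) for t in tops]
    scored.sort(key=lambda x: x[0])
    return scored[0][1]


# ---------------------------------------------------------------------------
# Random additive trees
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_leaves):
    """Random binary topology with branch lengths in [0.05, 0.6]; returns
    (newick, {frozenset(pair): path distance})."""
    labels = [f"T{i}" for i in range(n_leaves)]
    nodes = {lab: (lab, None) for lab in labels}
    depth = {lab: {lab: 0.0} for lab in labels}  # node -> leaf -> distance
    newick = {lab: lab for lab in labels}
    active = list(labels)
    dist = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la = round(float(rng.uniform(0.05, 0.6)), 3)
        lb = round(float(rng.uniform(0.05, 0.6)), 3)
        for x, dx in depth[a].items():
            for y, dy in depth[b].items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        new = f"({newick[a]}:{la},{newick[b]}:{lb})"
        key = f"N{len(newick)}"
        newick[key] = new
        depth[key] = {x: d + la for x, d in depth[a].items()}
        depth[key].update({y: d + lb for y, d in depth[b].items()})
        active = [x for x in active if x not in (a, b)] + [key]
    return newick[active[0]] + ";", dist
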