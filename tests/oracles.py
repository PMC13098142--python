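"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — transitive-closure merging, full
hypergeometric enumeration, explicit permutation enumeration, exhaustive
ancestral-assignment sums — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- cluster scanning -------------------------------------------------------

def gap_merge_oracle(hits, max_intervening, min_distinct):
    """Union-find merge of T6SS hits whenever the number of non-hit genes
    strictly between a pair is within the threshold; then filter by distinct
    component count.

    ``hits``: sorted list of (ordinal, component).  Returns (clusters,
    leftovers) where clusters are lists of hits and leftovers the members of
    discarded groups.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ordinals = [o for o, _ in hits]
    hit_set = set(ordinals)
    for i in range(n):
        for j in range(i + 1, n):
            between = range(ordinals[i] + 1, ordinals[j])
            non_hit = sum(1 for o in between if o not in hit_set)
            if non_hit <= max_intervening:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    clusters, leftovers = [], []
    for group in groups.values():
        group.sort()
        if len({c for _, c in group}) >= min_distinct:
            clusters.append(group)
        else:
            leftovers.extend(group)
    clusters.sort(key=lambda g: g[0][0])
    leftovers.sort()
    return clusters, leftovers


# --- exact tests ------------------------------------------------------------

def _log_hypergeom_pmf(k, r1, r2, c1):
    """log P(X = k) for the 2x2 table family with fixed margins."""
    n = r1 + r2

    def logC(a, b):
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    return logC(r1, k) + logC(r2, c1 - k) - logC(n, c1)


def fisher_enumeration(a, b, c, d, side="two_sided", rel_tol=1e-7):
    """Fisher exact p by full enumeration over the margin-constrained family."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    logs = {k: _log_hypergeom_pmf(k, r1, r2, c1) for k in range(lo, hi + 1)}
    obs = logs[a]
    if side == "greater":
        ks = [k for k in logs if k >= a]
    elif side == "less":
        ks = [k for k in logs if k <= a]
    else:
        cutoff = obs + math.log1p(rel_tol)
        ks = [k for k, lg in logs.items() if lg <= cutoff]
    return float(sum(math.exp(logs[k]) for k in ks))


def bh_stepup_oracle(p_values):
    """Direct formula: adjusted p_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            p_values[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def mann_whitney_enumeration(x, y, side):
    """Exact Mann-Whitney p by enumerating all rank assignments (no ties)."""
    x, y = list(x), list(y)
    nx_, ny_ = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    obs_u = sum(1 for xi in x for yi in y if xi > yi)
    count = 0
    total = 0
    for combo in itertools.combinations(range(nx_ + ny_), nx_):
        chosen = set(combo)
        u = sum(1 for i in chosen for j in range(nx_ + ny_)
                if j not in chosen and i > j)
        total += 1
        if side == "greater":
            count += u >= obs_u
        elif side == "less":
            count += u <= obs_u
        else:
            mean = nx_ * ny_ / 2
            count += abs(u - mean) >= abs(obs_u - mean) - 1e-12
    return count / total


# --- trees ------------------------------------------------------------------

def patristic_lca_oracle(tree):
    """Tip-pair path sums via root paths and the lowest common ancestor."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path

    def depth(path):
        return sum((n.edge.length or 0.0) for n in path[:-1])

    dist = {}
    labels = sorted(paths)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            set_b = set(id(n) for n in paths[b])
            lca = next(n for n in paths[a] if id(n) in set_b)
            da = 0.0
            for n in paths[a]:
                if n is lca:
                    break
                da += n.edge.length or 0.0
            db = 0.0
            for n in paths[b]:
                if n is lca:
                    break
                db += n.edge.length or 0.0
            dist[(a, b)] = dist[(b, a)] = da + db
    return dist


def f81_transition_oracle(t, pi):
    """Independent closed-form two-state F81 transition matrix."""
    pi = np.asarray(pi, dtype=float)
    nu = 1.0 - float(pi @ pi)
    e = math.exp(-t / nu)
    return np.array([
        [pi[0] + (1 - pi[0]) * e, pi[1] * (1 - e)],
        [pi[0] * (1 - e), pi[1] + (1 - pi[1]) * e],
    ])


def exhaustive_marginals(tree, tip_states, pi, states=("plasmid", "chromosome")):
    """Marginal ancestral posteriors by summing over every assignment of
    states to internal nodes (2^k terms)."""
    pi = np.asarray(pi, dtype=float)
    idx = {s: i for i, s in enumerate(states)}
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    like_by_node: dict[int, np.ndarray] = {}
    total = 0.0
    accum = {id(n): np.zeros(2) for n in nodes}
    for assignment in itertools.product(range(2), repeat=len(internal)):
        state_of = {id(n): s for n, s in zip(internal, assignment)}
        for n in nodes:
            if n.is_leaf():
                state_of[id(n)] = idx[tip_states[n.taxon.label]]
        lik = pi[state_of[id(tree.seed_node)]]
        for n in nodes:
            if n is tree.seed_node:
                continue
            P = f81_transition_oracle(n.edge.length or 0.0, pi)
            lik *= P[state_of[id(n.parent_node)], state_of[id(n)]]
        total += lik
        for n in nodes:
            accum[id(n)][state_of[id(n)]] += lik
    return {n: accum[id(n)] / total for n in nodes}, total


def deepest_common_rank(taxonomies):
    """Rank walk: first of species..class at which all taxonomies agree."""
    for i, rank in enumerate(("species", "genus", "family", "order", "class")):
        if len({t[i] for t in taxonomies}) == 1:
            return rank
    return None


def partitions(collection):
    """All set partitions of a list (Bell-number enumeration)."""
    collection = list(collection)
    if len(collection) == 1:
        yield [collection]
        return
    first, rest = collection[0], collection[1:]
    for smaller in partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller
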