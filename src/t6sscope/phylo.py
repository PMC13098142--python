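"""Patristic distances, closest-homolog ECDFs, co-resident comparisons and
two-state ancestral reconstruction of genomic compartment.

The ancestral reconstruction treats the replicon compartment of each
TssC-like sequence — plasmid (P) or chromosome (C) — as a binary character
evolving on a fixed rooted tree under the F81 model.  With equilibrium
frequencies ``pi = (pi_P, pi_C)`` the transition probability is

    P(i -> j, t) = pi_j + (delta_ij - pi_j) * exp(-t / nu),

where ``nu = 1 - sum_s pi_s**2`` rescales branch lengths so the expected
substitution rate is one.  Marginal posteriors at every node come from one
post-order (pruning) pass and one pre-order pass; the MPPA criterion then
selects, per node, the subset of states (taken in decreasing posterior
order) that minimises a Brier-style prediction error, so genuinely
ambiguous nodes keep both states.  A branch counts as a transition event
iff the MPPA sets of its parent and child are disjoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

STATES = ("plasmid", "chromosome")


@dataclass
class TipMetadata:
    """Per-tip annotations: compartment, host and identity-cluster id."""

    compartment: dict[str, str]
    host: dict[str, str] = field(default_factory=dict)
    identity_cluster: dict[str, str] = field(default_factory=dict)


@dataclass
class AncestralReconstruction:
    posteriors: dict[str, dict[str, float]]   # node id -> state -> posterior
    mppa: dict[str, frozenset]                # node id -> selected state set
    pi: dict[str, float]
    log_likelihood: float
    node_names: list


@dataclass
class ClosestHomologResult:
    per_tip: pd.DataFrame  # tip, d_plasmid, d_chromosome, zero_flags
    undefined_compartments: list = field(default_factory=list)


def load_tree(source: str) -> dendropy.Tree:
    """Parse a rooted Newick tree (string or file path)."""
    data = source
    if "(" not in source:  # path, not newick text
        with open(source) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(data=data, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises various parse errors
        raise ValueError(f"malformed newick: {exc}") from exc
    return tree


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels must be unique")
    return labels


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric tip-to-tip path-length matrix (cophenetic distances)."""
    labels = _tip_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    index = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    mat = np.zeros((n, n), dtype=float)
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = float(pdm.patristic_distance(index[a], index[labels[j]]))
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF support points and heights (reaches 1)."""
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        return np.array([]), np.array([])
    return v, np.arange(1, v.size + 1) / v.size


def closest_homolog(
    distances: pd.DataFrame,
    metadata: TipMetadata,
) -> ClosestHomologResult:
    """Minimum patristic distance from each plasmid tip to either compartment.

    For each plasmid-encoded sequence the closest homolog on another plasmid
    and on a chromosome is found by exhaustive minimisation over the
    distance matrix.  Tips sharing an identity cluster (near-identical
    protein) with a tip of a given compartment but a *different* genomic
    context are assigned distance zero for that compartment.
    """
    tips = list(distances.index)
    missing = [t for t in tips if t not in metadata.compartment]
    if missing:
        raise ValueError(f"tips missing compartment metadata: {missing[:5]}")
    by_compartment = {s: [t for t in tips if metadata.compartment[t] == s]
                      for s in STATES}
    undefined = [s for s in STATES if len(by_compartment[s]) < (2 if s == "plasmid" else 1)]

    rows = []
    for tip in by_compartment["plasmid"]:
        row: dict = {"tip": tip}
        cluster = metadata.identity_cluster.get(tip)
        for s in STATES:
            others = [t for t in by_compartment[s] if t != tip]
            if not others:
                row[f"d_{s}"] = math.nan
                row[f"zero_{s}"] = False
                continue
            zero = cluster is not None and any(
                metadata.identity_cluster.get(t) == cluster for t in others)
            d = 0.0 if zero else float(distances.loc[tip, others].min())
            row[f"d_{s}"] = d
            row[f"zero_{s}"] = bool(zero)
        rows.append(row)
    return ClosestHomologResult(pd.DataFrame(rows), undefined)


def coresident_comparison(
    distances: pd.DataFrame,
    metadata: TipMetadata,
) -> tuple[pd.DataFrame, float | None]:
    """Co-resident vs globally closest plasmid homolog, per dual-compartment host.

    For every host carrying sequences in both compartments, take each
    chromosomal tip's minimum distance to a plasmid tip of the *same host*
    (co-resident) and to any plasmid tip (global closest).  The one-sided
    Mann-Whitney test asks whether co-resident distances stochastically
    exceed the global minima (local duplication would make them equal).
    """
    from .stats import mann_whitney_u

    tips = list(distances.index)
    hosts: dict[str, dict[str, list]] = {}
    for tip in tips:
        host = metadata.host.get(tip)
        if host is None:
            continue
        hosts.setdefault(host, {"plasmid": [], "chromosome": []})[
            metadata.compartment[tip]].append(tip)
    all_plasmid = [t for t in tips if metadata.compartment[t] == "plasmid"]

    rows = []
    for host, groups in sorted(hosts.items()):
        if not groups["plasmid"] or not groups["chromosome"]:
            continue
        for chrom_tip in groups["chromosome"]:
            cores = float(distances.loc[chrom_tip, groups["plasmid"]].min())
            global_min = float(
                distances.loc[chrom_tip, [t for t in all_plasmid if t != chrom_tip]].min())
            rows.append({"host": host, "chromosome_tip": chrom_tip,
                         "coresident": cores, "global_closest": global_min})
    paired = pd.DataFrame(rows)
    p = None
    if len(paired) >= 2 and paired["coresident"].var() + paired["global_closest"].var() > 0:
        p = mann_whitney_u(paired["coresident"], paired["global_closest"],
                           side="greater").p
    return paired, p


# ---------------------------------------------------------------------------
# F81 two-state ancestral reconstruction


def _f81_transition(t: float, pi: np.ndarray) -> np.ndarray:
    """2x2 transition matrix P(i->j, t) under rate-normalised F81."""
    nu = 1.0 - float(np.sum(pi**2))
    decay = math.exp(-t / nu) if nu > 0 else 0.0
    P = np.array([[pi[0], pi[1]], [pi[0], pi[1]]])
    P = P + (np.eye(2) - P) * decay
    return P


def ancestral_states(
    tree: dendropy.Tree,
    tip_states: dict[str, str],
    pi: tuple[float, float] | None = None,
) -> AncestralReconstruction:
    """Marginal posteriors and MPPA state sets for every node.

    Parameters
    ----------
    tree
        Rooted tree with branch lengths (treated as supplied; not re-rooted).
    tip_states
        Tip label -> 'plasmid' | 'chromosome'.
    pi
        Equilibrium frequencies (plasmid, chromosome); default = observed
        tip-state proportions (clamped away from 0/1 when both states occur
        in neither direction).

    Raises
    ------
    ValueError
        If tip states are missing, or all branch lengths are zero while tip
        states conflict (unidentifiable).
    """
    leaves = _tip_labels(tree)
    missing = [t for t in leaves if t not in tip_states]
    if missing:
        raise ValueError(f"tips missing compartment state: {missing[:5]}")
    observed = [tip_states[t] for t in leaves]
    if pi is None:
        p_frac = observed.count("plasmid") / len(observed)
        p_frac = min(max(p_frac, 1.0 / (len(observed) + 1)),
                     1.0 - 1.0 / (len(observed) + 1))
        pi_vec = np.array([p_frac, 1.0 - p_frac])
    else:
        pi_vec = np.asarray(pi, dtype=float)
        if not np.isclose(pi_vec.sum(), 1.0):
            raise ValueError("pi must sum to 1")

    lengths = [e.length or 0.0 for e in tree.preorder_edge_iter()
               if e.head_node is not tree.seed_node]
    if all(l == 0.0 for l in lengths) and len(set(observed)) > 1:
        raise ValueError("all branch lengths zero with conflicting tip states: "
                         "reconstruction unidentifiable")

    # assign stable node ids
    node_names = []
    for idx, node in enumerate(tree.preorder_node_iter()):
        node.ar_id = node.taxon.label if node.is_leaf() else f"n{idx}"
        node_names.append(node.ar_id)

    state_index = {s: i for i, s in enumerate(STATES)}

    # post-order (pruning) pass: partial likelihoods L[v][s] = P(tip data
    # below v | state of v = s)
    down: dict[str, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(2)
            vec[state_index[tip_states[node.taxon.label]]] = 1.0
            down[node.ar_id] = vec
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                P = _f81_transition(child.edge.length or 0.0, pi_vec)
                vec = vec * (P @ down[child.ar_id])
            down[node.ar_id] = vec

    root = tree.seed_node
    root_like = pi_vec * down[root.ar_id]
    likelihood = float(root_like.sum())
    if likelihood <= 0:
        raise ValueError("zero likelihood: conflicting data on zero-length tree")

    # pre-order pass: up[v][s] aggregates everything outside v's subtree
    up: dict[str, np.ndarray] = {root.ar_id: pi_vec.copy()}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            # parent's outside message times siblings' contributions
            msg = up[node.ar_id].copy()
            for sibling in node.child_nodes():
                if sibling is child:
                    continue
                P_sib = _f81_transition(sibling.edge.length or 0.0, pi_vec)
                msg = msg * (P_sib @ down[sibling.ar_id])
            P = _f81_transition(child.edge.length or 0.0, pi_vec)
            up[child.ar_id] = P.T @ msg

    posteriors: dict[str, dict[str, float]] = {}
    mppa: dict[str, frozenset] = {}
    for node in tree.preorder_node_iter():
        joint = down[node.ar_id] * up[node.ar_id]
        post = joint / joint.sum()
        posteriors[node.ar_id] = {s: float(post[i]) for i, s in enumerate(STATES)}
        mppa[node.ar_id] = _mppa_select(post)

    return AncestralReconstruction(
        posteriors=posteriors, mppa=mppa,
        pi={s: float(pi_vec[i]) for i, s in enumerate(STATES)},
        log_likelihood=math.log(likelihood), node_names=node_names)


def _mppa_select(post: np.ndarray) -> frozenset:
    """Pick the top-k posterior states minimising the Brier prediction error.

    Predicting a set S uniformly scores sum_s (1[s in S]/|S| - p_s)^2;
    candidate sets are prefixes of the posterior-sorted state list.  Ties in
    the error (including tied posteriors) keep the larger, more conservative
    set.
    """
    order = np.argsort(-post, kind="mergesort")
    best_set: frozenset | None = None
    best_err = math.inf
    for k in range(1, len(post) + 1):
        chosen = order[:k]
        pred = np.zeros_like(post)
        pred[chosen] = 1.0 / k
        err = float(np.sum((pred - post) ** 2))
        if err < best_err - 1e-12:
            best_err = err
            best_set = frozenset(STATES[i] for i in chosen)
        elif abs(err - best_err) <= 1e-12:
            # tie: keep the larger (more conservative) set
            best_set = frozenset(STATES[i] for i in chosen)
    return best_set  # type: ignore[return-value]


def count_transitions(
    reconstruction: AncestralReconstruction,
    tree: dendropy.Tree,
) -> dict[str, int]:
    """Compartment-switch events: branches whose parent/child MPPA sets are
    disjoint contribute one event in the parent-to-child direction;
    ambiguous (overlapping) branches contribute none."""
    counts = {"plasmid->chromosome": 0, "chromosome->plasmid": 0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_set = reconstruction.mppa[node.parent_node.ar_id]
        child_set = reconstruction.mppa[node.ar_id]
        if parent_set & child_set:
            continue
        src = next(iter(parent_set))
        dst = next(iter(child_set))
        counts[f"{src}->{dst}"] += 1
    return counts


def posteriors_to_frame(reconstruction: AncestralReconstruction) -> pd.DataFrame:
    rows = []
    for node_id in reconstruction.node_names:
        post = reconstruction.posteriors[node_id]
        rows.append({
            "node": node_id,
            "p_plasmid": post["plasmid"],
            "p_chromosome": post["chromosome"],
            "mppa": "|".join(sorted(reconstruction.mppa[node_id])),
        })
    return pd.DataFrame(rows)


def annotated_newick(tree: dendropy.Tree, reconstruction: AncestralReconstruction) -> str:
    """Newick with MPPA state sets as node comments."""
    for node in tree.preorder_node_iter():
        states = "|".join(sorted(reconstruction.mppa[node.ar_id]))
        node.annotations.add_new("mppa", states)
    return tree.as_string(schema="newick", suppress_rooting=True,
                          suppress_annotations=False).strip()
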