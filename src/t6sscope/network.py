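"""Replicon-protein bipartite networks, Louvain transfer communities,
plasmid ANI networks, core proteomes and host-range grading.

The transfer network links replicon nodes to homologous-protein-cluster
(HPC) nodes; replicons sharing many near-identical T6SS proteins become
densely connected through common HPC nodes.  Community detection runs
Louvain modularity maximisation on the *weighted replicon projection*
(edge weight = number of shared HPCs), since modularity on the bipartite
graph itself is ill-posed; singleton replicons are reported as their own
communities.

Host-range grades follow the taxonomic depth a community spans:
I same species, II same genus, III same family, IV same order, V same
class; members disagreeing at class rank are flagged ``beyond V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

RANKS = ("species", "genus", "family", "order", "class")
GRADE_BY_RANK = {"species": "I", "genus": "II", "family": "III",
                 "order": "IV", "class": "V"}


@dataclass
class TransferCommunity:
    community_id: int
    members: list  # replicon ids
    compartment_mix: str = ""  # plasmid_only | chromosome_only | mixed
    ptus: list = field(default_factory=list)
    host_range_grade: str | None = None
    shared_is_family: bool | None = None

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def build_bipartite(hpc_table: pd.DataFrame, metadata: pd.DataFrame) -> nx.Graph:
    """Bipartite graph from an HPC membership table.

    Replicon nodes carry compartment/taxonomy/PTU attributes from
    ``metadata``; HPC nodes carry their member count.  Protein multiplicity
    collapses to a single (replicon, HPC) edge.
    """
    meta = metadata.set_index("replicon_id")
    missing = set(hpc_table["replicon_id"].astype(str)) - set(meta.index.astype(str))
    if missing:
        raise ValueError(f"replicon(s) missing from metadata: {sorted(missing)[:5]}")
    graph = nx.Graph()
    for replicon_id, row in meta.iterrows():
        graph.add_node(
            str(replicon_id), bipartite="replicon",
            compartment="plasmid" if row.get("kind", "plasmid") == "plasmid" else "chromosome",
            taxonomy=tuple(row.get(r, "") for r in RANKS),
            ptu=str(row.get("ptu", "none")),
        )
    edges = hpc_table[["replicon_id", "hpc_id"]].drop_duplicates()
    for hpc_id, count in edges["hpc_id"].value_counts().items():
        graph.add_node(str(hpc_id), bipartite="hpc", member_count=int(count))
    graph.add_edges_from(
        (str(r), str(h)) for r, h in zip(edges["replicon_id"], edges["hpc_id"]))
    return graph


def replicon_projection(network: nx.Graph) -> nx.Graph:
    """Weighted projection onto replicon nodes (weight = shared HPC count)."""
    replicons = [n for n, d in network.nodes(data=True) if d.get("bipartite") == "replicon"]
    return nx.bipartite.weighted_projected_graph(network, replicons)


def detect_communities(
    network: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
) -> list[TransferCommunity]:
    """Louvain communities on the weighted replicon projection.

    Deterministic under a fixed seed.  Every replicon node lands in exactly
    one community; isolated replicons come back as singletons.
    """
    projection = replicon_projection(network)
    if projection.number_of_nodes() == 0:
        return []
    partition = nx.community.louvain_communities(
        projection, weight="weight", resolution=resolution, seed=seed)
    communities = []
    for members in sorted((sorted(p) for p in partition), key=lambda m: m[0]):
        compartments = {network.nodes[m].get("compartment", "plasmid") for m in members}
        mix = ("mixed" if len(compartments) > 1
               else f"{next(iter(compartments))}_only")
        ptus = sorted({network.nodes[m].get("ptu", "none") for m in members} - {"none"})
        community = TransferCommunity(
            community_id=len(communities), members=list(members),
            compartment_mix=mix, ptus=ptus)
        if len(members) >= 2:
            taxonomies = [network.nodes[m].get("taxonomy") for m in members]
            taxonomies = [t for t in taxonomies if t]
            if len(taxonomies) >= 2:
                community.host_range_grade = host_range_grade(taxonomies)
        communities.append(community)
    return communities


def host_range_grade(taxonomies) -> str:
    """Grade = shallowest rank at which all members agree (I..V).

    ``taxonomies`` holds (species, genus, family, order, class) tuples.
    Disagreement at class rank yields ``beyond V``.
    """
    taxonomies = list(taxonomies)
    if len(taxonomies) < 2:
        raise ValueError("host_range_grade needs >= 2 taxonomies")
    for tax in taxonomies:
        if len(tax) != len(RANKS):
            raise ValueError("each taxonomy must have species..class ranks")
    for i, rank in enumerate(RANKS):
        values = {tax[i] for tax in taxonomies}
        if len(values) == 1:
            return GRADE_BY_RANK[rank]
    return "beyond V"


def core_proteome(
    network: nx.Graph,
    ptu: str,
    threshold: float = 0.8,
) -> set[str]:
    """HPCs present in at least ``threshold`` of the PTU's member replicons."""
    members = [n for n, d in network.nodes(data=True)
               if d.get("bipartite") == "replicon" and d.get("ptu") == ptu]
    if len(members) < 2:
        raise ValueError(f"PTU {ptu!r} has fewer than 2 members")
    counts: dict[str, int] = {}
    for m in members:
        for hpc in network.neighbors(m):
            counts[hpc] = counts.get(hpc, 0) + 1
    need = threshold * len(members)
    return {hpc for hpc, c in counts.items() if c >= need}


def ani_network(ani_table: pd.DataFrame, min_cov: float = 0.5) -> nx.Graph:
    """Plasmid similarity graph from pairwise ANI with aligned-fraction gating.

    ``ani_table`` columns: query, subject, ani, coverage (aligned fraction
    of the shorter replicon).  An edge appears iff coverage >= ``min_cov``
    (inclusive); weight = ANI.  Self-pairs are ignored.
    """
    graph = nx.Graph()
    for _, row in ani_table.iterrows():
        q, s = str(row["query"]), str(row["subject"])
        ani, cov = float(row["ani"]), float(row["coverage"])
        if not (0.0 <= ani <= 1.0 and 0.0 <= cov <= 1.0):
            raise ValueError(f"ANI and coverage must lie in [0,1]: {q} vs {s}")
        graph.add_node(q)
        graph.add_node(s)
        if q == s:
            continue
        if cov >= min_cov:
            graph.add_edge(q, s, weight=ani)
    return graph


def community_cross_tab(
    communities: list[TransferCommunity],
    network: nx.Graph,
    neighborhood_families: dict[str, frozenset] | None = None,
) -> tuple[pd.DataFrame, dict[int, bool]]:
    """Chord-style PTU/chromosome co-membership table plus shared-IS flags.

    Entities are PTU labels for plasmids (``PTU NA`` for unassigned) and
    ``Chr`` for chromosomes.  Each unordered entity pair co-occurring in a
    community contributes one count.  When ``neighborhood_families`` maps
    replicon -> IS families near its T6SS locus, a community's flag is set
    if some family occurs near members of both compartments.
    """
    pair_counts: dict[tuple[str, str], int] = {}
    shared_flags: dict[int, bool] = {}
    for community in communities:
        entities = set()
        fam_by_compartment: dict[str, set] = {"plasmid": set(), "chromosome": set()}
        for m in community.members:
            data = network.nodes[m]
            if data.get("compartment") == "chromosome":
                entities.add("Chr")
            else:
                ptu = data.get("ptu", "none")
                entities.add("PTU NA" if ptu in ("none", "") else ptu)
            if neighborhood_families and m in neighborhood_families:
                fam_by_compartment[data.get("compartment", "plasmid")].update(
                    neighborhood_families[m])
        for x in entities:
            for y in entities:
                if x < y:
                    pair_counts[(x, y)] = pair_counts.get((x, y), 0) + 1
        shared_flags[community.community_id] = bool(
            fam_by_compartment["plasmid"] & fam_by_compartment["chromosome"])
        community.shared_is_family = shared_flags[community.community_id]
    table = pd.DataFrame(
        [{"entity_a": a, "entity_b": b, "n_communities": n}
         for (a, b), n in sorted(pair_counts.items())],
        columns=["entity_a", "entity_b", "n_communities"])
    return table, shared_flags


def communities_to_frame(communities: list[TransferCommunity]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "community_id": c.community_id,
            "n_members": len(c.members),
            "members": ",".join(c.members),
            "compartment_mix": c.compartment_mix,
            "ptus": ",".join(c.ptus),
            "host_range_grade": c.host_range_grade or "",
            "shared_is_family": c.shared_is_family,
        } for c in communities],
        columns=["community_id", "n_members", "members", "compartment_mix",
                 "ptus", "host_range_grade", "shared_is_family"])
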