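"""Synthetic annotated replicons, protein-cluster tables and trees.

Every downstream stage of the pipeline is exercised on data generated here,
with the planted ground truth recorded so recovery can be checked exactly.
The generator emulates the *outputs* of the upstream annotation tools a real
screen would run (profile searches for T6SS components, MOB/MPF typing,
partition/TA/AMR/virulence hits, IS annotation, protein clustering at 99%
identity / 100% coverage) — it emits no sequences.

Gene order is the coordinate system: ordinals are 0-based and spans are
half-open.  Physical sizes in bp are synthesised only for megaplasmid
bookkeeping.  Each replicon draws from its own pseudo-random stream derived
from ``(seed, replicon index)``, so adding replicons never perturbs the ones
already generated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .detection import DetectionThresholds
from .vocabulary import CANONICAL_COMPONENTS

ISLAND_PLAN: dict[str, tuple[str, ...]] = {
    # island type -> components to plant (hcp=tssD, vgrG=tssI, PAAR=evpJ)
    "hcp": ("tssD",),
    "vgrG": ("tssI",),
    "hcp-hcp": ("tssD", "tssD"),
    "vgrG-vgrG": ("tssI", "tssI"),
    "hcp-vgrG": ("tssD", "tssI"),
    "hcp-PAAR": ("tssD", "evpJ"),
    "vgrG-PAAR": ("tssI", "evpJ"),
    "hcp-vgrG-PAAR": ("tssD", "tssI", "evpJ"),
}

MOB_CLASSES = ("MOB_F", "MOB_Q", "MOB_P", "MOB_H", "MOB_C", "MOB_V")
MPF_TYPES = ("MPF_F", "MPF_T", "MPF_I", "MPF_G")
IS_FAMILIES = ("IS3", "IS5", "IS110", "IS200/IS605", "ISAs1")

DEFAULT_TAXONOMY_POOL: tuple[tuple[str, str, str, str, str], ...] = (
    ("Burkholderia cepacia", "Burkholderia", "Burkholderiaceae", "Burkholderiales", "Betaproteobacteria"),
    ("Burkholderia gladioli", "Burkholderia", "Burkholderiaceae", "Burkholderiales", "Betaproteobacteria"),
    ("Cupriavidus necator", "Cupriavidus", "Burkholderiaceae", "Burkholderiales", "Betaproteobacteria"),
    ("Rhizobium etli", "Rhizobium", "Rhizobiaceae", "Hyphomicrobiales", "Alphaproteobacteria"),
    ("Rhizobium phaseoli", "Rhizobium", "Rhizobiaceae", "Hyphomicrobiales", "Alphaproteobacteria"),
    ("Agrobacterium tumefaciens", "Agrobacterium", "Rhizobiaceae", "Hyphomicrobiales", "Alphaproteobacteria"),
    ("Escherichia coli", "Escherichia", "Enterobacteriaceae", "Enterobacterales", "Gammaproteobacteria"),
    ("Salmonella enterica", "Salmonella", "Enterobacteriaceae", "Enterobacterales", "Gammaproteobacteria"),
    ("Campylobacter jejuni", "Campylobacter", "Campylobacteraceae", "Campylobacterales", "Epsilonproteobacteria"),
    ("Campylobacter coli", "Campylobacter", "Campylobacteraceae", "Campylobacterales", "Epsilonproteobacteria"),
    ("Vibrio cholerae", "Vibrio", "Vibrionaceae", "Vibrionales", "Gammaproteobacteria"),
    ("Ruegeria pomeroyi", "Ruegeria", "Rhodobacteraceae", "Rhodobacterales", "Alphaproteobacteria"),
)

#: Median genome size (bp) per family, analogous to the reference medians a
#: real analysis would take from a curated taxonomy resource.
FAMILY_MEDIAN_GENOME: dict[str, int] = {
    "Burkholderiaceae": 7_000_000,
    "Rhizobiaceae": 6_500_000,
    "Enterobacteriaceae": 5_000_000,
    "Campylobacteraceae": 1_700_000,
    "Vibrionaceae": 4_500_000,
    "Rhodobacteraceae": 4_200_000,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults portray a desk-scale cohort with the structure of the real
    screen: plasmids are a mix of large T6SS-bearing replicons and smaller
    island-only carriers, plasmid GC runs a few points below the host
    chromosome, and mobility/maintenance traits occur at realistic rates.
    """

    n_plasmids: int = 120
    n_chromosomes: int = 40
    genes_per_replicon: dict = field(
        default_factory=lambda: {"plasmid": (5.0, 0.5), "chromosome": (6.2, 0.3)}
    )  # lognormal (mean, sd) of log gene count
    p_complete_cluster: float = 0.45
    p_orphan_island: float = 0.35
    island_type_weights: dict = field(
        default_factory=lambda: {
            "hcp": 2.0, "vgrG": 3.0, "hcp-hcp": 0.5, "vgrG-vgrG": 0.5,
            "hcp-vgrG": 2.0, "hcp-PAAR": 1.0, "vgrG-PAAR": 1.0,
            "hcp-vgrG-PAAR": 1.0,
        }
    )
    p_isolated_gene: float = 0.25
    mge_neighbor_prob: float = 0.5
    trait_probs: dict = field(
        default_factory=lambda: {
            "relaxase": 0.45, "mpf": 0.35, "partition": 0.8,
            "ta": 0.7, "amr": 0.1, "vf": 0.2,
        }
    )
    gc_host_mean: float = 0.55
    gc_host_sd: float = 0.05
    gc_plasmid_offset_mean: float = -0.035
    gc_plasmid_offset_sd: float = 0.01
    size_params: dict = field(
        default_factory=lambda: {"bp_per_gene": 1000, "bp_jitter": 0.1}
    )
    taxonomy_pool: tuple = DEFAULT_TAXONOMY_POOL
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_complete_cluster", "p_orphan_island", "p_isolated_gene",
                     "mge_neighbor_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        for trait, p in self.trait_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"trait_probs[{trait!r}] must be in [0,1], got {p}")
        if self.n_plasmids < 0 or self.n_chromosomes < 0:
            raise ValueError("n_plasmids and n_chromosomes must be nonnegative")
        if self.n_plasmids + self.n_chromosomes < 1:
            raise ValueError("n_plasmids + n_chromosomes must be >= 1")
        weights = list(self.island_type_weights.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError(
                "island_type_weights must be nonnegative and not all zero")
        unknown = set(self.island_type_weights) - set(ISLAND_PLAN)
        if unknown:
            raise ValueError(f"island_type_weights has unknown types {sorted(unknown)}")
        if not (0 < self.gc_host_mean < 1):
            raise ValueError("gc_host_mean must be a fraction in (0,1)")


@dataclass
class GroundTruth:
    """What was planted, for exact recovery checks downstream."""

    planted_clusters: list = field(default_factory=list)   # (replicon_id, (start, end), classification)
    planted_islands: list = field(default_factory=list)    # (replicon_id, island_type)
    planted_isolated: list = field(default_factory=list)   # (replicon_id, ordinal, component)
    planted_traits: dict = field(default_factory=dict)     # replicon_id -> trait dict
    planted_communities: dict = field(default_factory=dict)  # replicon_id -> community id
    planted_transitions: list = field(default_factory=list)  # (branch_id, direction)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)


def _rng_for(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


_ISOLATED_DISPLAY = {"tssD": "hcp", "tssI": "vgrG"}


def _plant_complete(rng, thresholds: DetectionThresholds) -> list[tuple[int, str]]:
    """Relative (offset, component) layout for a complete cluster.

    Picks 8-14 distinct components and lays them out with small gene gaps
    (well inside the intervening-gene threshold).
    """
    k = int(rng.integers(thresholds.complete_min_distinct, len(CANONICAL_COMPONENTS) + 1))
    comps = list(rng.choice(CANONICAL_COMPONENTS, size=k, replace=False))
    offset = 0
    layout = []
    for comp in comps:
        layout.append((offset, comp))
        offset += 1 + int(rng.integers(0, 3))  # 0-2 intervening background genes
    return layout


def _plant_island(rng, island_type: str, thresholds: DetectionThresholds):
    comps = ISLAND_PLAN[island_type]
    offset = 0
    layout = []
    for comp in comps:
        layout.append((offset, comp))
        offset += 1 + int(rng.integers(1, min(5, thresholds.max_intervening_genes)))
    return layout


def simulate_replicons(
    config: SimulationConfig,
    thresholds: DetectionThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the annotated cohort.

    Returns
    -------
    (gene_table, metadata, truth)
        ``gene_table`` has columns replicon_id, ordinal, strand, label,
        category over all replicons.  ``metadata`` has one row per replicon
        (kind, length, gc, host taxonomy, family median genome size, host
        chromosome GC, planted trait fields, PTU label).  ``truth`` records
        every planted feature.
    """
    config.validate()
    thresholds = thresholds or DetectionThresholds()
    island_types = sorted(config.island_type_weights)
    weights = np.array([config.island_type_weights[t] for t in island_types], dtype=float)
    weights = weights / weights.sum()

    gene_rows: list[tuple] = []
    meta_rows: list[dict] = []
    truth = GroundTruth()
    n_total = config.n_plasmids + config.n_chromosomes

    for index in range(n_total):
        kind = "plasmid" if index < config.n_plasmids else "chromosome"
        kind_index = index if kind == "plasmid" else index - config.n_plasmids
        replicon_id = f"{'P' if kind == 'plasmid' else 'C'}{kind_index:05d}"
        # stream key is (seed, kind, within-kind index): adding replicons of
        # either kind never perturbs the ones already generated
        rng = np.random.default_rng(np.random.SeedSequence(
            (int(config.seed), 0 if kind == "plasmid" else 1, kind_index)))

        mu, sigma = config.genes_per_replicon[kind]
        n_genes = max(80, int(np.ceil(rng.lognormal(mu, sigma))))
        species, genus, family, order, klass = config.taxonomy_pool[
            int(rng.integers(0, len(config.taxonomy_pool)))
        ]
        host_gc = float(np.clip(rng.normal(config.gc_host_mean, config.gc_host_sd), 0.2, 0.8))
        if kind == "plasmid":
            gc = float(np.clip(
                host_gc + rng.normal(config.gc_plasmid_offset_mean,
                                     config.gc_plasmid_offset_sd), 0.15, 0.85))
        else:
            gc = host_gc
        bp_per_gene = config.size_params.get("bp_per_gene", 1000)
        jitter = config.size_params.get("bp_jitter", 0.1)
        length = int(n_genes * bp_per_gene * float(rng.lognormal(0.0, jitter)))

        # decide planted loci
        planted: list[tuple[list[tuple[int, str]], str]] = []  # (layout, tag)
        if rng.random() < config.p_complete_cluster:
            planted.append((_plant_complete(rng, thresholds), "complete"))
        if rng.random() < config.p_orphan_island:
            island_type = island_types[int(rng.choice(len(island_types), p=weights))]
            planted.append((_plant_island(rng, island_type, thresholds), f"island:{island_type}"))
        if rng.random() < config.p_isolated_gene:
            comp = "tssD" if rng.random() < 0.5 else "tssI"
            planted.append(([(0, comp)], f"isolated:{comp}"))

        # reserve slots with > max_intervening_genes background genes between
        spacing = thresholds.max_intervening_genes + 5
        starts: list[int] = []
        cursor = spacing
        for lay, _ in planted:
            width = max(o for o, _ in lay) + 1
            starts.append(cursor)
            cursor += width + spacing
        if planted and cursor >= n_genes:
            n_genes = cursor + spacing  # grow small replicons to fit plan
            length = int(n_genes * bp_per_gene)

        labels = np.array(["gene"] * n_genes, dtype=object)
        categories = np.array(["other"] * n_genes, dtype=object)

        for (layout, tag), start in zip(planted, starts):
            span_ordinals = [start + off for off, _ in layout]
            for off, comp in layout:
                labels[start + off] = comp
                categories[start + off] = "T6SS"
            lo, hi = min(span_ordinals), max(span_ordinals) + 1
            if tag == "complete":
                truth.planted_clusters.append((replicon_id, (lo, hi), "complete"))
            elif tag.startswith("island:"):
                island_type = tag.split(":", 1)[1]
                truth.planted_islands.append((replicon_id, island_type))
                if island_type in ("hcp-vgrG", "hcp-PAAR", "vgrG-PAAR", "hcp-vgrG-PAAR"):
                    truth.planted_clusters.append((replicon_id, (lo, hi), "orphan_island"))
                else:
                    for off, comp in layout:
                        truth.planted_isolated.append((replicon_id, start + off, comp))
            else:
                comp = tag.split(":", 1)[1]
                truth.planted_isolated.append((replicon_id, start, comp))
            # optional MGE neighbour within the 20-gene window of the locus
            if rng.random() < config.mge_neighbor_prob:
                family_is = IS_FAMILIES[int(rng.integers(0, len(IS_FAMILIES)))]
                pos = hi + 1 + int(rng.integers(0, min(20, spacing - 2)))
                if pos < n_genes and categories[pos] == "other":
                    labels[pos] = family_is
                    categories[pos] = "MGE"

        # traits (plasmids only)
        traits = {
            "relaxase_class": "none", "mpf_type": "none",
            "partition_I": 0, "partition_II": 0, "partition_III": 0,
            "ta_count": 0, "amr_count": 0, "vf_labels": "",
        }
        if kind == "plasmid":
            p = config.trait_probs
            if rng.random() < p.get("relaxase", 0.0):
                traits["relaxase_class"] = MOB_CLASSES[int(rng.integers(0, len(MOB_CLASSES)))]
            if traits["relaxase_class"] != "none" and rng.random() < (
                    p.get("mpf", 0.0) / max(p.get("relaxase", 1.0), 1e-9)):
                traits["mpf_type"] = MPF_TYPES[int(rng.integers(0, len(MPF_TYPES)))]
            if rng.random() < p.get("partition", 0.0):
                ptype = ("I", "II", "III")[int(rng.choice(3, p=(0.8, 0.15, 0.05)))]
                traits[f"partition_{ptype}"] = int(rng.integers(1, 4))
            if rng.random() < p.get("ta", 0.0):
                traits["ta_count"] = int(rng.integers(1, 10))
            if rng.random() < p.get("amr", 0.0):
                traits["amr_count"] = int(rng.integers(1, 12))
            if rng.random() < p.get("vf", 0.0):
                vf_pool = ("flgG", "fliI", "flgI", "cheW", "fliP", "cheR")
                k = int(rng.integers(1, 4))
                traits["vf_labels"] = ",".join(
                    sorted(rng.choice(vf_pool, size=k, replace=False)))
            # write trait genes into the annotation table on free ordinals
            free = np.flatnonzero(categories == "other")
            rng.shuffle(free)
            cursor_free = 0

            def place(label: str, category: str) -> None:
                nonlocal cursor_free
                if cursor_free < len(free):
                    labels[free[cursor_free]] = label
                    categories[free[cursor_free]] = category
                    cursor_free += 1

            if traits["relaxase_class"] != "none":
                place(traits["relaxase_class"], "relaxase")
            if traits["mpf_type"] != "none":
                place(traits["mpf_type"], "MPF")
            for ptype in ("I", "II", "III"):
                for _ in range(traits[f"partition_{ptype}"]):
                    place(f"par_{ptype}", "partition")
            for _ in range(traits["ta_count"]):
                place("ta_toxin", "TA")
            for _ in range(traits["amr_count"]):
                place("amr_gene", "AMR")
            for vf in filter(None, traits["vf_labels"].split(",")):
                place(vf, "VF")
        truth.planted_traits[replicon_id] = dict(traits)

        strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
        for ordinal in range(n_genes):
            gene_rows.append((replicon_id, ordinal, strands[ordinal],
                              labels[ordinal], categories[ordinal]))

        meta_rows.append({
            "replicon_id": replicon_id, "kind": kind, "length": length,
            "gc": round(gc, 4), "host_gc": round(host_gc, 4),
            "species": species, "genus": genus, "family": family,
            "order": order, "class": klass,
            "family_median_genome": FAMILY_MEDIAN_GENOME.get(family, 5_000_000),
            "ptu": "none", "host_id": f"H{index:05d}",
            **traits,
        })

    gene_table = pd.DataFrame(
        gene_rows, columns=["replicon_id", "ordinal", "strand", "label", "category"])
    metadata = pd.DataFrame(meta_rows)
    return gene_table, metadata, truth


def simulate_compartment_tree(
    n_tips: int,
    branch_rate: float = 10.0,
    switch_rate: float = 0.5,
    seed: int = 0,
    root_state: str = "chromosome",
) -> tuple[str, dict[str, str], GroundTruth]:
    """Random binary tree with a two-state compartment character evolved on it.

    Branch lengths are exponential with mean ``1 / branch_rate``.  The
    character {plasmid, chromosome} evolves by a symmetric two-state Markov
    jump process at ``switch_rate`` events per unit branch length; every
    realised jump is recorded per branch in the ground truth, so parameter-
    recovery experiments can compare inferred against actual switch events.

    Returns (newick string, tip->compartment map, GroundTruth with
    ``planted_transitions``).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if branch_rate < 0 or switch_rate < 0:
        raise ValueError("rates must be nonnegative")
    rng = _rng_for(seed, 0)

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node(taxon=taxa[i])
        nodes.append(node)
    # random sequential coalescent-style joins
    pool = nodes[:]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        right = pool.pop(j)
        left = pool.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        pool.append(parent)
    tree.seed_node = pool[0]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            edge.length = 0.0
        else:
            edge.length = float(rng.exponential(1.0 / branch_rate)) if branch_rate > 0 else 0.0

    truth = GroundTruth()
    states = ("plasmid", "chromosome")
    tree.seed_node.state = root_state
    branch_counter = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        state = node.parent_node.state
        t = node.edge.length or 0.0
        n_jumps = int(rng.poisson(switch_rate * t)) if switch_rate > 0 else 0
        branch_id = f"b{branch_counter}"
        node.edge.label = branch_id
        branch_counter += 1
        for _ in range(n_jumps):
            new_state = states[0] if state == states[1] else states[1]
            direction = "C->P" if new_state == "plasmid" else "P->C"
            truth.planted_transitions.append((branch_id, direction))
            state = new_state
        node.state = state

    tip_states = {leaf.taxon.label: leaf.state for leaf in tree.leaf_node_iter()}
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, tip_states, truth


def simulate_hpc_table(
    community_spec: dict[str, tuple[list[str], int]],
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Protein-cluster (HPC) membership table with planted communities.

    ``community_spec`` maps community id -> (replicon list, shared-protein
    count): every member of a community carries one protein in each of that
    community's shared clusters.  ``noise`` adds, per replicon, Geometric-
    distributed spurious singleton clusters (private to one replicon), which
    perturb the bipartite graph without linking communities.

    Returns a table with columns protein_id, replicon_id, hpc_id.
    """
    if not community_spec:
        raise ValueError("community_spec must not be empty")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0,1]")
    rng = _rng_for(seed, 1)
    rows = []
    protein_counter = 0
    for community_id in sorted(community_spec):
        replicons, n_shared = community_spec[community_id]
        if not replicons:
            raise ValueError(f"community {community_id!r} has no members")
        for k in range(int(n_shared)):
            hpc_id = f"HPC_{community_id}_{k}"
            for replicon in replicons:
                rows.append((f"prot{protein_counter}", replicon, hpc_id))
                protein_counter += 1
    if noise > 0:
        all_replicons = sorted({r for reps, _ in community_spec.values() for r in reps})
        for replicon in all_replicons:
            n_private = int(rng.geometric(1.0 - noise)) - 1
            for k in range(n_private):
                rows.append((f"prot{protein_counter}", replicon,
                             f"HPC_noise_{replicon}_{k}"))
                protein_counter += 1
    return pd.DataFrame(rows, columns=["protein_id", "replicon_id", "hpc_id"])
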