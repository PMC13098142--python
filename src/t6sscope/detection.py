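"""T6SS gene-cluster detection and classification on ordered gene tables.

The coordinate system is gene order: each gene on a replicon carries a
0-based ordinal, and clustering counts *intervening genes* between
consecutive T6SS hits, not base pairs.  Two hits are chained into the same
cluster when at most ``max_intervening_genes`` non-T6SS genes separate them
(MacSyFinder-style inter-gene-max-space semantics).  Chains with fewer than
``min_distinct_genes`` distinct components are discarded and their members
demoted to isolated-gene candidates.

Classification of a cluster:

* **complete** — at least ``complete_min_distinct`` (default 8) *distinct*
  components;
* **orphan_island** — the distinct components are exactly one of the
  tube/spike combinations hcp-vgrG, hcp-PAAR, vgrG-PAAR or hcp-vgrG-PAAR;
* **incomplete** — anything else.

Isolated hcp/vgrG genes outside every cluster span are inventoried
separately; two same-component isolated hits within the intervening-gene
threshold form a homotypic island (hcp-hcp or vgrG-vgrG).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .vocabulary import (
    CANONICAL_COMPONENTS,
    ORPHAN_COMBINATIONS,
    TUBE_SPIKE_COMPONENTS,
    island_type_for,
    normalize_component,
    subcomplex_presence,
)

logger = logging.getLogger(__name__)

T6SS_CATEGORY = "T6SS"

ISLAND_TYPES = (
    "hcp", "vgrG", "hcp-hcp", "vgrG-vgrG",
    "hcp-vgrG", "hcp-PAAR", "vgrG-PAAR", "hcp-vgrG-PAAR",
)


@dataclass(frozen=True)
class DetectionThresholds:
    """Detection and classification parameters.

    max_intervening_genes
        Maximum number of non-T6SS genes allowed between two hits of the
        same cluster (default 20).
    min_distinct_genes
        Minimum distinct components for a chain to count as a cluster
        (default 2).
    complete_min_distinct
        Distinct components required to call a cluster complete (default 8).
    phylo_min_distinct
        Stricter threshold used to select clusters for phylogenetic work
        (default 10).
    """

    max_intervening_genes: int = 20
    min_distinct_genes: int = 2
    complete_min_distinct: int = 8
    phylo_min_distinct: int = 10

    def __post_init__(self) -> None:
        for name in ("max_intervening_genes", "min_distinct_genes",
                     "complete_min_distinct", "phylo_min_distinct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.complete_min_distinct < self.min_distinct_genes:
            raise ValueError(
                "complete_min_distinct must be >= min_distinct_genes")


@dataclass
class T6SSCluster:
    """A detected run of T6SS genes on one replicon.

    ``span`` is half-open over gene ordinals and covers exactly the first
    through last member hit.  ``members`` holds ``(ordinal, component,
    raw_label)`` triples; duplicated components are retained there but
    counted once for classification.
    """

    replicon_id: str
    start: int
    end: int
    members: list[tuple[int, str, str]]
    distinct_components: frozenset[str]
    classification: str = "incomplete"
    island_type: str = "none"
    subtype: str = "unassigned"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_distinct(self) -> int:
        return len(self.distinct_components)

    def contains(self, ordinal: int) -> bool:
        return self.start <= ordinal < self.end


@dataclass(frozen=True)
class IsolatedGene:
    replicon_id: str
    ordinal: int
    component: str  # tssD or tssI


@dataclass
class IslandInventory:
    """Per-replicon inventory of orphan-island types.

    ``by_island`` counts islands; ``by_replicon`` counts replicons carrying
    at least one island of each type (the two candidate denominators for
    per-type prevalence).
    """

    by_island: Counter = field(default_factory=Counter)
    by_replicon: Counter = field(default_factory=Counter)


def _t6ss_hits(gene_table: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Extract normalised (ordinal, component, raw label) T6SS hits, sorted."""
    sub = gene_table[gene_table["category"] == T6SS_CATEGORY]
    hits = []
    for ordinal, label in zip(sub["ordinal"], sub["label"]):
        comp = normalize_component(str(label))
        if comp is None:
            logger.warning("unrecognized T6SS label %r ignored", label)
            continue
        hits.append((int(ordinal), comp, str(label)))
    hits.sort()
    return hits


def scan_clusters(
    gene_table: pd.DataFrame,
    thresholds: DetectionThresholds | None = None,
    circular: bool = False,
) -> tuple[list[T6SSCluster], list[tuple[int, str, str]]]:
    """Group T6SS hits into cluster candidates by the intervening-gene rule.

    Parameters
    ----------
    gene_table
        Ordered annotations for ONE replicon with columns ``replicon_id``,
        ``ordinal``, ``label``, ``category``.  Ordinals must be unique.
    circular
        When true, a cluster chain may wrap across the origin (the first and
        last hits merge if the wrap-around gap is within threshold).

    Returns
    -------
    (clusters, leftovers)
        ``clusters`` are candidates with >= ``min_distinct_genes`` distinct
        components, ordinal-sorted and non-overlapping.  ``leftovers`` are
        hits from discarded sub-threshold chains (isolated-gene candidates).
    """
    thresholds = thresholds or DetectionThresholds()
    if gene_table.empty:
        return [], []
    if gene_table["ordinal"].duplicated().any():
        dup = int(gene_table["ordinal"][gene_table["ordinal"].duplicated()].iloc[0])
        raise ValueError(f"duplicate ordinal {dup} on replicon")
    replicon_id = str(gene_table["replicon_id"].iloc[0])
    hits = _t6ss_hits(gene_table)
    if not hits:
        return [], []

    groups: list[list[tuple[int, str, str]]] = [[hits[0]]]
    for hit in hits[1:]:
        gap = hit[0] - groups[-1][-1][0] - 1  # genes strictly between
        if gap <= thresholds.max_intervening_genes:
            groups[-1].append(hit)
        else:
            groups.append([hit])

    if circular and len(groups) > 1:
        n_genes = int(gene_table["ordinal"].max()) + 1
        wrap_gap = n_genes - groups[-1][-1][0] - 1 + groups[0][0][0]
        if wrap_gap <= thresholds.max_intervening_genes:
            groups[0] = groups.pop() + groups[0]

    clusters: list[T6SSCluster] = []
    leftovers: list[tuple[int, str, str]] = []
    for group in groups:
        distinct = frozenset(c for _, c, _ in group)
        if len(distinct) < thresholds.min_distinct_genes:
            leftovers.extend(group)
            continue
        ordinals = [o for o, _, _ in group]
        clusters.append(T6SSCluster(
            replicon_id=replicon_id,
            start=min(ordinals),
            end=max(ordinals) + 1,
            members=sorted(group),
            distinct_components=distinct,
        ))
    clusters.sort(key=lambda c: c.start)
    for cluster in clusters:
        classify_cluster(cluster, thresholds)
    return clusters, leftovers


def classify_cluster(
    cluster: T6SSCluster, thresholds: DetectionThresholds | None = None
) -> T6SSCluster:
    """Assign complete / orphan_island / incomplete and the island type."""
    thresholds = thresholds or DetectionThresholds()
    comps = cluster.distinct_components
    if len(comps) >= thresholds.complete_min_distinct:
        cluster.classification = "complete"
        cluster.island_type = "none"
    elif comps in ORPHAN_COMBINATIONS:
        cluster.classification = "orphan_island"
        cluster.island_type = island_type_for(comps)
    else:
        cluster.classification = "incomplete"
        cluster.island_type = "none"
    return cluster


def find_isolated_genes(
    gene_table: pd.DataFrame,
    clusters: list[T6SSCluster],
    thresholds: DetectionThresholds | None = None,
    leftovers: list[tuple[int, str, str]] | None = None,
) -> tuple[list[IsolatedGene], IslandInventory]:
    """Report tube/spike (hcp, vgrG) hits outside every cluster span.

    Two same-component isolated hits within ``max_intervening_genes`` of each
    other are additionally inventoried as a homotypic island (hcp-hcp or
    vgrG-vgrG); such pairs are unreachable for the cluster scan, which
    requires two *distinct* components.

    The inventory also tallies the heterotypic orphan-island clusters that
    were classified from the same table, so it covers all eight island types.
    """
    thresholds = thresholds or DetectionThresholds()
    replicon_id = str(gene_table["replicon_id"].iloc[0]) if len(gene_table) else ""
    hits = _t6ss_hits(gene_table)
    isolated = [
        IsolatedGene(replicon_id, o, c)
        for o, c, _ in hits
        if c in TUBE_SPIKE_COMPONENTS and not any(cl.contains(o) for cl in clusters)
    ]

    inventory = IslandInventory()
    # homotypic pairs among isolated hits, greedy left-to-right
    paired: set[int] = set()
    by_component: dict[str, list[IsolatedGene]] = {}
    for gene in isolated:
        by_component.setdefault(gene.component, []).append(gene)
    display = {"tssD": "hcp", "tssI": "vgrG"}
    for comp, genes in by_component.items():
        i = 0
        while i < len(genes) - 1:
            if genes[i + 1].ordinal - genes[i].ordinal - 1 <= thresholds.max_intervening_genes:
                inventory.by_island[f"{display[comp]}-{display[comp]}"] += 1
                paired.update({genes[i].ordinal, genes[i + 1].ordinal})
                i += 2
            else:
                i += 1
        # unpaired isolated hits count as single-gene islands
    for gene in isolated:
        if gene.ordinal not in paired:
            inventory.by_island[display[gene.component]] += 1
    for cl in clusters:
        if cl.classification == "orphan_island":
            inventory.by_island[cl.island_type] += 1
    for island_type in list(inventory.by_island):
        inventory.by_replicon[island_type] = 1
    return isolated, inventory


def assign_subtype(
    cluster: T6SSCluster,
    marker_table: dict[str, str],
    gene_table: pd.DataFrame | None = None,
) -> str:
    """Assign a phylogenetic subtype (i/ii/iii) via diagnostic marker labels.

    ``marker_table`` maps raw annotation labels to subtype names; its
    insertion order is the priority order.  Markers are looked up among the
    cluster's member labels and, when ``gene_table`` is given, among all
    labels inside the cluster span.
    """
    if not marker_table:
        if not getattr(assign_subtype, "_warned_empty", False):
            logger.warning("empty subtype marker table; all clusters unassigned")
            assign_subtype._warned_empty = True  # type: ignore[attr-defined]
        cluster.subtype = "unassigned"
        return cluster.subtype
    labels = {raw for _, _, raw in cluster.members}
    if gene_table is not None:
        in_span = gene_table[
            (gene_table["ordinal"] >= cluster.start) & (gene_table["ordinal"] < cluster.end)
        ]
        labels.update(str(x) for x in in_span["label"])
    matched = [s for label, s in marker_table.items() if label in labels]
    if not matched:
        cluster.subtype = "unassigned"
    else:
        if len(set(matched)) > 1:
            logger.warning(
                "cluster %s:%d-%d matches markers of several subtypes %s; "
                "keeping first by priority", cluster.replicon_id,
                cluster.start, cluster.end, sorted(set(matched)))
        cluster.subtype = matched[0]
    return cluster.subtype


def summarize_component_distribution(
    clusters: list[T6SSCluster],
) -> tuple[dict[int, int], pd.DataFrame]:
    """Histogram of distinct-component counts plus subcomplex presence table."""
    histogram = Counter(c.n_distinct for c in clusters)
    rows = []
    for c in clusters:
        row = {"replicon_id": c.replicon_id, "start": c.start, "end": c.end,
               "n_distinct": c.n_distinct, "classification": c.classification}
        row.update(subcomplex_presence(c.distinct_components))
        rows.append(row)
    table = pd.DataFrame(rows)
    return dict(sorted(histogram.items())), table


def clusters_to_frame(clusters: list[T6SSCluster]) -> pd.DataFrame:
    """Tabulate clusters for TSV export."""
    return pd.DataFrame(
        [
            {
                "replicon_id": c.replicon_id,
                "start": c.start,
                "end": c.end,
                "n_distinct": c.n_distinct,
                "components": ",".join(sorted(c.distinct_components)),
                "classification": c.classification,
                "island_type": c.island_type,
                "subtype": c.subtype,
            }
            for c in clusters
        ],
        columns=["replicon_id", "start", "end", "n_distinct", "components",
                 "classification", "island_type", "subtype"],
    )


def detect_all(
    gene_tables: pd.DataFrame,
    thresholds: DetectionThresholds | None = None,
    circular: bool = False,
) -> tuple[list[T6SSCluster], list[IsolatedGene], IslandInventory]:
    """Run the full detection stage over a multi-replicon annotation table."""
    thresholds = thresholds or DetectionThresholds()
    clusters: list[T6SSCluster] = []
    isolated: list[IsolatedGene] = []
    inventory = IslandInventory()
    for _, table in gene_tables.groupby("replicon_id", sort=True):
        table = table.sort_values("ordinal")
        cls, leftovers = scan_clusters(table, thresholds, circular=circular)
        iso, inv = find_isolated_genes(table, cls, thresholds, leftovers)
        clusters.extend(cls)
        isolated.extend(iso)
        inventory.by_island.update(inv.by_island)
        inventory.by_replicon.update(inv.by_replicon)
    return clusters, isolated, inventory
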