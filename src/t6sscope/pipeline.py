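"""End-to-end pipeline: simulate -> detect -> traits -> mge -> network ->
phylo -> stats, with TSV artifacts as the source of truth and a versioned
JSON report aggregating them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import DetectionThresholds, clusters_to_frame, detect_all
from .io import report_hash, write_json, write_tsv
from .mge import family_association, reports_to_frame, window_scan
from .network import (build_bipartite, communities_to_frame,
                      community_cross_tab, detect_communities)
from .phylo import (TipMetadata, ancestral_states, closest_homolog,
                    count_transitions, load_tree, patristic_matrix,
                    posteriors_to_frame)
from .stats import fisher_exact
from .synthetic_data import (GroundTruth, SimulationConfig,
                             simulate_compartment_tree, simulate_hpc_table,
                             simulate_replicons)
from .traits import assign_analysis_group, cohort_summary, profile_traits, profiles_to_frame

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(
    config: SimulationConfig | None = None,
    outdir: str | Path = "t6sscope_out",
    seed: int | None = None,
    input_dir: str | Path | None = None,
    thresholds: DetectionThresholds | None = None,
) -> dict:
    """Run all stages and write artifacts under ``outdir``.

    Either simulate a cohort from ``config`` (``seed`` overrides the config
    seed) or load ``annotations.tsv`` / ``metadata.tsv`` from ``input_dir``.
    Returns the report dict (also written to ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or DetectionThresholds()
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}

    # ---- stage: inputs -----------------------------------------------------
    truth: GroundTruth | None = None
    if input_dir is not None:
        input_dir = Path(input_dir)
        ann_path = input_dir / "annotations.tsv"
        meta_path = input_dir / "metadata.tsv"
        for p in (ann_path, meta_path):
            if not p.exists():
                raise StageError("detect", f"missing input file {p}")
        gene_table = pd.read_csv(ann_path, sep="\t")
        metadata = pd.read_csv(meta_path, sep="\t")
        config_hash = "external-input"
        seed = seed if seed is not None else 0
    else:
        config = config or SimulationConfig()
        if seed is not None:
            config = dataclasses.replace(config, seed=seed)
        seed = config.seed
        gene_table, metadata, truth = simulate_replicons(config, thresholds)
        config_hash = hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]
        write_tsv(gene_table, outdir / "annotations.tsv")
        write_tsv(metadata, outdir / "metadata.tsv")
        (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")

    for col in ("replicon_id", "ordinal", "label", "category"):
        if col not in gene_table.columns:
            raise StageError("detect", f"annotations.tsv lacks column {col!r}")

    # ---- stage: detect -----------------------------------------------------
    clusters, isolated, inventory = detect_all(gene_table, thresholds)
    cluster_frame = clusters_to_frame(clusters)
    write_tsv(cluster_frame, outdir / "clusters.tsv")
    write_tsv(pd.DataFrame(
        [{"replicon_id": g.replicon_id, "ordinal": g.ordinal, "component": g.component}
         for g in isolated],
        columns=["replicon_id", "ordinal", "component"]),
        outdir / "isolated_genes.tsv")

    kind_by_replicon = dict(zip(metadata["replicon_id"], metadata.get("kind", "plasmid")))
    by_class = cluster_frame.groupby("classification").size().to_dict()
    report["dataset"] = {
        "n_plasmids": int((metadata["kind"] == "plasmid").sum()),
        "n_chromosomes": int((metadata["kind"] == "chromosome").sum()),
    }
    plasmid_clusters = cluster_frame[
        cluster_frame["replicon_id"].map(kind_by_replicon).eq("plasmid")]
    report["clusters"] = {
        "counts_by_classification": {k: int(v) for k, v in sorted(by_class.items())},
        "complete_systems_on_plasmids": int(
            (plasmid_clusters["classification"] == "complete").sum()),
        "plasmids_with_complete_system": int(
            plasmid_clusters.loc[plasmid_clusters["classification"] == "complete",
                                 "replicon_id"].nunique()),
        "island_inventory_by_island": dict(sorted(inventory.by_island.items())),
        "island_inventory_by_replicon": dict(sorted(inventory.by_replicon.items())),
        "n_isolated_genes": len(isolated),
    }

    # ---- stage: traits -----------------------------------------------------
    has_complete: dict[str, bool] = {}
    has_island: dict[str, bool] = {}
    for c in clusters:
        if c.classification == "complete":
            has_complete[c.replicon_id] = True
        elif c.classification == "orphan_island":
            has_island[c.replicon_id] = True
    for g in isolated:
        has_island[g.replicon_id] = True

    profiles = [profile_traits(row) for _, row in metadata.iterrows()]
    profile_frame = profiles_to_frame(profiles)
    profile_frame["group"] = [
        assign_analysis_group(has_complete.get(r, False), has_island.get(r, False))
        for r in profile_frame["replicon_id"]]
    write_tsv(profile_frame, outdir / "profiles.tsv")
    summary = cohort_summary(profile_frame)
    report["cohort"] = summary

    tests: dict[str, dict] = {}
    for name, table in summary.get("tables", {}).items():
        result = fisher_exact(table, side="two_sided")
        tests[f"{name}_fisher"] = {"table": table, "p": result.p,
                                   "odds_ratio": result.odds_ratio,
                                   "side": "two_sided"}

    # ---- stage: mge --------------------------------------------------------
    reports = []
    locus_class: dict[str, str] = {}
    for i, c in enumerate(clusters):
        if c.classification == "incomplete":
            continue
        locus_id = f"{c.replicon_id}:{c.start}-{c.end}"
        table = gene_table[gene_table["replicon_id"] == c.replicon_id]
        rep = window_scan(locus_id, (c.start, c.end), table)
        reports.append(rep)
        locus_class[locus_id] = ("complete" if c.classification == "complete"
                                 else "orphan")
    write_tsv(reports_to_frame(reports, locus_class), outdir / "mge_neighborhoods.tsv")
    by_locus_class = {"complete": [], "orphan": []}
    for rep in reports:
        by_locus_class[locus_class[rep.locus_id]].append(rep)
    if all(by_locus_class.values()):
        assoc = family_association(by_locus_class)
        write_tsv(assoc, outdir / "mge_association.tsv")
        report["mge"] = {
            "n_loci_screened": len(reports),
            "fraction_with_adjacent_mge": (
                sum(r.has_mge for r in reports) / len(reports) if reports else None),
            "families_tested": int(len(assoc)),
            "significant_families": assoc.loc[assoc["adjusted_p"] < 0.05,
                                              "family"].tolist() if len(assoc) else [],
        }
    else:
        report["mge"] = {"n_loci_screened": len(reports),
                         "note": "need loci of both classes for association tests"}

    # ---- stage: network ----------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    complete_replicons = sorted({c.replicon_id for c in clusters
                                 if c.classification == "complete"})
    if len(complete_replicons) >= 4:
        spec: dict[str, tuple[list[str], int]] = {}
        size = 4
        for i in range(0, len(complete_replicons), size):
            members = complete_replicons[i:i + size]
            spec[f"cm{i // size}"] = (members, 10)
        if truth is not None:
            for cid, (members, _) in spec.items():
                for m in members:
                    truth.planted_communities[m] = cid
        hpc_table = simulate_hpc_table(spec, noise=0.2, seed=seed)
        write_tsv(hpc_table, outdir / "hpc_table.tsv")
        bipartite = build_bipartite(hpc_table, metadata)
        communities = detect_communities(bipartite, seed=seed)
        fam_by_replicon = {
            rep.replicon_id: rep.families for rep in reports if rep.has_mge}
        cross_tab, _ = community_cross_tab(communities, bipartite, fam_by_replicon)
        write_tsv(communities_to_frame(communities), outdir / "communities.tsv")
        write_tsv(cross_tab, outdir / "community_cross_tab.tsv")
        multi = [c for c in communities if not c.is_singleton]
        report["network"] = {
            "n_communities": len(communities),
            "n_singletons": sum(c.is_singleton for c in communities),
            "n_multi_member": len(multi),
            "host_range_grades": {
                g: sum(1 for c in multi if c.host_range_grade == g)
                for g in ("I", "II", "III", "IV", "V", "beyond V")},
        }
    else:
        report["network"] = {"note": "fewer than 4 complete-system replicons; skipped"}

    # ---- stage: phylo ------------------------------------------------------
    n_tips = 60
    newick, tip_states, tree_truth = simulate_compartment_tree(
        n_tips=n_tips, branch_rate=10.0, switch_rate=0.5, seed=seed)
    (outdir / "compartment_tree.nwk").write_text(newick + "\n")
    tree = load_tree(newick)
    reconstruction = ancestral_states(tree, tip_states)
    write_tsv(posteriors_to_frame(reconstruction), outdir / "ancestral_posteriors.tsv")
    transitions = count_transitions(reconstruction, tree)
    dist = patristic_matrix(tree)
    meta_tips = TipMetadata(compartment=tip_states)
    homologs = closest_homolog(dist, meta_tips)
    write_tsv(homologs.per_tip, outdir / "closest_homologs.tsv")
    report["phylo"] = {
        "n_tips": n_tips,
        "equilibrium_frequencies": reconstruction.pi,
        "log_likelihood": reconstruction.log_likelihood,
        "inferred_transitions": transitions,
        "planted_transitions": len(tree_truth.planted_transitions),
        "median_closest_plasmid_distance": (
            float(homologs.per_tip["d_plasmid"].median())
            if len(homologs.per_tip) else None),
    }

    # ---- stage: stats / provenance ----------------------------------------
    report["tests"] = tests
    report["provenance"] = {
        "tool_version": __version__,
        "seed": int(seed),
        "config_hash": config_hash,
        "thresholds": dataclasses.asdict(thresholds),
        "schema_version": REPORT_SCHEMA_VERSION,
    }
    report["report_hash"] = report_hash(
        {k: v for k, v in report.items() if k != "report_hash"})
    write_json(report, outdir / "report.json")
    return report


def render_summary(report: dict) -> str:
    """Deterministic human-readable digest of a pipeline report."""
    lines = [f"t6sscope report (schema {report.get('schema_version')})"]
    ds = report.get("dataset", {})
    lines.append(f"replicons: {ds.get('n_plasmids', 0)} plasmids, "
                 f"{ds.get('n_chromosomes', 0)} chromosomes")
    cl = report.get("clusters", {})
    lines.append(
        f"T6SS loci: {cl.get('complete_systems_on_plasmids', 0)} complete systems on "
        f"{cl.get('plasmids_with_complete_system', 0)} plasmids; "
        f"counts by class {cl.get('counts_by_classification', {})}")
    cohort = report.get("cohort", {}).get("groups", {})
    for group, entry in sorted(cohort.items()):
        pct = entry.get("megaplasmid_pct")
        pct_str = "undefined" if pct is None else f"{pct:.1f}%"
        lines.append(f"  {group}: n={entry['n']}, megaplasmids {pct_str}")
    net = report.get("network", {})
    if "n_communities" in net:
        lines.append(f"communities: {net['n_communities']} "
                     f"({net['n_singletons']} singletons)")
    else:
        lines.append("communities: none detected")
    phylo = report.get("phylo", {})
    if phylo:
        tr = phylo.get("inferred_transitions", {})
        lines.append(
            f"compartment switches: C->P {tr.get('chromosome->plasmid', 0)}, "
            f"P->C {tr.get('plasmid->chromosome', 0)} "
            f"(planted {phylo.get('planted_transitions', 0)})")
    for name, t in sorted(report.get("tests", {}).items()):
        lines.append(f"test {name}: p={t['p']:.3g} (odds ratio {t['odds_ratio']:.3g})")
    return "\n".join(lines) + "\n"
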