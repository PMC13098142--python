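"""Replicon-level trait classification: megaplasmid status, transmissibility,
GC divergence, maintenance and accessory content, and cohort summaries.

A plasmid is a **megaplasmid** when its length is at least 5% of the median
genome size of the host's taxonomic family (the median is supplied as
metadata; no lookups are performed).  **Transmissibility** follows the
relaxase/MPF trichotomy: conjugative when both a relaxase and a mating-pair
formation (MPF) system are present, mobilizable when only a relaxase is
detected, non-transmissible otherwise.  An MPF system without a relaxase is
non-transmissible and flagged, since a relaxase is required to initiate
transfer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEGAPLASMID_RATIO = 0.05

#: Precedence used when several relaxase classes hit one replicon.
MOB_PRECEDENCE = ("MOB_F", "MOB_Q", "MOB_P", "MOB_H", "MOB_C", "MOB_V")


@dataclass
class RepliconProfile:
    replicon_id: str
    kind: str  # plasmid | chromosome
    length: int
    gc: float
    family: str
    family_median_genome: float | None
    megaplasmid: bool | None  # None = unknown (missing family median)
    relaxase_class: str = "none"
    mpf_type: str = "none"
    transmissibility: str = "non_transmissible"
    partition_counts: dict = field(default_factory=lambda: {"I": 0, "II": 0, "III": 0})
    ta_count: int = 0
    amr_count: int = 0
    vf_labels: list = field(default_factory=list)
    ptu: str = "none"
    gc_divergence: float | None = None  # percentage points vs host chromosome


def is_megaplasmid(length: float, family_median_genome: float | None) -> bool | None:
    """Length >= 5% of the host family's median genome size (inclusive).

    Returns ``None`` (status unknown, excluded from tallies) when the family
    median is missing.
    """
    if family_median_genome is None or (
            isinstance(family_median_genome, float) and math.isnan(family_median_genome)):
        return None
    if length <= 0 or family_median_genome <= 0:
        raise ValueError("length and family_median_genome must be positive")
    return length / family_median_genome >= MEGAPLASMID_RATIO


def classify_transmissibility(relaxase_present: bool, mpf_present: bool) -> str:
    """Conjugative / mobilizable / non-transmissible from the two flags."""
    if relaxase_present and mpf_present:
        return "conjugative"
    if relaxase_present:
        return "mobilizable"
    if mpf_present:
        logger.warning("MPF system without relaxase: classified non_transmissible")
    return "non_transmissible"


def gc_divergence(plasmid_gc: float, host_chromosome_gc: float | None) -> float | None:
    """Signed GC difference in percentage points: 100*(plasmid - host).

    Returns ``None`` when the host chromosome GC is unavailable.
    """
    if host_chromosome_gc is None or (
            isinstance(host_chromosome_gc, float) and math.isnan(host_chromosome_gc)):
        return None
    for v in (plasmid_gc, host_chromosome_gc):
        if not 0.0 < v < 1.0:
            raise ValueError(f"GC fraction must be in (0,1), got {v}")
    return 100.0 * (plasmid_gc - host_chromosome_gc)


def host_chromosome_gc(chromosomes: pd.DataFrame) -> float | None:
    """Length-weighted mean GC over a host's chromosomes."""
    if chromosomes.empty:
        return None
    weights = chromosomes["length"].to_numpy(dtype=float)
    return float(np.average(chromosomes["gc"].to_numpy(dtype=float), weights=weights))


def profile_traits(metadata_row: pd.Series, hit_table: pd.DataFrame | None = None) -> RepliconProfile:
    """Aggregate trait hits for one replicon into a profile.

    ``metadata_row`` is a row of the replicon-metadata table; ``hit_table``
    optionally carries per-gene hits (columns label, category) which override
    the metadata trait columns when provided.
    """
    relaxase = str(metadata_row.get("relaxase_class", "none"))
    mpf = str(metadata_row.get("mpf_type", "none"))
    partition = {p: int(metadata_row.get(f"partition_{p}", 0)) for p in ("I", "II", "III")}
    ta = int(metadata_row.get("ta_count", 0))
    amr = int(metadata_row.get("amr_count", 0))
    vf_raw = metadata_row.get("vf_labels", "")
    if vf_raw is None or (isinstance(vf_raw, float) and math.isnan(vf_raw)):
        vf = []
    elif isinstance(vf_raw, str):
        vf = [v for v in vf_raw.split(",") if v]
    else:
        vf = list(vf_raw)

    if hit_table is not None and len(hit_table):
        relax_hits = [str(x) for x in hit_table.loc[hit_table["category"] == "relaxase", "label"]]
        if relax_hits:
            known = [m for m in MOB_PRECEDENCE if m in relax_hits]
            if len(set(relax_hits)) > 1:
                logger.warning("replicon %s has multiple relaxase classes %s; keeping %s",
                               metadata_row["replicon_id"], sorted(set(relax_hits)),
                               known[0] if known else relax_hits[0])
            relaxase = known[0] if known else relax_hits[0]
        mpf_hits = [str(x) for x in hit_table.loc[hit_table["category"] == "MPF", "label"]]
        if mpf_hits:
            mpf = mpf_hits[0]
        part_hits = hit_table[hit_table["category"] == "partition"]
        if len(part_hits):
            partition = {p: int((part_hits["label"] == f"par_{p}").sum()) for p in ("I", "II", "III")}
        ta = int((hit_table["category"] == "TA").sum()) or ta
        amr = int((hit_table["category"] == "AMR").sum()) or amr
        vf_hits = [str(x) for x in hit_table.loc[hit_table["category"] == "VF", "label"]]
        if vf_hits:
            vf = sorted(vf_hits)

    length = int(metadata_row["length"])
    fam_median = metadata_row.get("family_median_genome")
    kind = str(metadata_row.get("kind", "plasmid"))
    mega = is_megaplasmid(length, fam_median) if kind == "plasmid" else False
    profile = RepliconProfile(
        replicon_id=str(metadata_row["replicon_id"]),
        kind=kind,
        length=length,
        gc=float(metadata_row["gc"]),
        family=str(metadata_row.get("family", "")),
        family_median_genome=fam_median,
        megaplasmid=mega,
        relaxase_class=relaxase,
        mpf_type=mpf,
        transmissibility=classify_transmissibility(relaxase != "none", mpf != "none"),
        partition_counts=partition,
        ta_count=ta,
        amr_count=amr,
        vf_labels=vf,
        ptu=str(metadata_row.get("ptu", "none")),
    )
    host_gc = metadata_row.get("host_gc")
    if kind == "plasmid" and host_gc is not None and not pd.isna(host_gc):
        profile.gc_divergence = gc_divergence(profile.gc, float(host_gc))
    return profile


def profiles_to_frame(profiles: list[RepliconProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "replicon_id": p.replicon_id, "kind": p.kind, "length": p.length,
            "gc": p.gc, "family": p.family, "megaplasmid": p.megaplasmid,
            "relaxase_class": p.relaxase_class, "mpf_type": p.mpf_type,
            "transmissibility": p.transmissibility,
            "partition_I": p.partition_counts["I"],
            "partition_II": p.partition_counts["II"],
            "partition_III": p.partition_counts["III"],
            "ta_count": p.ta_count, "amr_count": p.amr_count,
            "n_vf": len(p.vf_labels), "ptu": p.ptu,
            "gc_divergence": p.gc_divergence,
        })
    return pd.DataFrame(rows)


def assign_analysis_group(has_complete: bool, has_island: bool) -> str:
    """complete_T6SS > orphan_only > neither (a plasmid with both counts as
    complete_T6SS; the orphan group is island-only by construction)."""
    if has_complete:
        return "complete_T6SS"
    if has_island:
        return "orphan_only"
    return "neither"


def cohort_summary(
    profiles: pd.DataFrame,
    groups: pd.Series | None = None,
) -> dict:
    """Per-group counts, proportions and medians over plasmid profiles.

    ``groups`` maps replicon_id -> analysis group (complete_T6SS /
    orphan_only / neither); when absent a ``group`` column is expected.
    Proportions of an empty group are reported as ``None`` (undefined), not
    zero.  The returned dict also carries the 2x2 tables (megaplasmid,
    transmissible, virulence-positive for complete_T6SS vs orphan_only)
    ready for the statistics layer.
    """
    df = profiles.copy()
    if groups is not None:
        df = df.set_index("replicon_id")
        df["group"] = groups
        df = df.reset_index()
    if "group" not in df.columns:
        raise ValueError("cohort_summary needs group assignments")
    df = df[df["kind"] == "plasmid"] if "kind" in df.columns else df

    summary: dict = {"groups": {}}
    for group, sub in df.groupby("group"):
        n = len(sub)
        entry: dict = {"n": n}
        trans_counts = sub["transmissibility"].value_counts().to_dict()
        entry["transmissibility_counts"] = {
            k: int(trans_counts.get(k, 0))
            for k in ("conjugative", "mobilizable", "non_transmissible")}
        entry["transmissibility_proportions"] = {
            k: (v / n if n else None) for k, v in entry["transmissibility_counts"].items()}
        known_mega = sub[sub["megaplasmid"].notna()] if sub["megaplasmid"].isna().any() else sub
        n_known = len(known_mega)
        n_mega = int(sum(bool(v) for v in known_mega["megaplasmid"] if not pd.isna(v)))
        entry["megaplasmid_count"] = n_mega
        entry["megaplasmid_pct"] = round(100.0 * n_mega / n_known, 1) if n_known else None
        entry["mob_counts"] = {k: int(v) for k, v in
                               sub["relaxase_class"].value_counts().items()}
        entry["mpf_counts"] = {k: int(v) for k, v in
                               sub["mpf_type"].value_counts().items()}
        for col in ("ta_count", "amr_count", "length"):
            if col in sub.columns and n:
                entry[f"median_{col}"] = float(sub[col].median())
        summary["groups"][group] = entry

    g = summary["groups"]
    if "complete_T6SS" in g and "orphan_only" in g:
        a, b = g["complete_T6SS"], g["orphan_only"]

        def two_by_two(count_a: int, count_b: int) -> list[list[int]]:
            return [[count_a, a["n"] - count_a], [count_b, b["n"] - count_b]]

        trans_a = a["transmissibility_counts"]["conjugative"] + a["transmissibility_counts"]["mobilizable"]
        trans_b = b["transmissibility_counts"]["conjugative"] + b["transmissibility_counts"]["mobilizable"]
        summary["tables"] = {
            "megaplasmid": two_by_two(a["megaplasmid_count"], b["megaplasmid_count"]),
            "transmissible": two_by_two(trans_a, trans_b),
        }
        if "n_vf" in df.columns:
            vf_a = int((df.loc[df["group"] == "complete_T6SS", "n_vf"] > 0).sum())
            vf_b = int((df.loc[df["group"] == "orphan_only", "n_vf"] > 0).sum())
            summary["tables"]["virulence"] = two_by_two(vf_a, vf_b)
    return summary
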