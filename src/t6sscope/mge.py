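"""Mobile-genetic-element (MGE) context around T6SS loci.

A fixed window of genes on each side of a detected locus (default 20,
excluding the locus itself) is screened for insertion sequences, integrases,
recombinases and transposases; per-IS-family enrichment between complete
systems and orphan islands is then tested with Fisher's exact test under
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .stats import bh_adjust, fisher_exact

MGE_CATEGORIES = frozenset({"MGE", "IS", "integrase", "recombinase", "transposase"})

DEFAULT_WINDOW = 20


@dataclass
class NeighborhoodReport:
    """MGE hits within ``window`` genes of a locus span (span excluded).

    ``internal_hits`` lists MGE genes *inside* the span; they are reported
    for completeness but do not set ``has_mge`` (the screen asks about
    adjacency).
    """

    locus_id: str
    replicon_id: str
    span: tuple[int, int]
    window: int
    mge_hits: list = field(default_factory=list)       # (ordinal, family label, kind)
    internal_hits: list = field(default_factory=list)

    @property
    def has_mge(self) -> bool:
        return bool(self.mge_hits)

    @property
    def families(self) -> frozenset:
        return frozenset(label for _, label, _ in self.mge_hits)


def window_scan(
    locus_id: str,
    span: tuple[int, int],
    gene_table: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    circular: bool = False,
) -> NeighborhoodReport:
    """Collect MGE-category genes within ``window`` genes of ``span``.

    The window is symmetric: ordinals in ``[start - window, start) ∪
    [end, end + window)``, truncated at replicon ends (or wrapped when
    ``circular``).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    start, end = span
    replicon_id = str(gene_table["replicon_id"].iloc[0]) if len(gene_table) else ""
    n_genes = int(gene_table["ordinal"].max()) + 1 if len(gene_table) else 0
    report = NeighborhoodReport(locus_id, replicon_id, (start, end), window)
    mge = gene_table[gene_table["category"].isin(MGE_CATEGORIES)]
    for ordinal, label, category in zip(mge["ordinal"], mge["label"], mge["category"]):
        ordinal = int(ordinal)
        if start <= ordinal < end:
            report.internal_hits.append((ordinal, str(label), str(category)))
            continue
        if circular and n_genes:
            # distance to the nearer span edge going either way round
            up = (start - ordinal) % n_genes
            down = (ordinal - (end - 1)) % n_genes
            dist = min(up, down)
        elif ordinal < start:
            dist = start - ordinal
        else:
            dist = ordinal - end + 1
        if dist <= window:
            report.mge_hits.append((ordinal, str(label), str(category)))
    report.mge_hits.sort()
    report.internal_hits.sort()
    return report


def reports_to_frame(reports: list[NeighborhoodReport], locus_class: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "locus_id": r.locus_id, "replicon_id": r.replicon_id,
            "start": r.span[0], "end": r.span[1], "window": r.window,
            "has_mge": r.has_mge,
            "families": ",".join(sorted(r.families)),
            "locus_class": (locus_class or {}).get(r.locus_id, ""),
        })
    return pd.DataFrame(rows)


def family_association(
    reports_by_class: dict[str, list[NeighborhoodReport]],
) -> pd.DataFrame:
    """Per-IS-family 2x2 Fisher tests (present/absent x complete/orphan).

    ``reports_by_class`` maps locus class ('complete', 'orphan') to its
    neighborhood reports.  Families absent everywhere are skipped.  Returns
    a table with the 2x2 counts, two-sided p, odds ratio and BH-adjusted p.
    """
    classes = sorted(reports_by_class)
    if len(classes) != 2:
        raise ValueError("family_association expects exactly two locus classes")
    ref, other = classes  # alphabetical: ('complete', 'orphan')
    families = sorted({f for reports in reports_by_class.values()
                       for r in reports for f in r.families})
    rows = []
    for family in families:
        present = {c: sum(1 for r in reports_by_class[c] if family in r.families)
                   for c in classes}
        total = {c: len(reports_by_class[c]) for c in classes}
        table = [[present[ref], total[ref] - present[ref]],
                 [present[other], total[other] - present[other]]]
        result = fisher_exact(table, side="two_sided")
        rows.append({
            "family": family,
            f"present_{ref}": present[ref], f"absent_{ref}": total[ref] - present[ref],
            f"present_{other}": present[other], f"absent_{other}": total[other] - present[other],
            "odds_ratio": result.odds_ratio, "p": result.p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["adjusted_p"] = bh_adjust(df["p"].tolist())
    return df
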